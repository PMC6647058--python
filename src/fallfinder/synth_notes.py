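"""Seeded synthetic ED provider notes with known ground truth.

Real ED notes are protected health information and cannot ship with the
package, so every pipeline stage is exercised on generated notes instead.
Each note is assembled from sectioned templates (Chief Complaint, HPI,
Past Medical History, Review of Systems, Physical Exam, MDM) around one
*construct*: a phrase family with a known gold label and a known expected
verdict under the published ruleset.

Construct families fall into two pools.  The benign pool contains only
patterns the published algorithm handles correctly (clean positives,
negations, idiom/uncertainty/averted/risk/season exclusions, embedded
words, historical mentions confined to the PMH), so on a corpus drawn
purely from it the pipeline must score 100% sensitivity and specificity
against gold.  The adversarial pool reproduces the documented error
families of the validated algorithm — notes whose gold label and expected
published verdict deliberately disagree (e.g. the FOOSH acronym, "fell
apart", "fall 2016" without "of", a frozen chicken package that fell).

Generation is fully deterministic: one integer seed drives family
assignment, and each note draws from its own child stream so the corpus
is byte-identical across runs.

The templates are minimal-but-sectioned synthetic text: headers plus short
clinical sentences.  They emulate note *structure* and fall phraseology,
not clinical nuance.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import ClinicalNote, GoldLabel, Label

__all__ = [
    "SynthSpec",
    "SynthNote",
    "generate_corpus",
    "write_corpus",
    "BENIGN_FAMILIES",
    "ADVERSARIAL_FAMILIES",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic corpus.

    ``prevalence`` is the target proportion of gold-positive notes
    (default 0.24, the consensus-coded fall prevalence in the validation
    test set).  ``adversarial_rate`` is the proportion of notes drawn
    from the documented error constructs.  ``construct_weights``
    optionally re-weights families within each pool.
    """

    n_notes: int
    prevalence: float = 0.24
    seed: int = 0
    adversarial_rate: float = 0.0
    construct_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_notes < 1:
            raise ValueError("n_notes must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0.0 <= self.adversarial_rate <= 1.0:
            raise ValueError("adversarial_rate must be in [0, 1]")


@dataclass(frozen=True)
class SynthNote:
    """A generated note with its ground truth and expected pipeline verdict."""

    note: ClinicalNote
    gold: GoldLabel
    expected_label_published: Label
    construct_tags: tuple[str, ...]


@dataclass(frozen=True)
class _Family:
    name: str
    gold: bool
    expected_published: Label
    adversarial: bool
    variants: tuple[Mapping[str, str], ...]
    negated_mention: bool = False


def _benign(name, gold, expected, variants, negated_mention=False):
    return _Family(name, gold, Label(expected), False, tuple(variants), negated_mention)


def _adv(name, gold, expected, variants):
    return _Family(name, gold, Label(expected), True, tuple(variants))


# ---------------------------------------------------------------------------
# Benign pool: constructs the published algorithm classifies correctly.
# ---------------------------------------------------------------------------

_BENIGN = (
    _benign("clean_positive", True, "FALL", [
        {"hpi": "She fell down the stairs at home earlier today."},
        {"hpi": "Pt slipped and fell in the bathroom this morning."},
        {"hpi": "He fell off a ladder while cleaning the gutters."},
        {"hpi": "Patient reports falling while walking to the mailbox."},
        {"hpi": "Witnessed fall from standing height in the kitchen."},
    ]),
    _benign("postneg_positive", True, "FALL", [
        {"hpi": "Patient fell but did not lose consciousness."},
        {"hpi": "She fell but denies striking her head."},
        {"hpi": "Fell from the chair but no loss of consciousness."},
    ]),
    _benign("presumed_positive", True, "FALL", [
        {"hpi": "Presumed fall given the bruising pattern."},
        {"hpi": "She is believed to have fallen during the night."},
    ]),
    _benign("clean_negative", False, "NO_FALL", [
        {"hpi": "Symptoms have been constant since onset."},
        {"hpi": "Patient reports gradual worsening over two days."},
        {"hpi": "Symptoms improved somewhat with rest."},
    ]),
    _benign("negated", False, "NO_FALL", [
        {"hpi": "Patient denies falls."},
        {"hpi": "She denies any fall or head injury."},
        {"hpi": "No falls recently per family."},
        {"hpi": "He has never fallen before."},
        {"hpi": "She didn’t fall."},
        {"hpi": "Without falls or syncope in the interim."},
    ], negated_mention=True),
    _benign("exception_asleep", False, "NO_FALL", [
        {"hpi": "He fell asleep on the couch watching television."},
        {"hpi": "She falls asleep easily during the day."},
    ]),
    _benign("embedded_word", False, "NO_FALL", [
        {"hpi": "The ENT fellow was consulted at bedside."},
        {"hpi": "Imaging showed a known fallopian cyst."},
        {"hpi": "The orthopedic fellowship service was notified."},
    ]),
    _benign("season_of", False, "NO_FALL", [
        {"hpi": "She has had multiple UTIs in the fall of 2016."},
        {"hpi": "Last seen in clinic in the fall of 2015."},
    ]),
    _benign("historical_pmh", False, "NO_FALL", [
        {"pmh": "s/p fall in 2015 without sequelae."},
        {"pmh": "remote fall with hip fracture in 2014."},
    ]),
    _benign("uncertain", False, "NO_FALL", [
        {"hpi": "She may have fallen at home."},
        {"hpi": "Unsure if the patient fell before arrival."},
        {"hpi": "Uncertain if patient fell or simply slid from the bed."},
    ]),
    _benign("averted", False, "NO_FALL", [
        {"hpi": "She almost fell getting out of bed."},
        {"hpi": "He nearly fell stepping off the curb."},
    ]),
    _benign("risk", False, "NO_FALL", [
        {"hpi": "She is at high fall risk per physical therapy."},
        {"hpi": "Fall precautions were reviewed with the family."},
        {"hpi": "Discussed risk of falls given her new medication."},
    ]),
)

# ---------------------------------------------------------------------------
# Adversarial pool: the documented error families.  Gold label and expected
# published verdict disagree by construction.
# ---------------------------------------------------------------------------

_ADVERSARIAL = (
    # false positives of the published algorithm
    _adv("cc_error", False, "FALL", [
        {"cc": "Patient presents with other weakness Fall.",
         "hpi": "Profuse watery diarrhea and generalized weakness for three days."},
    ]),
    _adv("object_fell", False, "FALL", [
        {"hpi": "A frozen chicken package fell from the freezer and struck his left lower leg."},
        {"hpi": "A picture frame fell from the wall and hit her forearm."},
    ]),
    _adv("historical_hpi", False, "FALL", [
        {"hpi": "Had a fall three weeks ago with left knee laceration, now presents with fatigue and low hemoglobin."},
    ]),
    _adv("season_no_of", False, "FALL", [
        {"hpi": "She has had multiple UTIs in the fall 2016."},
    ]),
    _adv("pmh_abbrev", False, "FALL", [
        {"pmh_header": "PMH: hypertension, diabetes mellitus. s/p fall."},
    ]),
    _adv("transcription_error", False, "FALL", [
        {"hpi": "Patient has a known left-sided ovarian mass which her primary care physician and her husband falling."},
    ]),
    _adv("idiom", False, "FALL", [
        {"hpi": "Pt states she fell apart after her divorce."},
    ]),
    _adv("unable_confirm", False, "FALL", [
        {"hpi": "The patient is unable to confirm falling."},
        {"hpi": "Son is unable to confirm if the patient fell or not."},
    ]),
    # false negatives of the published algorithm
    _adv("foosh", True, "NO_FALL", [
        {"hpi": "Presents with left wrist pain sustained after a FOOSH injury while playing tennis."},
    ]),
    _adv("described_no_fall_word", True, "NO_FALL", [
        {"hpi": "She missed the toilet and landed on her right hip."},
        {"hpi": "She went down to the ground and struck her head."},
        {"hpi": "He woke up on the floor with a large hematoma on the back of his head."},
    ]),
    _adv("past_fall_relevant", True, "NO_FALL", [
        {"hpi": "Presents with a CT angiogram showing occlusion.",
         "pmh": "fell one month ago with a wound to the right knee, now a non-healing sore."},
    ]),
)

BENIGN_FAMILIES: tuple[str, ...] = tuple(f.name for f in _BENIGN)
ADVERSARIAL_FAMILIES: tuple[str, ...] = tuple(f.name for f in _ADVERSARIAL)
_BY_NAME = {f.name: f for f in _BENIGN + _ADVERSARIAL}

_BENIGN_POSITIVE = tuple(f.name for f in _BENIGN if f.gold)
_BENIGN_NEGATIVE = tuple(f.name for f in _BENIGN if not f.gold)

# filler vocabulary — deliberately free of fall-family words
_COMPLAINTS = (
    "abdominal pain", "shortness of breath", "chest pain", "dizziness",
    "fever and cough", "generalized weakness", "left wrist pain",
)
_COMORBIDITIES = (
    "hypertension", "diabetes mellitus", "atrial fibrillation",
    "COPD", "chronic kidney disease",
)
_HPI_EXTRAS = (
    "Patient reports associated nausea.",
    "Pain is rated 6 out of 10.",
    "Vitals were stable on arrival.",
    "Symptoms were witnessed by a family member.",
    "Patient lives alone and is independent in activities of daily living.",
)
_ROS_FILLERS = (
    "Review of Systems: Negative for fever, chills, and weight loss. All other systems reviewed and negative.",
    "Review of Systems: Ten systems reviewed and negative except as noted in the HPI.",
)
_PE_FILLERS = (
    "Physical Exam: Alert and oriented. Heart regular rate and rhythm. Lungs clear to auscultation.",
    "Physical Exam: No acute distress. Abdomen soft and nontender. Neurologic exam nonfocal.",
)
_MDM_FILLERS = (
    "MDM: Labs and imaging reviewed. Plan discussed with the patient. Will treat symptomatically and arrange follow-up.",
    "MDM: Workup reassuring. Discussed return precautions. Discharged in stable condition.",
)


def _pick(rng: np.random.Generator, options: Sequence) -> object:
    return options[int(rng.integers(len(options)))]


def _render_note(note_id: str, family: _Family, rng: np.random.Generator) -> ClinicalNote:
    payload = _pick(rng, family.variants)
    age = int(rng.integers(65, 96))
    sex = _pick(rng, ("male", "female"))
    complaint = _pick(rng, _COMPLAINTS)
    comorbidity = _pick(rng, _COMORBIDITIES)

    cc = payload.get("cc", f"Patient presents with {complaint}.")
    hpi_parts = [f"The patient is a {age}-year-old {sex} with a history of {comorbidity}."]
    if "hpi" in payload:
        hpi_parts.append(payload["hpi"])
    hpi_parts.append(str(_pick(rng, _HPI_EXTRAS)))

    pmh_items = f"{comorbidity}, osteoarthritis"
    pmh_extra = f" {payload['pmh']}" if "pmh" in payload else ""
    pmh = payload.get("pmh_header", f"Past Medical History: {pmh_items}.{pmh_extra}")

    lines = [
        f"Chief Complaint: {cc}",
        "HPI: " + " ".join(hpi_parts),
        pmh,
        str(_pick(rng, _ROS_FILLERS)),
        str(_pick(rng, _PE_FILLERS)),
        str(_pick(rng, _MDM_FILLERS)),
    ]
    return ClinicalNote(note_id=note_id, text="\n".join(lines) + "\n")


def _draw_family(rng: np.random.Generator, pool: Sequence[str],
                 weights: Mapping[str, float] | None) -> str:
    if weights:
        w = np.array([float(weights.get(name, 1.0)) for name in pool])
        if w.sum() <= 0:
            raise ValueError("construct_weights must give the pool positive mass")
        return str(pool[int(rng.choice(len(pool), p=w / w.sum()))])
    return str(_pick(rng, pool))


def generate_corpus(spec: SynthSpec) -> list[SynthNote]:
    """Generate a deterministic corpus of synthetic notes.

    Exactly ``round(n_notes * adversarial_rate)`` notes are drawn from the
    adversarial pool; gold-positive notes total ``round(n_notes *
    prevalence)`` where the adversarial draws allow (adversarial families
    carry fixed gold labels, so the achievable positive count is clamped
    to the benign notes available).
    """
    master = np.random.default_rng(spec.seed)
    n = spec.n_notes

    n_adv = int(round(n * spec.adversarial_rate))
    adv_idx = set(map(int, master.choice(n, size=n_adv, replace=False))) if n_adv else set()

    families: dict[int, str] = {}
    for i in sorted(adv_idx):
        families[i] = _draw_family(master, ADVERSARIAL_FAMILIES, spec.construct_weights)

    n_pos_target = int(round(n * spec.prevalence))
    adv_pos = sum(_BY_NAME[families[i]].gold for i in sorted(adv_idx))
    benign_idx = [i for i in range(n) if i not in adv_idx]
    n_pos_benign = min(max(n_pos_target - adv_pos, 0), len(benign_idx))
    pos_benign = (
        set(map(int, master.choice(len(benign_idx), size=n_pos_benign, replace=False)))
        if benign_idx
        else set()
    )
    for j, i in enumerate(benign_idx):
        pool = _BENIGN_POSITIVE if j in pos_benign else _BENIGN_NEGATIVE
        families[i] = _draw_family(master, pool, spec.construct_weights)

    notes: list[SynthNote] = []
    for i in range(n):
        fam = _BY_NAME[families[i]]
        note_id = f"note_{i:05d}"
        rng = np.random.default_rng([spec.seed, i])  # per-note child stream
        note = _render_note(note_id, fam, rng)
        tags = (fam.name, "adversarial") if fam.adversarial else (fam.name,)
        notes.append(
            SynthNote(
                note=note,
                gold=GoldLabel(note_id=note_id, fall=fam.gold,
                               negated_mention=fam.negated_mention),
                expected_label_published=fam.expected_published,
                construct_tags=tags,
            )
        )
    return notes


def write_corpus(notes: list[SynthNote], out_dir: str | Path) -> None:
    """Write a corpus as a txt_dir plus gold.csv and constructs.jsonl."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sn in notes:
        (out / f"{sn.note.note_id}.txt").write_text(sn.note.text, encoding="utf-8")
    with open(out / "gold.csv", "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["note_id", "fall", "negated_mention"])
        for sn in notes:
            writer.writerow([
                sn.gold.note_id,
                int(sn.gold.fall),
                int(bool(sn.gold.negated_mention)),
            ])
    with open(out / "constructs.jsonl", "w", encoding="utf-8") as fh:
        for sn in notes:
            fh.write(json.dumps({
                "note_id": sn.note.note_id,
                "construct_tags": list(sn.construct_tags),
                "gold_fall": sn.gold.fall,
                "expected_label_published": sn.expected_label_published.value,
            }) + "\n")
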
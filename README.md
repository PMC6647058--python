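# fallfinder

Pragmatic rules-based NLP for identifying fall-related visits in
emergency-department provider notes.

Falls are a leading cause of injury in adults 65 and older, and the ED is
where many of them surface — but a fall visit is a *syndromic* presentation
that diagnosis codes capture poorly, and manual chart review does not scale
to surveillance or quality measurement. `fallfinder` implements a short,
transparent, rules-based pipeline that classifies each free-text ED provider
note as **FALL** or **NO_FALL**:

1. **Section removal** — the Past Medical History (old falls unrelated to
   the visit) and Review of Systems (unstructured negated lists) sections
   are never scanned.
2. **Sentence division** — deterministic rule-based splitting with an
   abbreviation guard, preserving character offsets into the original note.
3. **Fall-term matching** — word-boundary regular expression over
   fall / falls / fell / fallen / falling ("fellow" and "fallopian" never
   match).
4. **Exception filtering** — idioms ("fell asleep"), uncertainty ("may have
   fallen"), averted events ("almost fell"), fall-risk language ("fall
   risk"), and the season ("fall of 2016") are excluded; certainty language
   ("presumed fall") is kept.
5. **Directional negation** — a mention is negated iff a cue ("no", "not",
   "n't", "negative", "never", "didn't", "without", "denies", "deny")
   precedes the term in its sentence; cues after the term are ignored
   ("Patient fell but did not lose consciousness" stays positive).
6. **Note-level vote** — FALL iff positive mentions strictly outnumber
   negated ones; ties go to no-fall.

Against gold-standard consensus coding such a classifier is scored with the
standard 2×2 panel — sensitivity TP/(TP+FN), specificity TN/(TN+FP),
PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy, F1 = 2·PPV·Se/(PPV+Se) — each
with an exact Clopper–Pearson 95% interval from beta-quantile inversion
(Wilson intervals behind a flag), plus Cohen's κ for inter-rater agreement.

Because real ED notes are protected health information, the package ships a
seeded synthetic note generator (`fallfinder.synth_notes`) producing
sectioned notes with known ground truth, including an adversarial pool that
reproduces every documented error family of the validated ruleset (FOOSH,
"fell apart", "fall 2016", objects that fell, falls described without fall
words, …). Two rulesets are bundled: `published` (the validated behavior,
blind spots included) and `extended` (adds the fixes for the documented,
fixable errors).

## Worked example

```python
import fallfinder as ff

rules = ff.load_ruleset("published")
note = ff.ClinicalNote("ed_0001",
    "Chief Complaint: Patient presents with right hip pain.\n"
    "HPI: Pt fell down the stairs at home this morning. She fell but denies "
    "striking her head. Patient denies prior falls.\n"
    "Past Medical History: hypertension, s/p fall in 2015.\n"
    "Review of Systems: Negative for fever, chills, and weight loss.\n"
    "MDM: Imaging reviewed. Will admit for further workup.\n")
cls, mentions = ff.classify_note(note, rules)
print("label:", cls.label.value)
print("counts:", cls.n_positive, "positive,", cls.n_negated, "negated")
for m in mentions:
    print(f"  {m.surface!r} at {m.term_start}:{m.term_end} -> {m.status.value}")
```

prints

```
label: FALL
counts: 2 positive, 1 negated
  'fell' at 63:67 -> POSITIVE
  'fell' at 110:114 -> POSITIVE
  'falls' at 166:171 -> NEGATED
```

The two positive mentions outnumber the one negated mention, so the note is
coded FALL; the "s/p fall" in the Past Medical History was never scanned,
and "denies" before "falls" negated that mention. Scoring a 2×2 outcome
table:

```python
cm = ff.ConfusionMatrix(tp=115, fp=10, fn=5, tn=370)
print(ff.compute_metrics(cm).summary())
```

```
Sensitivity (Recall)   95.8%  (95%CI 90.5-98.6)
Specificity            97.4%  (95%CI 95.2-98.7)
PPV (Precision)        92.0%  (95%CI 85.8-96.1)
NPV                    98.7%  (95%CI 96.9-99.6)
Accuracy               97.0%  (95%CI 95.1-98.3)
F1 Score              0.939
Misclassified         15 of 500
```

## Command line

```sh
fallfinder synth --n 500 --prevalence 0.24 --seed 1 --adversarial-rate 0.0 --out-dir corpus/
fallfinder run   --notes corpus/ --format txt_dir --ruleset published --out results.csv --evidence evidence.jsonl
fallfinder eval  --pred results.csv --gold corpus/gold.csv --out metrics.json
```

`synth` writes one `.txt` per note plus `gold.csv` and a
`constructs.jsonl` manifest of each note's construct family and expected
verdict; `run` writes a flat results CSV (per-mention evidence spans are
opt-in via `--evidence`); `eval` prints the metrics table and writes them
as JSON.

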
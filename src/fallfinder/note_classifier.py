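"""Note-level aggregation and the end-to-end classification pipeline.

Mentions vote: a note is coded FALL only when positive mentions strictly
outnumber negated ones.  Ties go to no-fall — the negation-favoring
tie-break chosen during the algorithm's development because the
positive-favoring alternative produced many more false positives than
false negatives.  Excluded mentions carry no vote.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .corpus_io import ClinicalNote, Label, ResultRecord
from .mention_detection import (
    FallMention,
    MentionStatus,
    apply_exceptions,
    find_fall_terms,
)
from .negation import detect_negation
from .preprocess import segment_sections, split_sentences
from .rules import RuleSet

__all__ = ["NoteClassification", "aggregate_note", "classify_note", "classify_corpus"]

_EXCLUDED = {
    MentionStatus.EXCLUDED_EXCEPTION,
    MentionStatus.EXCLUDED_UNCERTAIN,
    MentionStatus.EXCLUDED_AVERTED,
    MentionStatus.EXCLUDED_RISK,
    MentionStatus.EXCLUDED_SEASON,
}


@dataclass(frozen=True)
class NoteClassification:
    """Note-level verdict with the mention counts that produced it."""

    note_id: str
    n_positive: int
    n_negated: int
    n_excluded: dict[str, int]
    label: Label
    negated_mention: bool

    def to_result_record(self, mentions: tuple = ()) -> ResultRecord:
        return ResultRecord(
            note_id=self.note_id,
            label=self.label,
            n_positive=self.n_positive,
            n_negated=self.n_negated,
            negated_mention=self.negated_mention,
            mentions=mentions,
        )


def aggregate_note(
    mentions: list[FallMention], rules: RuleSet | None = None, note_id: str = ""
) -> NoteClassification:
    """Reduce a note's mentions to a single FALL / NO_FALL verdict.

    With the default negation-favoring tie-break, FALL requires
    ``n_positive > n_negated``; the configurable positive-favoring variant
    relaxes the tie to FALL.  An empty mention list yields NO_FALL.
    """
    ids = {m.note_id for m in mentions if m.note_id}
    if len(ids) > 1:
        raise ValueError(f"mentions from multiple notes: {sorted(ids)}")
    if not note_id and ids:
        note_id = next(iter(ids))
    if any(m.status is None for m in mentions):
        raise ValueError("all mentions must have a terminal status")

    n_pos = sum(m.status is MentionStatus.POSITIVE for m in mentions)
    n_neg = sum(m.status is MentionStatus.NEGATED for m in mentions)
    n_excl = Counter(m.status.value for m in mentions if m.status in _EXCLUDED)

    tie_break = rules.tie_break if rules is not None else "negated_wins"
    if tie_break == "positive_wins":
        fall = n_pos >= n_neg and n_pos > 0
    else:
        fall = n_pos > n_neg
    return NoteClassification(
        note_id=note_id,
        n_positive=n_pos,
        n_negated=n_neg,
        n_excluded=dict(n_excl),
        label=Label.FALL if fall else Label.NO_FALL,
        negated_mention=n_neg >= 1,
    )


def classify_note(
    note: ClinicalNote, rules: RuleSet
) -> tuple[NoteClassification, list[FallMention]]:
    """Run the full pipeline on one note.

    Composition of the five stages: section removal → sentence division →
    fall-term matching → exception checks → directional negation →
    note-level vote.  Returns the verdict together with every mention
    (terminal statuses included) as the audit trail.
    """
    sectioned = segment_sections(note, rules)
    sentences = split_sentences(sectioned, rules)
    mentions: list[FallMention] = []
    for idx, sent in enumerate(sentences):
        for cand in find_fall_terms(sent, rules, note_id=note.note_id, sentence_index=idx):
            m = apply_exceptions(cand, sent, rules)
            if m.status is None:
                m = detect_negation(m, sent, rules)
            mentions.append(m)
    return aggregate_note(mentions, rules, note_id=note.note_id), mentions


def classify_corpus(
    notes: list[ClinicalNote], rules: RuleSet
) -> list[tuple[NoteClassification, list[FallMention]]]:
    """Classify every note in a corpus, preserving input order."""
    return [classify_note(n, rules) for n in notes]
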
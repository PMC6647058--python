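"""Fall-term matching and exception classification.

A candidate mention is any word-boundary match of the fall pattern
(fall / falls / fell / fallen / falling, case-insensitive) in a retained
sentence; terms embedded in longer words ("fellow", "fallopian") never
match.  Each candidate is then checked against the exception lists —
idioms ("fell asleep"), uncertainty ("may have fallen"), averted events
("almost fell"), fall-risk language ("fall risk") and the season written
as "fall of 2016" — before negation is considered.  Certainty language
used for medical decision making ("presumed fall", "believed to have
fallen") matches no exception and therefore stays a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .preprocess import Sentence
from .rules import RuleSet

__all__ = ["MentionStatus", "FallMention", "find_fall_terms", "apply_exceptions"]


class MentionStatus(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATED = "NEGATED"
    EXCLUDED_EXCEPTION = "EXCLUDED_EXCEPTION"
    EXCLUDED_UNCERTAIN = "EXCLUDED_UNCERTAIN"
    EXCLUDED_AVERTED = "EXCLUDED_AVERTED"
    EXCLUDED_RISK = "EXCLUDED_RISK"
    EXCLUDED_SEASON = "EXCLUDED_SEASON"


#: exception class name -> terminal status
_CLASS_STATUS = {
    "exception": MentionStatus.EXCLUDED_EXCEPTION,
    "uncertain": MentionStatus.EXCLUDED_UNCERTAIN,
    "averted": MentionStatus.EXCLUDED_AVERTED,
    "risk": MentionStatus.EXCLUDED_RISK,
    "season": MentionStatus.EXCLUDED_SEASON,
}


@dataclass(frozen=True)
class FallMention:
    """One matched fall term.

    Offsets are 0-based half-open character positions into the original
    note text.  ``status`` is ``None`` while the mention is still a
    candidate; the detect → except → negate cascade sets it exactly once.
    """

    note_id: str
    sentence_index: int
    term_start: int
    term_end: int
    surface: str
    status: MentionStatus | None = None

    def to_dict(self) -> dict:
        return {
            "note_id": self.note_id,
            "sentence_index": self.sentence_index,
            "term_start": self.term_start,
            "term_end": self.term_end,
            "surface": self.surface,
            "status": self.status.value if self.status else None,
        }


def find_fall_terms(
    sentence: Sentence, rules: RuleSet, note_id: str = "", sentence_index: int = 0
) -> list[FallMention]:
    """Find candidate fall terms in one sentence.

    Matches are non-overlapping, left-to-right, at word boundaries, so a
    fall stem inside a longer word never produces a candidate.
    """
    out = []
    for m in rules.fall_regex.finditer(sentence.text):
        out.append(
            FallMention(
                note_id=note_id,
                sentence_index=sentence_index,
                term_start=sentence.start + m.start(),
                term_end=sentence.start + m.end(),
                surface=m.group(0),
                status=None,
            )
        )
    return out


def apply_exceptions(
    candidate: FallMention, sentence: Sentence, rules: RuleSet
) -> FallMention:
    """Assign an EXCLUDED_* status when an exception pattern covers the term.

    Exception patterns are matched case-insensitively against the whole
    sentence (cue and term may be separated, as in "uncertain if patient
    fell"); a pattern excludes the candidate when its match span contains
    the fall term.  Classes are tried in a fixed order so the status is
    set deterministically and exactly once; a candidate matching no
    exception is returned unchanged for negation to decide.
    """
    if candidate.status is not None:
        raise ValueError("candidate already has a status")
    rel_start = candidate.term_start - sentence.start
    rel_end = candidate.term_end - sentence.start
    for cls, regex in rules.exception_regexes():
        for m in regex.finditer(sentence.text):
            if m.start() <= rel_start and rel_end <= m.end():
                return replace(candidate, status=_CLASS_STATUS[cls])
    return candidate
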
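"""Directional negation of surviving fall candidates.

A mention is negated when a negation cue ("no", "not", "n't", "negative",
"never", "didn't", "without", "denies", "deny") occurs as a whole token
anywhere *before* the fall term within the same sentence.  Cues after the
term are deliberately ignored: they overwhelmingly negate events that did
not occur *during* a fall ("Patient fell but did not lose consciousness"),
not the fall itself.  Scope is the whole preceding portion of the
sentence — no token-distance window — and each mention is tested
independently, so one "denies" preceding two fall terms negates both.
"""

from __future__ import annotations

import re
from dataclasses import replace

from .mention_detection import FallMention, MentionStatus
from .preprocess import Sentence
from .rules import RuleSet

__all__ = ["detect_negation"]

# EHR text mixes straight and curly apostrophes; treat them as one glyph.
_APOSTROPHES = {"’": "'", "‘": "'"}

_TOKEN = re.compile(r"[A-Za-z]+(?:'[A-Za-z]+)*")


def _normalize(text: str) -> str:
    for curly, straight in _APOSTROPHES.items():
        text = text.replace(curly, straight)
    return text


def detect_negation(
    candidate: FallMention, sentence: Sentence, rules: RuleSet
) -> FallMention:
    """Classify a surviving candidate as NEGATED or POSITIVE.

    NEGATED iff any configured cue appears as a whole token (or "n't" as a
    token suffix) before the term in the sentence; otherwise POSITIVE.
    """
    if candidate.status is not None:
        raise ValueError("candidate already has a status")
    before = _normalize(sentence.text[: candidate.term_start - sentence.start])
    cues = [_normalize(c) for c in rules.negation_cues]
    if not rules.negation_case_sensitive:
        before = before.lower()
        cues = [c.lower() for c in cues]
    # "n't" (or any cue containing an apostrophe-contraction) matches as a
    # token suffix: "didn't", "doesn't", "couldn't" all carry it.
    suffix_cues = tuple(c for c in cues if c.startswith("n'") or c.startswith("'"))
    word_cues = frozenset(cues)
    negated = any(
        tok.group(0) in word_cues
        or any(tok.group(0).endswith(s) for s in suffix_cues)
        for tok in _TOKEN.finditer(before)
    )
    status = MentionStatus.NEGATED if negated else MentionStatus.POSITIVE
    return replace(candidate, status=status)
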
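"""Section removal and sentence segmentation.

Two sections of the ED note are deliberately never scanned: the Past
Medical History, which routinely mentions falls that precede or are
unrelated to the current visit, and the Review of Systems, whose
long negated item lists lack usable sentence structure.  Everything else
is divided into sentences with character offsets into the original note,
so every downstream mention can be traced back to the raw text.

All coordinates are 0-based half-open character offsets into the original
note text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus_io import ClinicalNote
from .rules import RuleSet

__all__ = ["SectionedNote", "Sentence", "segment_sections", "split_sentences"]


@dataclass(frozen=True)
class Sentence:
    """One sentence of retained note text; offsets index the original note."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class SectionedNote:
    """A note partitioned into retained spans and removed sections."""

    note_id: str
    text: str
    retained_segments: tuple[tuple[int, int, str], ...]
    removed_sections: tuple[tuple[str, int, int], ...]


def _header_regex(name: str) -> re.Pattern[str]:
    # header words separated by arbitrary whitespace, optional trailing colon
    words = [re.escape(w) for w in name.split()]
    return re.compile(r"\b" + r"\s+".join(words) + r"\b\s*:?", re.IGNORECASE)


def _anchored(text: str, start: int) -> bool:
    """A header counts only at line start or after sentence-terminal punctuation."""
    j = start
    while j > 0 and text[j - 1] in " \t":
        j -= 1
    return j == 0 or text[j - 1] in "\n.!?"


def _find_headers(text: str, rules: RuleSet) -> list[tuple[str, int, int]]:
    """Non-overlapping (section_name, start, end_of_header) sorted by start."""
    known = list(dict.fromkeys(list(rules.section_known) + list(rules.section_remove)))
    hits: list[tuple[int, int, str]] = []
    for name in known:
        for m in _header_regex(name).finditer(text):
            if _anchored(text, m.start()):
                hits.append((m.start(), -(m.end() - m.start()), name))
    hits.sort()
    out: list[tuple[str, int, int]] = []
    last_end = -1
    for start, neg_len, name in hits:
        end = start - neg_len
        if start >= last_end:  # longest match at each position wins
            out.append((name, start, end))
            last_end = end
    return out


def segment_sections(note: ClinicalNote, rules: RuleSet) -> SectionedNote:
    """Partition a note into retained spans and removed sections.

    A section runs from its recognized header to the next recognized header
    of any known type, or to the end of the note.  Text before the first
    header is always retained; a headerless note is retained whole.
    """
    text = note.text
    headers = _find_headers(text, rules)
    remove_names = {n.lower() for n in rules.section_remove}

    retained: list[tuple[int, int, str]] = []
    removed: list[tuple[str, int, int]] = []

    cursor = 0
    for i, (name, start, _hdr_end) in enumerate(headers):
        if cursor < start:
            retained.append((cursor, start, text[cursor:start]))
        end = headers[i + 1][1] if i + 1 < len(headers) else len(text)
        if name.lower() in remove_names:
            removed.append((name, start, end))
        else:
            retained.append((start, end, text[start:end]))
        cursor = end
    if cursor < len(text):
        retained.append((cursor, len(text), text[cursor:]))

    # drop empty spans
    retained = [(s, e, t) for s, e, t in retained if e > s]
    return SectionedNote(
        note_id=note.note_id,
        text=text,
        retained_segments=tuple(retained),
        removed_sections=tuple(removed),
    )


_TERMINALS = ".!?"


def _is_abbreviation(text: str, dot: int, abbreviations: tuple[str, ...]) -> bool:
    """True when the period at ``dot`` ends a listed abbreviation token."""
    m = re.search(r"[A-Za-z](?:[A-Za-z.]*[A-Za-z])?$", text[:dot])
    if not m:
        return False
    return m.group(0).lower() in abbreviations


def _sentence_breaks(text: str, rules: RuleSet) -> list[int]:
    """Positions just after which a sentence ends (break indices)."""
    breaks: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            breaks.append(i)
            while i + 1 < n and text[i + 1] == "\n":
                i += 1
                breaks.append(i)
        elif ch in _TERMINALS:
            # absorb runs like "..." or "?!"
            j = i
            while j + 1 < n and text[j + 1] in _TERMINALS:
                j += 1
            if ch == "." and i == j:
                inside_decimal = (
                    0 < i < n - 1 and text[i - 1].isdigit() and text[i + 1].isdigit()
                )
                if inside_decimal or _is_abbreviation(text, i, rules.abbreviations):
                    i += 1
                    continue
            breaks.append(j)
            i = j
        i += 1
    return breaks


def split_sentences(sectioned: SectionedNote, rules: RuleSet) -> list[Sentence]:
    """Divide retained text into sentences.

    Splits at ``.``, ``!``, ``?`` and newlines, guarded by a configurable
    abbreviation list and a no-split rule inside decimal numbers.  A
    sentence never crosses a retained-segment boundary, and slicing the
    original note text by each sentence's offsets reproduces its text.
    """
    out: list[Sentence] = []
    for seg_start, _seg_end, seg_text in sectioned.retained_segments:
        prev = 0
        bounds = [b + 1 for b in _sentence_breaks(seg_text, rules)]
        if not bounds or bounds[-1] < len(seg_text):
            bounds.append(len(seg_text))
        for b in bounds:
            chunk = seg_text[prev:b]
            stripped = chunk.strip()
            if stripped:
                lead = len(chunk) - len(chunk.lstrip())
                start = seg_start + prev + lead
                out.append(Sentence(text=stripped, start=start, end=start + len(stripped)))
            prev = b
    out.sort(key=lambda s: s.start)
    return out
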
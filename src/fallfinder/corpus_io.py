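"""Corpus input/output: notes, gold-standard labels and per-note results.

The unit of analysis throughout the package is the ED provider note — one
free-text document per visit.  Notes arrive as a directory of ``*.txt``
files, a JSONL stream, or a CSV table; gold labels as CSV or JSONL.
Results are written as a flat CSV, optionally accompanied by a JSONL
evidence file carrying the matched fall mentions for audit.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Label",
    "ClinicalNote",
    "GoldLabel",
    "ResultRecord",
    "read_notes",
    "read_gold",
    "write_results",
    "read_results",
]


class Label(str, Enum):
    """Note-level verdict."""

    FALL = "FALL"
    NO_FALL = "NO_FALL"


@dataclass(frozen=True)
class ClinicalNote:
    """One ED provider note: an opaque identifier plus raw text."""

    note_id: str
    text: str


@dataclass(frozen=True)
class GoldLabel:
    """Consensus-coded reference label for one note.

    Negated fall mentions belong to the no-fall group, so ``fall`` is the
    only field evaluation depends on; ``negated_mention`` is carried for
    descriptive statistics.
    """

    note_id: str
    fall: bool
    negated_mention: bool | None = None


@dataclass(frozen=True)
class ResultRecord:
    """Per-note pipeline output row."""

    note_id: str
    label: Label
    n_positive: int
    n_negated: int
    negated_mention: bool
    mentions: tuple = field(default_factory=tuple, compare=False)


def _read_text(path: Path) -> str:
    # EHR exports vary in encoding: UTF-8 first, latin-1 as fallback.
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate note_id in {what}: {i!r}")
        seen.add(i)


def read_notes(path: str | Path, format: str = "txt_dir") -> list[ClinicalNote]:
    """Read a corpus of notes.

    Parameters
    ----------
    path
        Directory of ``*.txt`` files (``txt_dir``, note_id = filename stem,
        lexicographic order), or a JSONL / CSV file with ``note_id`` and
        ``text`` fields.  Input order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"notes path does not exist: {path}")
    notes: list[ClinicalNote] = []
    if format == "txt_dir":
        for f in sorted(path.glob("*.txt")):
            notes.append(ClinicalNote(note_id=f.stem, text=_read_text(f)))
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                notes.append(ClinicalNote(str(rec["note_id"]), str(rec["text"])))
    elif format == "csv":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for rec in df.itertuples(index=False):
            notes.append(ClinicalNote(str(rec.note_id), str(rec.text)))
    else:
        raise ValueError(f"unknown notes format: {format!r}")
    _check_unique([n.note_id for n in notes], "notes")
    for n in notes:
        if not n.text.strip():
            logger.warning("note %r has empty text; retained", n.note_id)
    return notes


_TRUE = {"1", "true", "yes", "y", "fall"}
_FALSE = {"0", "false", "no", "n", "no fall", "no_fall", "nofall"}


def _parse_bool(value: object, line_no: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable fall value {value!r} on line {line_no}")


def read_gold(path: str | Path, format: str = "csv") -> list[GoldLabel]:
    """Read gold-standard labels (``note_id`` + boolean ``fall``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gold path does not exist: {path}")
    labels: list[GoldLabel] = []
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=2):
                neg = row.get("negated_mention")
                labels.append(
                    GoldLabel(
                        note_id=str(row["note_id"]),
                        fall=_parse_bool(row["fall"], line_no),
                        negated_mention=(
                            _parse_bool(neg, line_no) if neg not in (None, "") else None
                        ),
                    )
                )
    elif format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                rec = json.loads(line)
                neg = rec.get("negated_mention")
                labels.append(
                    GoldLabel(
                        note_id=str(rec["note_id"]),
                        fall=_parse_bool(rec["fall"], line_no),
                        negated_mention=(
                            _parse_bool(neg, line_no) if neg is not None else None
                        ),
                    )
                )
    else:
        raise ValueError(f"unknown gold format: {format!r}")
    _check_unique([g.note_id for g in labels], "gold labels")
    return labels


_RESULT_COLUMNS = ["note_id", "label", "n_positive", "n_negated", "negated_mention"]


def write_results(
    records: Iterable[ResultRecord],
    path: str | Path,
    evidence_path: str | Path | None = None,
) -> None:
    """Write per-note results as CSV; optionally mention evidence as JSONL."""
    records = list(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESULT_COLUMNS)
        for r in records:
            writer.writerow(
                [r.note_id, r.label.value, r.n_positive, r.n_negated,
                 str(bool(r.negated_mention)).lower()]
            )
    if evidence_path is not None:
        with open(evidence_path, "w", encoding="utf-8") as fh:
            for r in records:
                for m in r.mentions:
                    rec = m if isinstance(m, dict) else m.to_dict()
                    fh.write(json.dumps(rec) + "\n")


def read_results(path: str | Path) -> list[ResultRecord]:
    """Read back a results CSV written by :func:`write_results`."""
    out: list[ResultRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ResultRecord(
                    note_id=row["note_id"],
                    label=Label(row["label"]),
                    n_positive=int(row["n_positive"]),
                    n_negated=int(row["n_negated"]),
                    negated_mention=row["negated_mention"].lower() == "true",
                )
            )
    _check_unique([r.note_id for r in out], "results")
    return out
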
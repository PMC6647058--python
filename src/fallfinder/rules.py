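"""Ruleset configuration: fall-term pattern, exceptions, negation cues, sections.

Every behavioral knob of the pipeline lives in a :class:`RuleSet`, normally
loaded from a YAML file so a site can extend the exception lists without
touching code.  Two rulesets ship with the package:

``published``
    Reproduces the validated algorithm exactly, including its documented
    blind spots (season written as "fall 2016", the idiom "fell apart",
    the FOOSH acronym, the "PMH:" header abbreviation).
``extended``
    Adds the fixes for the error sources the validation study itself
    identified as fixable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = ["RuleSet", "load_ruleset", "dump_ruleset", "EXCLUSION_CLASSES"]

#: Exception classes a fall term may be excluded under, in cascade order.
EXCLUSION_CLASSES = ("exception", "uncertain", "averted", "risk", "season")

TIE_BREAKS = ("negated_wins", "positive_wins")


@dataclass(frozen=True)
class RuleSet:
    """Complete configuration of the fall-identification pipeline."""

    fall_pattern: str
    exceptions: dict[str, tuple[str, ...]]
    keep_phrases: tuple[str, ...] = ()
    negation_cues: tuple[str, ...] = ()
    negation_case_sensitive: bool = False
    tie_break: str = "negated_wins"
    section_remove: tuple[str, ...] = ()
    section_known: tuple[str, ...] = ()
    abbreviations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        unknown = set(self.exceptions) - set(EXCLUSION_CLASSES)
        if unknown:
            raise ValueError(f"unknown exception classes: {sorted(unknown)}")
        if self.tie_break not in TIE_BREAKS:
            raise ValueError(
                f"tie_break must be one of {TIE_BREAKS}, got {self.tie_break!r}"
            )
        # fail fast on malformed regexes
        re.compile(self.fall_pattern, re.IGNORECASE)
        for pats in self.exceptions.values():
            for p in pats:
                re.compile(p, re.IGNORECASE)

    # -- compiled views -------------------------------------------------

    @property
    def fall_regex(self) -> re.Pattern[str]:
        return re.compile(self.fall_pattern, re.IGNORECASE)

    def exception_regexes(self) -> list[tuple[str, re.Pattern[str]]]:
        """(class, compiled pattern) pairs in deterministic cascade order."""
        out: list[tuple[str, re.Pattern[str]]] = []
        for cls in EXCLUSION_CLASSES:
            for pat in self.exceptions.get(cls, ()):
                out.append((cls, re.compile(pat, re.IGNORECASE)))
        return out

    def with_tie_break(self, tie_break: str) -> "RuleSet":
        return replace(self, tie_break=tie_break)

    def with_negation_case_sensitive(self, flag: bool) -> "RuleSet":
        return replace(self, negation_case_sensitive=flag)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fall_pattern": self.fall_pattern,
            "exceptions": {cls: list(pats) for cls, pats in self.exceptions.items()},
            "keep_phrases": list(self.keep_phrases),
            "negation": {
                "cues": list(self.negation_cues),
                "case_sensitive": self.negation_case_sensitive,
            },
            "aggregation": {"tie_break": self.tie_break},
            "sections": {
                "remove": list(self.section_remove),
                "known": list(self.section_known),
            },
            "sentences": {"abbreviations": list(self.abbreviations)},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "RuleSet":
        negation = data.get("negation", {})
        sections = data.get("sections", {})
        sentences = data.get("sentences", {})
        return cls(
            fall_pattern=data["fall_pattern"],
            exceptions={
                c: tuple(p)
                for c, p in (data.get("exceptions") or {}).items()
            },
            keep_phrases=tuple(data.get("keep_phrases") or ()),
            negation_cues=tuple(negation.get("cues") or ()),
            negation_case_sensitive=bool(negation.get("case_sensitive", False)),
            tie_break=(data.get("aggregation") or {}).get("tie_break", "negated_wins"),
            section_remove=tuple(sections.get("remove") or ()),
            section_known=tuple(sections.get("known") or ()),
            abbreviations=tuple(
                str(a).lower() for a in (sentences.get("abbreviations") or ())
            ),
        )


def load_ruleset(source: str | Path = "published") -> RuleSet:
    """Load a ruleset from a YAML file or by bundled name.

    ``source`` may be ``"published"`` or ``"extended"`` (the bundled
    rulesets) or a path to a YAML file with the same schema.
    """
    name = str(source)
    if name in ("published", "extended"):
        text = (
            resources.files("fallfinder.rulesets")
            .joinpath(f"{name}.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"ruleset not found: {source}")
        text = path.read_text(encoding="utf-8")
    return RuleSet.from_dict(yaml.safe_load(text))


def dump_ruleset(rules: RuleSet, path: str | Path) -> None:
    """Serialize a ruleset to YAML; ``load_ruleset`` round-trips it."""
    Path(path).write_text(
        yaml.safe_dump(rules.to_dict(), sort_keys=False, allow_unicode=True),
        encoding="utf-8",
    )
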
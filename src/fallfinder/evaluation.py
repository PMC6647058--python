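"""Diagnostic accuracy statistics with exact confidence intervals.

Verdicts are compared to gold-standard consensus labels at the note
level; notes whose only fall mentions are negated belong to the no-fall
group on both sides.  Point estimates are the usual 2×2 ratios; interval
estimates are exact Clopper–Pearson binomial intervals from beta-quantile
inversion (Wilson score intervals are available behind a flag).  Cohen's
kappa is provided for inter-rater agreement on a 2×2 table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import beta, norm

from .corpus_io import GoldLabel, Label
from .note_classifier import NoteClassification

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "MetricsReport",
    "build_confusion",
    "compute_metrics",
    "exact_binomial_ci",
    "wilson_ci",
    "cohen_kappa",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 comparison of pipeline verdicts against gold labels.

    tp: pipeline FALL, gold fall; fp: pipeline FALL, gold no-fall;
    fn: pipeline NO_FALL, gold fall; tn: pipeline NO_FALL, gold no-fall.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Estimate:
    """A proportion with its denominator and confidence interval.

    ``value`` is ``None`` when the denominator is zero — undefined, never
    silently 0 or 1.
    """

    value: float | None
    ci: tuple[float, float] | None
    numerator: int
    denominator: int

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_lower": self.ci[0] if self.ci else None,
            "ci_upper": self.ci[1] if self.ci else None,
            "numerator": self.numerator,
            "denominator": self.denominator,
        }


@dataclass(frozen=True)
class MetricsReport:
    """The full panel of note-level diagnostic accuracy metrics."""

    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    f1: float | None
    misclassified: int
    prevalence_gold: float
    prevalence_pred: float
    confusion: ConfusionMatrix
    ci_level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.to_dict(),
            "specificity": self.specificity.to_dict(),
            "ppv": self.ppv.to_dict(),
            "npv": self.npv.to_dict(),
            "accuracy": self.accuracy.to_dict(),
            "f1": self.f1,
            "misclassified": self.misclassified,
            "prevalence_gold": self.prevalence_gold,
            "prevalence_pred": self.prevalence_pred,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
                "tn": self.confusion.tn,
            },
            "ci_level": self.ci_level,
        }

    def summary(self) -> str:
        """Human-readable table, percentages to 1 decimal, F1 to 3."""

        def fmt(e: Estimate) -> str:
            if e.value is None:
                return "undefined"
            s = f"{100 * e.value:5.1f}%"
            if e.ci is not None:
                s += f"  (95%CI {100 * e.ci[0]:.1f}-{100 * e.ci[1]:.1f})"
            return s

        lines = [
            f"{'Sensitivity (Recall)':<22}{fmt(self.sensitivity)}",
            f"{'Specificity':<22}{fmt(self.specificity)}",
            f"{'PPV (Precision)':<22}{fmt(self.ppv)}",
            f"{'NPV':<22}{fmt(self.npv)}",
            f"{'Accuracy':<22}{fmt(self.accuracy)}",
            f"{'F1 Score':<22}"
            + (f"{self.f1:.3f}" if self.f1 is not None else "undefined"),
            f"{'Misclassified':<22}{self.misclassified} of {self.confusion.total}",
        ]
        return "\n".join(lines)


def build_confusion(
    pred: list[NoteClassification], gold: list[GoldLabel]
) -> ConfusionMatrix:
    """Pair pipeline verdicts with gold labels into a 2×2 table.

    The note-id sets must match exactly; mismatches are fatal and name
    the offending ids.
    """
    pred_by_id = {p.note_id: p for p in pred}
    gold_by_id = {g.note_id: g for g in gold}
    if len(pred_by_id) != len(pred):
        raise ValueError("duplicate note_id in predictions")
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate note_id in gold labels")
    only_pred = sorted(set(pred_by_id) - set(gold_by_id))
    only_gold = sorted(set(gold_by_id) - set(pred_by_id))
    if only_pred or only_gold:
        raise ValueError(
            f"note_id mismatch: only in predictions {only_pred[:10]}, "
            f"only in gold {only_gold[:10]}"
        )
    tp = fp = fn = tn = 0
    for nid, p in pred_by_id.items():
        is_fall = p.label is Label.FALL
        g = gold_by_id[nid].fall
        if is_fall and g:
            tp += 1
        elif is_fall and not g:
            fp += 1
        elif not is_fall and g:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def exact_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval via beta quantiles.

    The lower bound is exactly 0 when ``successes == 0`` and the upper
    bound exactly 1 when ``successes == n``.
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"invalid confidence level: {level}")
    alpha = 1.0 - level
    lower = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes, n - successes + 1))
    upper = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lower, upper


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval (closed form), offered as an alternative."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    z = float(norm.ppf(1 - (1 - level) / 2))
    p = successes / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def _estimate(
    num: int, den: int, level: float, ci_method: str
) -> Estimate:
    if den == 0:
        return Estimate(value=None, ci=None, numerator=num, denominator=den)
    ci_fn = wilson_ci if ci_method == "wilson" else exact_binomial_ci
    return Estimate(value=num / den, ci=ci_fn(num, den, level), numerator=num, denominator=den)


def compute_metrics(
    cm: ConfusionMatrix, ci_level: float = 0.95, ci_method: str = "clopper-pearson"
) -> MetricsReport:
    """Compute the full metrics panel from a confusion matrix.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), ppv = tp/(tp+fp),
    npv = tn/(tn+fn), accuracy = (tp+tn)/N, F1 = 2·ppv·sens/(ppv+sens).
    Any metric with a zero denominator is reported as undefined.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if ci_method not in ("clopper-pearson", "wilson"):
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    sens = _estimate(cm.tp, cm.tp + cm.fn, ci_level, ci_method)
    spec = _estimate(cm.tn, cm.tn + cm.fp, ci_level, ci_method)
    ppv = _estimate(cm.tp, cm.tp + cm.fp, ci_level, ci_method)
    npv = _estimate(cm.tn, cm.tn + cm.fn, ci_level, ci_method)
    acc = _estimate(cm.tp + cm.tn, cm.total, ci_level, ci_method)
    if sens.value is not None and ppv.value is not None and (ppv.value + sens.value) > 0:
        f1 = 2 * ppv.value * sens.value / (ppv.value + sens.value)
    else:
        f1 = None
    return MetricsReport(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        f1=f1,
        misclassified=cm.fp + cm.fn,
        prevalence_gold=(cm.tp + cm.fn) / cm.total,
        prevalence_pred=(cm.tp + cm.fp) / cm.total,
        confusion=cm,
        ci_level=ci_level,
    )


def cohen_kappa(table: list[list[int]] | tuple) -> tuple[float | None, float]:
    """Cohen's kappa and raw agreement for a 2×2 rater-agreement table.

    ``table[i][j]`` counts items rated category ``i`` by rater A and
    ``j`` by rater B.  kappa = (p_o − p_e)/(1 − p_e), with chance
    agreement p_e from the marginal products; ``None`` when p_e == 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("agreement counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("agreement table must contain at least one item")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if math.isclose(p_e, 1.0):
        return None, p_o
    return (p_o - p_e) / (1 - p_e), p_o
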
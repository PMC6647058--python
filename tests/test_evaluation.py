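import numpy as np
import pytest

from fallfinder.corpus_io import GoldLabel, Label
from fallfinder.evaluation import (
    ConfusionMatrix,
    build_confusion,
    cohen_kappa,
    compute_metrics,
    exact_binomial_ci,
    wilson_ci,
)
from fallfinder.note_classifier import NoteClassification


def _cls(note_id, label):
    return NoteClassification(
        note_id=note_id, n_positive=int(label is Label.FALL), n_negated=0,
        n_excluded={}, label=label, negated_mention=False,
    )


def paired(tp, fp, fn, tn):
    pred, gold = [], []
    i = 0
    for count, p_fall, g_fall in [
        (tp, True, True), (fp, True, False), (fn, False, True), (tn, False, False),
    ]:
        for _ in range(count):
            nid = f"n{i}"
            pred.append(_cls(nid, Label.FALL if p_fall else Label.NO_FALL))
            gold.append(GoldLabel(nid, g_fall))
            i += 1
    return pred, gold


class TestBuildConfusion:
    def test_counts_from_paired_labels(self):
        cm = build_confusion(*paired(115, 10, 5, 370))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (115, 10, 5, 370)
        assert cm.total == 500

    def test_all_agree(self):
        cm = build_confusion(*paired(3, 0, 0, 0))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (3, 0, 0, 0)

    def test_id_mismatch_names_offender(self):
        pred, gold = paired(1, 0, 0, 1)
        pred.append(_cls("extra", Label.FALL))
        with pytest.raises(ValueError, match="extra"):
            build_confusion(pred, gold)


class TestComputeMetrics:
    def test_published_counts(self):
        """The 2x2 test-set table must reproduce every headline metric at its
        printed precision."""
        r = compute_metrics(ConfusionMatrix(115, 10, 5, 370))
        assert round(100 * r.sensitivity.value, 1) == 95.8
        assert round(100 * r.specificity.value, 1) == 97.4
        assert round(100 * r.ppv.value, 1) == 92.0
        assert round(100 * r.npv.value, 1) == 98.7
        assert round(100 * r.accuracy.value, 1) == 97.0
        assert round(r.f1, 3) == 0.939
        assert r.misclassified == 15
        assert round(100 * r.prevalence_gold, 1) == 24.0
        assert round(100 * r.prevalence_pred, 1) == 25.0

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionMatrix(10, 0, 0, 10))
        assert (r.sensitivity.value, r.specificity.value, r.ppv.value,
                r.npv.value, r.accuracy.value, r.f1) == (1, 1, 1, 1, 1, 1)

    def test_degenerate_metrics_undefined_not_zero(self):
        r = compute_metrics(ConfusionMatrix(0, 0, 0, 10))
        assert r.sensitivity.value is None and r.ppv.value is None
        assert r.specificity.value == 1.0
        assert r.f1 is None
        assert "undefined" in r.summary()

    def test_all_zero_matrix_fatal(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_matches_sklearn_on_random_matrices(self):
        """Point estimates agree with scikit-learn to 1e-12 on 100 random
        confusion matrices."""
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        rng = np.random.default_rng(20240917)
        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 200, size=4))
            r = compute_metrics(ConfusionMatrix(tp, fp, fn, tn))
            y_true = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            y_pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
            assert r.sensitivity.value == pytest.approx(
                recall_score(y_true, y_pred), abs=1e-12)
            assert r.ppv.value == pytest.approx(
                precision_score(y_true, y_pred), abs=1e-12)
            assert r.accuracy.value == pytest.approx(
                accuracy_score(y_true, y_pred), abs=1e-12)
            assert r.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)
            assert r.specificity.value == pytest.approx(
                recall_score(y_true, y_pred, pos_label=0), abs=1e-12)


class TestExactBinomialCI:
    def test_published_sensitivity_interval(self):
        lo, hi = exact_binomial_ci(115, 120, 0.95)
        assert (round(lo, 3), round(hi, 3)) == (0.905, 0.986)

    def test_boundaries_exact(self):
        assert exact_binomial_ci(0, 50, 0.95)[0] == 0.0
        assert exact_binomial_ci(50, 50, 0.95)[1] == 1.0

    def test_invalid_counts_fatal(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4, 0.95)
        with pytest.raises(ValueError):
            exact_binomial_ci(-1, 4, 0.95)

    def test_ci_nesting(self):
        """The 90% interval is contained in the 95% interval."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 300))
            k = int(rng.integers(0, n + 1))
            lo90, hi90 = exact_binomial_ci(k, n, 0.90)
            lo95, hi95 = exact_binomial_ci(k, n, 0.95)
            assert lo95 <= lo90 and hi90 <= hi95

    def test_matches_statsmodels_to_1e12(self):
        from statsmodels.stats.proportion import proportion_confint

        rng = np.random.default_rng(41)
        for _ in range(100):
            n = int(rng.integers(1, 500))
            k = int(rng.integers(0, n + 1))
            lo, hi = exact_binomial_ci(k, n, 0.95)
            ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="beta")
            ref_lo = 0.0 if k == 0 else ref_lo
            ref_hi = 1.0 if k == n else ref_hi
            assert lo == pytest.approx(ref_lo, abs=1e-12)
            assert hi == pytest.approx(ref_hi, abs=1e-12)
            wlo, whi = wilson_ci(k, n, 0.95)
            rlo, rhi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert wlo == pytest.approx(rlo, abs=1e-12)
            assert whi == pytest.approx(rhi, abs=1e-12)

    def test_coverage_sanity(self):
        """On seeded Bernoulli replicates (n=120, p=0.958) the 95% interval
        covers p at least 95% of the time, within Monte-Carlo error."""
        rng = np.random.default_rng(958)
        n, p, reps = 120, 0.958, 2000
        ks = rng.binomial(n, p, size=reps)
        covered = 0
        for k in np.unique(ks):
            lo, hi = exact_binomial_ci(int(k), n, 0.95)
            if lo <= p <= hi:
                covered += int(np.sum(ks == k))
        mc_err = 3 * np.sqrt(0.95 * 0.05 / reps)
        assert covered / reps >= 0.95 - mc_err


class TestCohenKappa:
    def test_perfect_agreement(self):
        kappa, po = cohen_kappa([[30, 0], [0, 70]])
        assert kappa == pytest.approx(1.0) and po == 1.0

    def test_chance_agreement(self):
        kappa, po = cohen_kappa([[25, 25], [25, 25]])
        assert kappa == pytest.approx(0.0) and po == 0.5

    def test_hand_computed_table(self):
        # p_o = 85/100, p_e = (50*45 + 50*55)/100^2 = 0.5
        # kappa = (0.85 - 0.5)/(1 - 0.5) = 0.7
        kappa, po = cohen_kappa([[40, 10], [5, 45]])
        assert kappa == pytest.approx(0.7)
        assert po == pytest.approx(0.85)

    def test_degenerate_chance_one(self):
        kappa, po = cohen_kappa([[10, 0], [0, 0]])
        assert kappa is None and po == 1.0

    def test_empty_table_fatal(self):
        with pytest.raises(ValueError):
            cohen_kappa([[0, 0], [0, 0]])

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, size=4))
            kappa, _ = cohen_kappa([[a, b], [c, d]])
            ra = [0] * (a + b) + [1] * (c + d)
            rb = [0] * a + [1] * b + [0] * c + [1] * d
            assert kappa == pytest.approx(cohen_kappa_score(ra, rb), abs=1e-12)
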
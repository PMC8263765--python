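"""Diagnostic metrics, ROC-AUC, and rank concordance."""

import itertools

import numpy as np
import pytest

from methylnode.classification import BENIGN, MALIGNANT
from methylnode.errors import DegenerateInputError, InvalidArgumentError
from methylnode.evaluation import (
    ConfusionCounts,
    confusion,
    diagnostic_metrics,
    empirical_auc,
    roc_auc,
    spearman_concordance,
)


class TestConfusion:
    def test_all_correct(self):
        calls = [MALIGNANT, BENIGN, MALIGNANT]
        c = confusion(calls, calls)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (2, 1)

    def test_hand_tallied_six_samples(self):
        calls = [MALIGNANT, MALIGNANT, BENIGN, BENIGN, MALIGNANT, BENIGN]
        truth = [MALIGNANT, BENIGN, MALIGNANT, BENIGN, MALIGNANT, BENIGN]
        c = confusion(calls, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 2)
        assert c.total == 6

    def test_length_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            confusion([MALIGNANT], [MALIGNANT, BENIGN])

    def test_counts_partition_cohort(self, demo_study):
        meta = demo_study["cohort"].metadata
        calls = meta["cytology"].replace("indeterminate", BENIGN).tolist()
        c = confusion(calls, meta["histology"].tolist())
        assert c.total == len(meta)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ConfusionCounts(-1, 0, 0, 0)


class TestDiagnosticMetrics:
    def test_prospective_study_counts(self):
        """Counts reconstructed from the printed cohort sizes and accuracy:
        108 malignant (sens 90.7% -> TP 98) and 110 benign (spec 99.1% ->
        TN 109) give PPV 99.0% and NPV 91.6%."""
        report = diagnostic_metrics(ConfusionCounts(tp=98, fp=1, fn=10, tn=109))
        assert round(report.sensitivity.percent, 1) == 90.7
        assert round(report.specificity.percent, 1) == 99.1
        assert round(report.ppv.percent, 1) == 99.0
        assert round(report.npv.percent, 1) == 91.6

    def test_perfect_classifier(self):
        report = diagnostic_metrics(ConfusionCounts(50, 0, 0, 50))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            assert getattr(report, name).percent == 100.0

    def test_matches_ratio_formulas(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 200, size=4)
            r = diagnostic_metrics(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            assert r.sensitivity.percent == pytest.approx(100 * tp / (tp + fn), abs=1e-12)
            assert r.specificity.percent == pytest.approx(100 * tn / (tn + fp), abs=1e-12)
            assert r.ppv.percent == pytest.approx(100 * tp / (tp + fp), abs=1e-12)
            assert r.npv.percent == pytest.approx(100 * tn / (tn + fn), abs=1e-12)

    def test_zero_denominator_flags_only_that_metric(self):
        report = diagnostic_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert not report.sensitivity.defined
        assert not report.ppv.defined
        assert report.specificity.defined and report.specificity.percent == 100.0

    def test_exact_ci_reproduces_cytology_interval(self):
        """Clopper-Pearson on 98/106 approximately reproduces the cytology
        sensitivity interval 85.6-96.6 reported for the prospective study."""
        report = diagnostic_metrics(ConfusionCounts(tp=98, fp=0, fn=8, tn=0))
        assert report.sensitivity.ci_low == pytest.approx(85.6, abs=0.15)
        assert report.sensitivity.ci_high == pytest.approx(96.6, abs=0.15)

    def test_ci_brackets_point_estimate(self):
        report = diagnostic_metrics(ConfusionCounts(90, 5, 10, 95))
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            p = getattr(report, name)
            assert p.ci_low <= p.percent <= p.ci_high

    def test_pooled_counts_equal_summed_strata(self):
        a = ConfusionCounts(10, 2, 3, 15)
        b = ConfusionCounts(7, 1, 4, 20)
        pooled = diagnostic_metrics(a + b)
        direct = diagnostic_metrics(ConfusionCounts(17, 3, 7, 35))
        assert pooled.sensitivity.percent == direct.sensitivity.percent
        assert pooled.npv.percent == direct.npv.percent


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([1, 2, 3, 10, 11], [BENIGN] * 3 + [MALIGNANT] * 2)
        assert auc == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = [MALIGNANT if u < 0.5 else BENIGN for u in rng.random(2000)]
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_all_pairs_enumeration_oracle(self):
        scores = [1.0, 3.0, 2.5, 2.5, 4.0, 0.5]
        labels = [MALIGNANT, MALIGNANT, MALIGNANT, BENIGN, BENIGN, BENIGN]
        pos = [s for s, l in zip(scores, labels) if l == MALIGNANT]
        neg = [s for s, l in zip(scores, labels) if l == BENIGN]
        u = sum(
            1.0 if p > n else 0.5 if p == n else 0.0
            for p, n in itertools.product(pos, neg)
        )
        assert empirical_auc(scores, labels) == pytest.approx(u / (len(pos) * len(neg)))

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 2], [MALIGNANT, MALIGNANT])

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0, 100, 60)
        labels = [MALIGNANT if s + rng.normal(0, 20) > 50 else BENIGN for s in scores]
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        a1 = empirical_auc(scores, labels)
        a2 = empirical_auc(np.sqrt(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_against_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        y = (rng.random(100) < 0.4).astype(int)
        if y.sum() in (0, 100):
            pytest.skip("degenerate draw")
        assert empirical_auc(scores, y) == pytest.approx(
            sklearn.roc_auc_score(y, scores), abs=1e-12
        )

    def test_delong_ci_brackets_and_shrinks(self):
        rng = np.random.default_rng(3)
        small = rng.normal(0, 1, 40) + np.repeat([0, 1.5], 20)
        labels_small = [BENIGN] * 20 + [MALIGNANT] * 20
        big = rng.normal(0, 1, 400) + np.repeat([0, 1.5], 200)
        labels_big = [BENIGN] * 200 + [MALIGNANT] * 200
        auc_s, (lo_s, hi_s) = roc_auc(small, labels_small)
        auc_b, (lo_b, hi_b) = roc_auc(big, labels_big)
        assert lo_s <= auc_s <= hi_s
        assert (hi_b - lo_b) < (hi_s - lo_s)

    def test_bootstrap_ci_agrees_with_delong(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 200) + np.repeat([0.0, 1.2], 100)
        labels = [BENIGN] * 100 + [MALIGNANT] * 100
        _, (dlo, dhi) = roc_auc(scores, labels, method="delong")
        _, (blo, bhi) = roc_auc(scores, labels, method="bootstrap", seed=0)
        assert dlo == pytest.approx(blo, abs=0.05)
        assert dhi == pytest.approx(bhi, abs=0.05)


class TestSpearman:
    def test_identical_vectors(self):
        assert spearman_concordance([1, 2, 3], [1, 2, 3]).spearman_r == pytest.approx(1.0)

    def test_reversed_vectors(self):
        assert spearman_concordance([1, 2, 3, 4], [4, 3, 2, 1]).spearman_r == pytest.approx(-1.0)

    def test_tied_vector_matches_hand_rank_formula(self):
        x = [10.0, 20.0, 20.0, 30.0, 40.0]  # average ranks: 1, 2.5, 2.5, 4, 5
        y = [1.0, 2.0, 4.0, 3.0, 5.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ry = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_concordance(x, y).spearman_r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        result = spearman_concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not result.defined

    def test_length_preconditions(self):
        with pytest.raises(InvalidArgumentError):
            spearman_concordance([1, 2], [1, 2])
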
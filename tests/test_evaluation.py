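"""Metric oracles, aggregation, gap statistics and the deployment report."""

import numpy as np
import pytest
from sklearn.metrics import roc_curve

from fogbench.evaluation import (
    FoldMetrics,
    aggregate,
    auc_score,
    deployment_report,
    gap_percent,
    paired_comparison,
    sd_fold_difference,
    tier,
    welch_comparison,
    window_metrics,
)


def fm(subject, f1, n=10, n_pos=5, auc=0.5):
    """Consistent FoldMetrics helper: precision = sensitivity = f1."""
    return FoldMetrics(
        subject_id=subject, auc=auc, f1=f1, precision=f1, sensitivity=f1,
        accuracy=f1, n_windows=n, n_positive=n_pos,
    )


class TestWindowMetrics:
    def test_perfect_scores_give_perfect_metrics(self):
        m = window_metrics(np.array([0, 1, 0, 1]), np.array([0.1, 0.9, 0.2, 0.8]))
        assert (m.auc, m.f1, m.precision, m.sensitivity, m.accuracy) == (1, 1, 1, 1, 1)

    def test_all_positive_predictor_collapse_signature(self):
        y = np.array([1, 0, 0, 0, 0])
        m = window_metrics(y, np.array([0.9, 0.9, 0.9, 0.9, 0.9]))
        assert m.precision == pytest.approx(0.2)
        assert m.sensitivity == 1.0
        assert m.f1 == pytest.approx(1 / 3)
        assert m.accuracy == pytest.approx(0.2)

    def test_auc_by_concordant_pair_counting(self):
        m = window_metrics(
            np.array([0, 0, 1, 1]), np.array([0.1, 0.4, 0.35, 0.8])
        )
        assert m.auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="single class"):
            window_metrics(np.ones(4, dtype=int), np.full(4, 0.9))

    def test_no_predicted_positives_flagged_not_dropped(self):
        m = window_metrics(np.array([1, 0, 1, 0]), np.array([0.1, 0.2, 0.3, 0.1]))
        assert m.precision == 0.0
        assert m.degenerate_precision

    def test_f1_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            FoldMetrics("x", 0.5, 0.9, 0.5, 0.5, 0.5, 10, 5)


class TestAUCOracle:
    def test_rank_form_equals_trapezoidal_roc_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            s = np.round(rng.random(n), 2)  # coarse scores exercise ties
            fpr, tpr, _ = roc_curve(y, s)
            assert abs(auc_score(y, s) - np.trapezoid(tpr, fpr)) <= 1e-9

    @pytest.mark.parametrize("prevalence", [0.1, 0.179, 0.5])
    def test_all_positive_predictor_closed_forms(self, prevalence):
        n = 1000
        n_pos = int(round(n * prevalence))
        y = np.r_[np.ones(n_pos, dtype=int), np.zeros(n - n_pos, dtype=int)]
        scores = np.full(n, 0.9)
        m = window_metrics(y, scores)
        pi = n_pos / n
        assert m.precision == pytest.approx(pi)
        assert m.sensitivity == 1.0
        assert m.f1 == pytest.approx(2 * pi / (1 + pi))


class TestAggregate:
    def test_identical_folds_have_zero_sd(self):
        agg = aggregate([fm("a", 0.5), fm("b", 0.5)])
        assert agg["f1"] == (0.5, 0.0)

    def test_mean_and_sample_sd(self):
        agg = aggregate([fm("a", 0.4), fm("b", 0.6)])
        assert agg["f1"][0] == pytest.approx(0.5)
        assert agg["f1"][1] == pytest.approx(0.14142, abs=1e-4)

    def test_order_invariance(self):
        folds = [fm("a", 0.2), fm("b", 0.7), fm("c", 0.5)]
        fwd, rev = aggregate(folds), aggregate(folds[::-1])
        for name in fwd:
            assert fwd[name] == pytest.approx(rev[name], abs=1e-12)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            aggregate([fm("a", 0.5)])


class TestGapStatistics:
    @pytest.mark.parametrize(
        "lab, dl, expected",
        [(1.00, 0.77, 30), (0.9999, 0.51, 96), (0.9999, 0.67, 49), (0.5, 0.5, 0)],
    )
    def test_gap_percent_reproduces_reference_integers(self, lab, dl, expected):
        assert round(gap_percent(lab, dl)) == expected

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            gap_percent(1.0, 0.0)

    @pytest.mark.parametrize(
        "sd_dl, sd_lab, expected",
        [(0.26, 0.0002, 1300), (0.28, 0.0003, 933), (0.1, 0.1, 1)],
    )
    def test_sd_fold_difference_reproduces_reference_integers(
        self, sd_dl, sd_lab, expected
    ):
        assert round(sd_fold_difference(sd_dl, sd_lab)) == expected

    def test_zero_laboratory_sd_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            sd_fold_difference(0.14, 0.0)


class TestPairedComparison:
    def test_identical_arrays_are_null(self):
        r = paired_comparison(np.array([0.4, 0.5, 0.6]), np.array([0.4, 0.5, 0.6]))
        assert (r.t, r.p_raw, r.cohens_d) == (0.0, 1.0, 0.0)

    def test_constant_nonzero_difference_overflows(self):
        r = paired_comparison(np.array([1.0, 1, 1, 1]), np.zeros(4))
        assert r.overflow and np.isinf(r.t)

    def test_matches_textbook_formula(self):
        a = np.array([0.5, 0.8, 0.6])
        b = np.array([0.4, 0.5, 0.4])
        d = a - b  # [0.1, 0.3, 0.2]
        r = paired_comparison(a, b, n_comparisons=3)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert r.t == pytest.approx(expected_t, rel=1e-9)
        assert r.df == 2
        assert r.p_adjusted == pytest.approx(min(1.0, r.p_raw * 3))
        assert r.cohens_d == pytest.approx(d.mean() / d.std(ddof=1), rel=1e-9)


class TestWelchComparison:
    def test_identical_samples_give_zero_t(self):
        r = welch_comparison(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert r.t == 0.0

    def test_separated_samples_are_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-3, 6)
        b = 1 + rng.normal(0, 1e-3, 6)
        r = welch_comparison(a, b)
        assert abs(r.t) > 100 and r.p < 0.001

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 10)
        r = welch_comparison(a, b)
        va, vb = a.var(ddof=1) / 10, b.var(ddof=1) / 10
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 9 + vb**2 / 9)
        assert r.t == pytest.approx(t, rel=1e-9)
        assert r.df == pytest.approx(df, rel=1e-9)

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            welch_comparison(np.array([1.0]), np.array([1.0, 2.0]))


class TestTier:
    @pytest.mark.parametrize(
        "f1, expected",
        [(0.75, "excellent"), (0.70, "excellent"), (0.69, "moderate"),
         (0.50, "moderate"), (0.49, "poor"), (0.0, "poor")],
    )
    def test_thresholds(self, f1, expected):
        assert tier(f1) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tier(1.2)


class TestDeploymentReport:
    def _folds(self, values):
        return [fm(f"s{i}", v) for i, v in enumerate(values)]

    def test_identical_fold_lists_are_null_comparison(self):
        folds = self._folds([0.4, 0.6, 0.5])
        rep = deployment_report(folds, folds)
        assert all(abs(g) < 1e-9 for g in rep.gap_percent.values())
        assert rep.sd_fold_difference["f1"] == pytest.approx(1.0)

    def test_f1_gap_from_means(self):
        rep = deployment_report(
            self._folds([1.0, 1.0, 1.0]), self._folds([0.5, 0.5, 0.5])
        )
        assert rep.gap_percent["f1"] == pytest.approx(100.0)
        # zero SD on both arms: ratio undefined, rendered as an em dash
        assert rep.sd_fold_difference["f1"] is None
        assert "—" in rep.to_markdown()

    def test_tier_counts_cover_all_daily_living_folds(self):
        dl = self._folds([0.8, 0.75, 0.6, 0.3, 0.1])
        rep = deployment_report(self._folds([0.9, 0.95, 0.99]), dl)
        assert rep.tier_counts == {"excellent": 2, "moderate": 1, "poor": 2}
        assert sum(rep.tier_counts.values()) == len(dl)

    def test_report_internally_consistent(self):
        lab = self._folds([0.9, 0.92, 0.95])
        dl = self._folds([0.5, 0.3, 0.7])
        rep = deployment_report(lab, dl)
        assert rep.gap_percent["f1"] == pytest.approx(
            gap_percent(rep.lab["f1"][0], rep.daily_living["f1"][0])
        )
        assert rep.sd_fold_difference["f1"] == pytest.approx(
            rep.daily_living["f1"][1] / rep.lab["f1"][1]
        )
        json_text = rep.to_json()
        assert "gap_percent" in json_text
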
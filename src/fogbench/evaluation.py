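"""Window-level metrics, cross-fold aggregation and deployment-gap statistics.

Metrics follow the standard window-level FoG evaluation protocol: AUC
(rank / Mann-Whitney form, ties counting one half), F1, precision,
sensitivity and accuracy per held-out subject, aggregated as mean +/- sample
standard deviation across LOSO folds. The cross-regime comparison reports,
per metric, the relative gap ``(lab - daily_living) / daily_living * 100``
and the across-fold SD ratio ``daily_living / lab``, plus a Welch t-test
with Cohen's d on F1 and the excellent/moderate/poor performance tiers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FoldMetrics",
    "DeploymentReport",
    "PairedTestResult",
    "WelchTestResult",
    "window_metrics",
    "aggregate",
    "gap_percent",
    "sd_fold_difference",
    "paired_comparison",
    "welch_comparison",
    "tier",
    "deployment_report",
]

METRIC_NAMES = ("auc", "f1", "precision", "sensitivity", "accuracy")


@dataclass
class FoldMetrics:
    """Window-level metrics for one held-out subject."""

    subject_id: str
    auc: float
    f1: float
    precision: float
    sensitivity: float
    accuracy: float
    n_windows: int
    n_positive: int
    degenerate_precision: bool = False  # no predicted positives; precision set to 0

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        ps = self.precision + self.sensitivity
        expected_f1 = 0.0 if ps == 0 else 2 * self.precision * self.sensitivity / ps
        if abs(self.f1 - expected_f1) > 1e-9:
            raise ValueError(
                f"F1 {self.f1} inconsistent with precision/sensitivity "
                f"(harmonic mean {expected_f1})"
            )


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-form AUC: probability a random positive outranks a random negative.

    Ties contribute one half (Mann-Whitney convention).
    """
    y = np.asarray(y_true)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: y_true contains a single class")
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def window_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    threshold: float = 0.5,
    subject_id: str = "",
) -> FoldMetrics:
    """Confusion-matrix metrics plus rank-form AUC at a fixed threshold.

    Predictions are ``scores > threshold``. When no window is predicted
    positive, precision is reported as 0 with ``degenerate_precision=True``
    so fold aggregation never silently drops a fold.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    pred = (s > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    degenerate = (tp + fp) == 0
    precision = 0.0 if degenerate else tp / (tp + fp)
    sensitivity = 0.0 if (tp + fn) == 0 else tp / (tp + fn)
    f1 = (
        0.0
        if precision + sensitivity == 0
        else 2 * precision * sensitivity / (precision + sensitivity)
    )
    return FoldMetrics(
        subject_id=subject_id,
        auc=auc_score(y, s),
        f1=f1,
        precision=precision,
        sensitivity=sensitivity,
        accuracy=(tp + tn) / y.size,
        n_windows=int(y.size),
        n_positive=int(y.sum()),
        degenerate_precision=degenerate,
    )


def aggregate(folds: list[FoldMetrics]) -> dict[str, tuple[float, float]]:
    """Mean and sample (n-1) standard deviation per metric across folds."""
    if len(folds) < 2:
        raise ValueError("aggregate requires >= 2 folds for a standard deviation")
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def gap_percent(lab_value: float, dl_value: float) -> float:
    """Relative deployment gap: ``(lab - daily_living) / daily_living * 100``."""
    if dl_value <= 0:
        raise ValueError("daily-living value must be positive")
    return (lab_value - dl_value) / dl_value * 100.0


def sd_fold_difference(sd_dl: float, sd_lab: float) -> float:
    """Across-fold stability ratio ``sd_daily_living / sd_lab``.

    A zero laboratory SD leaves the ratio undefined; the report renders it
    as an em dash.
    """
    if sd_lab <= 0:
        raise ValueError("sd_fold_difference undefined for laboratory sd <= 0")
    return sd_dl / sd_lab


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float
    overflow: bool = False  # zero-variance nonzero-mean differences


def paired_comparison(
    metric_a: np.ndarray, metric_b: np.ndarray, n_comparisons: int = 1
) -> PairedTestResult:
    """Paired t-test on fold-wise differences with Bonferroni adjustment.

    Cohen's d uses the paired form: mean difference over the SD of the
    differences. Degenerate inputs follow the conventions: identical arrays
    give t = 0, p = 1, d = 0; zero-variance nonzero-mean differences are
    flagged as overflow.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_comparison requires equal-length arrays, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(0.0, n - 1, 1.0, 1.0, 0.0)
        return PairedTestResult(
            float(np.inf) if d.mean() > 0 else float(-np.inf),
            n - 1, 0.0, 0.0, float(np.inf), overflow=True,
        )
    res = stats.ttest_rel(a, b)
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return PairedTestResult(
        t=float(res.statistic),
        df=n - 1,
        p_raw=float(res.pvalue),
        p_adjusted=p_adj,
        cohens_d=float(d.mean() / sd),
    )


@dataclass
class WelchTestResult:
    t: float
    df: float
    p: float
    cohens_d: float


def welch_comparison(sample_a: np.ndarray, sample_b: np.ndarray) -> WelchTestResult:
    """Welch's unequal-variance t-test with pooled-SD Cohen's d."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_comparison requires n >= 2 in each sample")
    res = stats.ttest_ind(a, b, equal_var=False)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = 0.0 if pooled == 0 else float((a.mean() - b.mean()) / pooled)
    return WelchTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue), cohens_d=d
    )


def tier(f1: float) -> str:
    """Performance tier: excellent (>= 0.70), moderate (0.50-0.69), poor (< 0.50)."""
    if not 0.0 <= f1 <= 1.0:
        raise ValueError(f"f1 must be in [0, 1], got {f1}")
    if f1 >= 0.70:
        return "excellent"
    if f1 >= 0.50:
        return "moderate"
    return "poor"


@dataclass
class DeploymentReport:
    """Cross-regime aggregate comparison (lab vs daily living)."""

    lab: dict[str, tuple[float, float]]
    daily_living: dict[str, tuple[float, float]]
    gap_percent: dict[str, float]
    sd_fold_difference: dict[str, float | None]
    f1_welch: WelchTestResult
    tier_counts: dict[str, int]
    n_folds_lab: int = 0
    n_folds_daily_living: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_markdown(self) -> str:
        """Render the two comparison tables (metrics + stability)."""
        lines = [
            "| Metric | Daily living | Laboratory | Gap, % |",
            "| --- | --- | --- | --- |",
        ]
        for m in ("auc", "f1", "precision", "sensitivity"):
            dl_m, dl_s = self.daily_living[m]
            lab_m, lab_s = self.lab[m]
            lines.append(
                f"| {m.upper() if m == 'auc' else m.capitalize()} | "
                f"{dl_m:.2f} ± {dl_s:.2f} | {lab_m:.4f} ± {lab_s:.4f} | "
                f"{round(self.gap_percent[m])} |"
            )
        lines += [
            "",
            "| Metric | Daily living SD | Laboratory SD | Fold difference |",
            "| --- | --- | --- | --- |",
        ]
        for m in ("auc", "f1", "precision", "sensitivity"):
            ratio = self.sd_fold_difference[m]
            shown = "—" if ratio is None else f"{round(ratio)}"
            lines.append(
                f"| {m.upper() if m == 'auc' else m.capitalize()} | "
                f"{self.daily_living[m][1]:.4f} | {self.lab[m][1]:.4f} | {shown} |"
            )
        return "\n".join(lines)


def deployment_report(
    folds_lab: list[FoldMetrics], folds_dl: list[FoldMetrics]
) -> DeploymentReport:
    """Assemble the cross-regime comparison from two completed LOSO runs."""
    agg_lab = aggregate(folds_lab)
    agg_dl = aggregate(folds_dl)
    gaps = {m: gap_percent(agg_lab[m][0], agg_dl[m][0]) for m in METRIC_NAMES}
    ratios: dict[str, float | None] = {}
    for m in METRIC_NAMES:
        try:
            ratios[m] = sd_fold_difference(agg_dl[m][1], agg_lab[m][1])
        except ValueError:
            ratios[m] = None
    welch = welch_comparison(
        np.array([f.f1 for f in folds_lab]), np.array([f.f1 for f in folds_dl])
    )
    counts = {"excellent": 0, "moderate": 0, "poor": 0}
    for f in folds_dl:
        counts[tier(f.f1)] += 1
    return DeploymentReport(
        lab=agg_lab,
        daily_living=agg_dl,
        gap_percent=gaps,
        sd_fold_difference=ratios,
        f1_welch=welch,
        tier_counts=counts,
        n_folds_lab=len(folds_lab),
        n_folds_daily_living=len(folds_dl),
    )
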
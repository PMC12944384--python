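"""Training plans, early stopping and leave-one-subject-out orchestration.

Three named plans reproduce the benchmark's imbalance-handling arms:

========  =============  =======  ==============  =================
Plan      Early stopping  gamma   class weights    weighted sampling
========  =============  =======  ==============  =================
C         AUC             1.5     [0.18, 0.82]     yes
D         F1              1.0     [0.30, 0.70]     no
E         F1              1.2     [0.25, 0.75]     no
========  =============  =======  ==============  =================

All plans share the optimizer settings (Adam, learning rate 1e-3, weight
decay 1e-4, batch size 32, up to 200 epochs, patience 30, 10% stratified
validation split). ``make_plan`` accepts keyword overrides so scaled-down
experiments can shrink the epoch budget without touching the imbalance
stack. For high-prevalence (majority-freeze) cohorts the class weights of
plans C and D are reversed automatically when requested via
``weights_for_prevalence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from fogbench.cohort import SensorRecording
from fogbench.evaluation import FoldMetrics, auc_score, window_metrics
from fogbench.imbalance import ImbalanceConfig, make_sample_weights
from fogbench.preprocessing import (
    NormalizerStats,
    PreprocessConfig,
    WindowSet,
    apply_normalizer,
    concat_windowsets,
    fit_normalizer,
    preprocess_recording,
)
from fogbench.tcn import TCN, Adam, TCNSpec, build_model, focal_loss_batch

__all__ = [
    "TrainPlan",
    "TrainHistory",
    "make_plan",
    "weights_for_prevalence",
    "split_validation",
    "train",
    "loso_folds",
    "run_loso",
]


@dataclass(frozen=True)
class TrainPlan:
    """One training configuration."""

    name: str
    stopping_metric: str  # "AUC" | "F1"
    imbalance: ImbalanceConfig
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 30
    min_delta: float = 0.0
    val_frac: float = 0.10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stopping_metric not in ("AUC", "F1"):
            raise ValueError("stopping_metric must be 'AUC' or 'F1'")
        if not 0.0 < self.val_frac < 1.0:
            raise ValueError("val_frac must be in (0, 1)")
        for name in ("learning_rate", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_PLAN_PRESETS = {
    "C": dict(
        stopping_metric="AUC",
        imbalance=ImbalanceConfig(
            focal_gamma=1.5, class_weights=(0.18, 0.82), weighted_sampling=True
        ),
    ),
    "D": dict(
        stopping_metric="F1",
        imbalance=ImbalanceConfig(
            focal_gamma=1.0, class_weights=(0.30, 0.70), weighted_sampling=False
        ),
    ),
    "E": dict(
        stopping_metric="F1",
        imbalance=ImbalanceConfig(
            focal_gamma=1.2, class_weights=(0.25, 0.75), weighted_sampling=False
        ),
    ),
}


def make_plan(name: str, **overrides) -> TrainPlan:
    """Return a named plan preset (C, D or E), optionally with overrides."""
    if name not in _PLAN_PRESETS:
        raise ValueError(
            f"unknown plan {name!r}; valid presets: {sorted(_PLAN_PRESETS)}"
        )
    plan = TrainPlan(name=name, **_PLAN_PRESETS[name])
    return replace(plan, **overrides) if overrides else plan


def weights_for_prevalence(
    weights: tuple[float, float], prevalence: float
) -> tuple[float, float]:
    """Reverse (neg, pos) class weights when freezing is the majority class."""
    return tuple(reversed(weights)) if prevalence > 0.5 else tuple(weights)


@dataclass
class TrainHistory:
    """Per-epoch training trace with the early-stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_auc: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def monitored(self, metric: str) -> list[float]:
        return self.val_auc if metric == "AUC" else self.val_f1


def split_validation(
    train_windows: WindowSet, val_frac: float, seed: int
) -> tuple[WindowSet, WindowSet]:
    """Stratified random window split; each class contributes ~val_frac."""
    y = train_windows.labels
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("split_validation requires >= 2 windows of each class")
    rng = np.random.default_rng(seed)
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(idx.size * val_frac)))
        val_idx.append(rng.permutation(idx)[:n_val])
    val_idx = np.sort(np.concatenate(val_idx))
    mask = np.zeros(train_windows.n_windows, dtype=bool)
    mask[val_idx] = True
    return train_windows.subset(~mask), train_windows.subset(mask)


def _f1_at_threshold(y: np.ndarray, scores: np.ndarray, threshold: float) -> float:
    pred = scores > threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    denom = 2 * tp + fp + fn
    return 0.0 if denom == 0 else 2 * tp / denom


def train(
    model: TCN, train_windows: WindowSet, plan: TrainPlan
) -> tuple[TCN, TrainHistory]:
    """Train under a plan with metric-monitored early stopping.

    The monitored metric (validation AUC or F1 at the plan's decision
    threshold) is evaluated after every epoch; training halts once it fails
    to improve by more than ``min_delta`` for ``patience`` epochs, and the
    best epoch's weights (earliest epoch on ties) are restored before
    returning. ``min_delta`` separates "still improving" from "plateaued":
    a metric creeping up in its third decimal no longer resets the patience
    counter, which is what lets a ranking metric (AUC) terminate training
    while a threshold metric (F1) is still climbing.
    """
    tr, val = split_validation(train_windows, plan.val_frac, plan.seed)
    if len(set(val.labels.tolist())) < 2:
        raise ValueError("validation split lacks a class; cannot monitor metrics")
    alpha = np.asarray(
        weights_for_prevalence(
            plan.imbalance.class_weights, float(train_windows.labels.mean())
        )
    )
    rng = np.random.default_rng(plan.seed + 1)
    optimizer = Adam(
        model.params(), lr=plan.learning_rate, weight_decay=plan.weight_decay
    )
    history = TrainHistory()
    n = tr.n_windows
    sample_weights = None
    if plan.imbalance.weighted_sampling:
        w = make_sample_weights(tr.labels)
        sample_weights = w / w.sum()
    best_metric = -np.inf
    best_state = None
    stop_ref = -np.inf
    since_improve = 0
    x_tr, y_tr = tr.windows, tr.labels.astype(int)
    for epoch in range(plan.max_epochs):
        if sample_weights is not None:
            order = rng.choice(n, size=n, replace=True, p=sample_weights)
        else:
            order = rng.permutation(n)
        losses = []
        for i in range(0, n, plan.batch_size):
            idx = order[i : i + plan.batch_size]
            logits = model.forward(x_tr[idx], train=True)
            loss, dlogits = focal_loss_batch(
                logits, y_tr[idx], alpha, plan.imbalance.focal_gamma
            )
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        scores = model.predict_proba(val.windows)[:, 1]
        v_auc = auc_score(val.labels, scores)
        v_f1 = _f1_at_threshold(val.labels, scores, plan.decision_threshold)
        history.train_loss.append(float(np.mean(losses)))
        history.val_auc.append(v_auc)
        history.val_f1.append(v_f1)
        monitored = v_auc if plan.stopping_metric == "AUC" else v_f1
        if monitored > best_metric:
            best_metric = monitored
            history.best_epoch = epoch
            best_state = model.state_dict()
        if monitored > stop_ref + plan.min_delta:
            stop_ref = monitored
            since_improve = 0
        else:
            since_improve += 1
        history.stopped_epoch = epoch
        if since_improve >= plan.patience:
            break
    model.load_state_dict(best_state)
    return model, history


def loso_folds(
    cohort: list[SensorRecording],
    min_positive_windows: int = 1,
    config: PreprocessConfig | None = None,
) -> tuple[list[tuple[list[str], str]], list[str]]:
    """Leave-one-subject-out folds with low-positive-count exclusions.

    A subject whose windowed positive count falls below
    ``min_positive_windows`` is excluded from the test role (its data still
    trains other folds). Returns ``(folds, excluded_ids)`` where each fold
    is ``(train_subject_ids, test_subject_id)``.
    """
    if len(cohort) < 2:
        raise ValueError("LOSO requires at least two subjects")
    config = config or PreprocessConfig()
    ids = [rec.subject_id for rec in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be distinct")
    pos_counts = {
        rec.subject_id: int(preprocess_recording(rec, config).labels.sum())
        for rec in cohort
    }
    excluded = sorted(
        sid for sid, c in pos_counts.items() if c < min_positive_windows
    )
    folds = [
        ([sid for sid in ids if sid != test_id], test_id)
        for test_id in sorted(ids)
        if test_id not in excluded
    ]
    if not folds:
        raise ValueError("all subjects excluded; no LOSO folds remain")
    return folds, excluded


def _fold_seed(base_seed: int, fold_index: int) -> int:
    return int(
        np.random.SeedSequence((base_seed, fold_index)).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_loso(
    cohort: list[SensorRecording],
    plan: TrainPlan,
    config: PreprocessConfig | None = None,
    model_spec: TCNSpec | None = None,
    min_positive_windows: int = 1,
) -> tuple[list[FoldMetrics], list[str]]:
    """Full leave-one-subject-out evaluation of a plan on a cohort.

    Per fold: the normalizer is fit on training-subject windows only, the
    model trains under the plan (fold-specific seed derived from
    ``plan.seed``), and the held-out subject's windows are scored at the
    plan's decision threshold. Returns fold metrics ordered by subject id,
    plus the excluded subject ids.
    """
    config = config or PreprocessConfig()
    model_spec = model_spec or TCNSpec()
    window_sets = {
        rec.subject_id: preprocess_recording(rec, config) for rec in cohort
    }
    folds, excluded = loso_folds(cohort, min_positive_windows, config)
    results = []
    for k, (train_ids, test_id) in enumerate(folds):
        seed = _fold_seed(plan.seed, k)
        train_ws = concat_windowsets([window_sets[sid] for sid in train_ids])
        stats = fit_normalizer(train_ws)
        if test_id in stats.provenance:
            raise RuntimeError(
                f"leakage: normalizer provenance contains test subject {test_id}"
            )
        train_ws = apply_normalizer(train_ws, stats)
        test_ws = apply_normalizer(window_sets[test_id], stats)
        model = build_model(model_spec, seed=seed)
        fold_plan = replace(plan, seed=seed)
        try:
            model, _ = train(model, train_ws, fold_plan)
            scores = model.predict_proba(test_ws.windows)[:, 1]
            fm = window_metrics(
                test_ws.labels, scores, fold_plan.decision_threshold, subject_id=test_id
            )
        except ValueError as exc:
            raise RuntimeError(f"fold {test_id}: {exc}") from exc
        results.append(fm)
    return sorted(results, key=lambda f: f.subject_id), excluded
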
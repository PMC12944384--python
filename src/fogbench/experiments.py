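"""Pre-registered scaled-down benchmark experiments.

The full-size protocol (64-channel TCN, 200-epoch budget, tens of subjects
with hour-scale recordings) is too expensive for a desk-scale test run, so
the package defines one scaled-down study whose conditions are fixed here
and reused verbatim by the test suite and the acceptance script:

* cohorts of 8 subjects x 5 minutes per regime;
* an 8-hidden-channel TCN (architecture otherwise identical: 4 blocks,
  dilations 1/2/4/8, kernel 3, two convs per block, 30% dropout);
* non-overlapping 2-s windows for training economy;
* 15-epoch budget with patience 5 and a 0.005 minimum improvement delta,
  learning rate 3e-3 (the smaller network tolerates, and the reduced epoch
  budget requires, a faster schedule than the full-scale 1e-3), batch 64;
* five cohort seeds per comparison.

Four arms cover the three study questions: Plan C as configured
(AUC-stopped, fully stacked imbalance corrections) against the same plan
with F1 stopping (the stopping-metric effect); Plan C against Plan D (the
overcorrection effect); and Plan D on matched lab vs daily-living cohorts
(the deployment gap).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from fogbench.cohort import generate_cohort, regime_preset
from fogbench.evaluation import FoldMetrics
from fogbench.preprocessing import PreprocessConfig
from fogbench.tcn import TCNSpec
from fogbench.training import make_plan, run_loso

__all__ = [
    "SCALED_MODEL",
    "SCALED_PREP",
    "N_SUBJECTS",
    "DURATION_S",
    "N_COHORT_SEEDS",
    "scaled_plan",
    "deployment_experiment",
    "mean_metric",
]

SCALED_MODEL = TCNSpec(hidden_channels=8)
SCALED_PREP = PreprocessConfig(overlap_frac=0.0)
N_SUBJECTS = 8
DURATION_S = 300.0
N_COHORT_SEEDS = 5

_SCALED_TRAINING = dict(
    max_epochs=15,
    patience=5,
    min_delta=0.005,
    batch_size=64,
    learning_rate=3e-3,
)


def scaled_plan(name: str, seed: int, **overrides):
    """A named plan preset under the scaled-down training schedule."""
    return make_plan(name, seed=seed, **{**_SCALED_TRAINING, **overrides})


def deployment_experiment(
    base_seed: int = 0, n_seeds: int = N_COHORT_SEEDS
) -> dict[str, list[FoldMetrics]]:
    """Run the four-arm scaled study and pool folds across cohort seeds.

    Arms (all leave-one-subject-out, pooled over ``n_seeds`` cohorts):

    - ``"C"``: Plan C on daily-living cohorts (AUC stopping, gamma 1.5,
      weights [0.18, 0.82], weighted sampling);
    - ``"C_f1"``: Plan C with F1 stopping, everything else identical;
    - ``"D"``: Plan D on the same daily-living cohorts;
    - ``"lab_D"``: Plan D on matched lab-regime cohorts.
    """
    results: dict[str, list[FoldMetrics]] = {"C": [], "C_f1": [], "D": [], "lab_D": []}
    for i in range(n_seeds):
        seed = base_seed + i
        dl = generate_cohort(
            regime_preset("daily_living"), N_SUBJECTS, DURATION_S, seed
        )
        lab = generate_cohort(regime_preset("lab"), N_SUBJECTS, DURATION_S, seed)
        plan_c = scaled_plan("C", seed)
        plan_d = scaled_plan("D", seed)
        arms = [
            ("C", plan_c, dl),
            ("C_f1", replace(plan_c, stopping_metric="F1"), dl),
            ("D", plan_d, dl),
            ("lab_D", plan_d, lab),
        ]
        for name, plan, cohort in arms:
            folds, _ = run_loso(
                cohort, plan, config=SCALED_PREP, model_spec=SCALED_MODEL
            )
            results[name].extend(folds)
    return results


def mean_metric(folds: list[FoldMetrics], name: str) -> float:
    return float(np.mean([getattr(f, name) for f in folds]))
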
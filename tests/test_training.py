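"""Training plans, early stopping, validation splits and LOSO integrity."""

import dataclasses

import numpy as np
import pytest

from fogbench.cohort import generate_cohort, regime_preset
from fogbench.preprocessing import PreprocessConfig, fit_normalizer
from fogbench.tcn import TCNSpec, build_model
from fogbench.training import (
    loso_folds,
    make_plan,
    run_loso,
    split_validation,
    train,
    weights_for_prevalence,
)
from conftest import make_toy_windowset

FAST = dict(max_epochs=10, patience=10, batch_size=32, learning_rate=3e-3)
TOY_SPEC = TCNSpec(
    in_channels=2, n_blocks=2, dilations=(1, 2), kernel_size=3,
    hidden_channels=4, dropout=0.1,
)
SEP_SPEC = dataclasses.replace(TOY_SPEC, in_channels=6)


class TestPlans:
    def test_presets_match_configured_arms(self):
        c = make_plan("C")
        assert c.stopping_metric == "AUC"
        assert c.imbalance.focal_gamma == 1.5
        assert c.imbalance.class_weights == (0.18, 0.82)
        assert c.imbalance.weighted_sampling

        d = make_plan("D")
        assert d.stopping_metric == "F1"
        assert d.imbalance.focal_gamma == 1.0
        assert d.imbalance.class_weights == (0.30, 0.70)
        assert not d.imbalance.weighted_sampling

        e = make_plan("E")
        assert e.stopping_metric == "F1"
        assert e.imbalance.focal_gamma == 1.2
        assert e.imbalance.class_weights == (0.25, 0.75)
        assert not e.imbalance.weighted_sampling

    def test_shared_optimizer_settings(self):
        d = make_plan("D")
        assert (d.learning_rate, d.weight_decay) == (1e-3, 1e-4)
        assert (d.batch_size, d.max_epochs, d.patience) == (32, 200, 30)
        assert d.val_frac == 0.10

    def test_unknown_plan_lists_presets(self):
        with pytest.raises(ValueError, match="C.*D.*E"):
            make_plan("A")

    def test_weights_reverse_on_majority_freeze_cohorts(self):
        assert weights_for_prevalence((0.30, 0.70), 0.18) == (0.30, 0.70)
        assert weights_for_prevalence((0.30, 0.70), 0.60) == (0.70, 0.30)


class TestSplitValidation:
    def test_validation_size_contract(self):
        ws = make_toy_windowset(n=100)
        tr, val = split_validation(ws, 0.1, seed=0)
        assert val.n_windows == 10 and tr.n_windows == 90

    def test_stratification_preserves_prevalence(self):
        ws = make_toy_windowset(n=200)
        _, val = split_validation(ws, 0.1, seed=1)
        assert abs(val.prevalence - ws.prevalence) <= 0.05

    def test_deterministic_given_seed(self):
        ws = make_toy_windowset(n=100)
        _, v1 = split_validation(ws, 0.1, seed=3)
        _, v2 = split_validation(ws, 0.1, seed=3)
        np.testing.assert_array_equal(v1.windows, v2.windows)

    def test_underpopulated_class_rejected(self):
        ws = make_toy_windowset(n=40)
        ws.labels[:] = 0
        ws.labels[0] = 1
        with pytest.raises(ValueError):
            split_validation(ws, 0.1, seed=0)


class TestTrain:
    def test_separable_toy_reaches_perfect_validation_f1(self):
        ws = make_toy_windowset(n=120)
        plan = make_plan("D", seed=0, max_epochs=50, **{
            k: v for k, v in FAST.items() if k != "max_epochs"})
        model = build_model(TOY_SPEC, seed=0)
        model, hist = train(model, ws, plan)
        assert max(hist.val_f1) == 1.0
        assert hist.best_epoch < 50

    def test_early_stopping_contract(self):
        ws = make_toy_windowset(n=120)
        plan = make_plan("D", seed=0, max_epochs=30, patience=3,
                         batch_size=32, learning_rate=3e-3)
        _, hist = train(build_model(TOY_SPEC, seed=0), ws, plan)
        assert hist.stopped_epoch - hist.best_epoch <= 30
        monitored = hist.monitored("F1")
        best = monitored[hist.best_epoch]
        assert best == max(monitored)
        assert hist.best_epoch == monitored.index(best)  # earliest on ties

    def test_training_is_bit_reproducible(self):
        ws = make_toy_windowset(n=80)
        plan = make_plan("D", seed=5, **FAST)
        m1, h1 = train(build_model(TOY_SPEC, seed=5), ws, plan)
        m2, h2 = train(build_model(TOY_SPEC, seed=5), ws, plan)
        assert h1.train_loss == h2.train_loss
        assert h1.val_f1 == h2.val_f1
        np.testing.assert_array_equal(
            m1.predict_proba(ws.windows), m2.predict_proba(ws.windows)
        )


class TestLosoFolds:
    def test_each_subject_tested_once_without_overlap(self):
        cohort = generate_cohort(regime_preset("lab"), 5, 60.0, 0)
        folds, excluded = loso_folds(cohort, min_positive_windows=1)
        assert excluded == []
        assert len(folds) == 5
        test_ids = [t for _, t in folds]
        assert sorted(test_ids) == sorted(r.subject_id for r in cohort)
        for train_ids, test_id in folds:
            assert test_id not in train_ids
            assert len(train_ids) == 4

    def test_low_positive_subjects_excluded(self):
        regime = regime_preset("lab")
        cohort = generate_cohort(regime, 7, 60.0, 1)
        empty = generate_cohort(
            regime_preset("lab", prevalence_target=0.0), 3, 60.0, 2
        )
        for i, rec in enumerate(empty):
            rec.subject_id = f"zz-empty-{i}"
        folds, excluded = loso_folds(cohort + empty, min_positive_windows=1)
        assert len(folds) == 7
        assert len(excluded) == 3
        assert all(sid.startswith("zz-empty") for sid in excluded)

    def test_all_excluded_rejected(self):
        cohort = generate_cohort(
            regime_preset("lab", prevalence_target=0.0), 3, 60.0, 0
        )
        with pytest.raises(ValueError, match="excluded"):
            loso_folds(cohort, min_positive_windows=1)


class TestRunLoso:
    prep = PreprocessConfig(overlap_frac=0.0)

    def test_separable_cohort_scores_perfectly_on_every_fold(self, separable_cohort):
        plan = make_plan("D", seed=0, max_epochs=20, patience=20,
                         batch_size=32, learning_rate=3e-3)
        folds, excluded = run_loso(
            separable_cohort, plan, config=self.prep, model_spec=SEP_SPEC
        )
        assert excluded == []
        assert len(folds) == 4
        assert all(f.f1 == 1.0 for f in folds)

    def test_run_is_bit_reproducible(self, separable_cohort):
        plan = make_plan("D", seed=9, max_epochs=4, patience=4,
                         batch_size=32, learning_rate=3e-3)
        a, _ = run_loso(separable_cohort[:3], plan, config=self.prep,
                        model_spec=SEP_SPEC)
        b, _ = run_loso(separable_cohort[:3], plan, config=self.prep,
                        model_spec=SEP_SPEC)
        assert [dataclasses.asdict(f) for f in a] == [
            dataclasses.asdict(f) for f in b
        ]

    def test_normalizer_provenance_excludes_test_subject(self, separable_cohort):
        from fogbench.preprocessing import concat_windowsets, preprocess_recording

        folds, _ = loso_folds(separable_cohort, 1, self.prep)
        for train_ids, test_id in folds:
            ws = concat_windowsets([
                preprocess_recording(r, self.prep)
                for r in separable_cohort
                if r.subject_id in train_ids
            ])
            stats = fit_normalizer(ws)
            assert test_id not in stats.provenance
            assert set(stats.provenance) == set(train_ids)
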
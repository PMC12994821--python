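"""Optimization loop, cross-validation and fine-tuning contracts."""

import dataclasses

import numpy as np
import pytest

from aetrans.model import AETransModel
from aetrans.nn import Adam, ReduceLROnPlateau
from aetrans.pairing import pair_corpus, stratified_split
from aetrans.training import (
    TrainConfig,
    TrainingError,
    cross_validate,
    fine_tune_single_modality,
    train_model,
)
from tests.conftest import TINY_ARCH


def make_plans(rna, meth, seed=0):
    split = stratified_split(rna, meth, test_fraction=0.25, seed=seed)
    train = pair_corpus(rna, meth, split.rna_train, split.meth_train, "train")
    val = pair_corpus(rna, meth, split.rna_test, split.meth_test, "val")
    return train, val


class TestTrainModel:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_cohort):
        rna, meth, _ = tiny_cohort
        train, val = make_plans(rna, meth)
        model = AETransModel(TINY_ARCH, seed=0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(learning_rate=0.0, max_epochs=2, seed=0)
        model, _ = train_model(model, rna, meth, train, val, cfg)
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_training_loss_decreases_on_separable_cohort(self, trained_tiny):
        traj = trained_tiny["trajectory"]
        assert traj[-1].train.classification < traj[0].train.classification
        assert traj[-1].train.total < traj[0].train.total

    def test_leaky_plans_rejected(self, tiny_cohort):
        rna, meth, _ = tiny_cohort
        train, _ = make_plans(rna, meth)
        model = AETransModel(TINY_ARCH, seed=0)
        with pytest.raises(TrainingError, match="leakage"):
            train_model(model, rna, meth, train, train, TrainConfig(max_epochs=1))

    def test_empty_pair_set_rejected(self, tiny_cohort):
        from aetrans.pairing import PairingPlan

        rna, meth, _ = tiny_cohort
        _, val = make_plans(rna, meth)
        model = AETransModel(TINY_ARCH, seed=0)
        with pytest.raises(TrainingError, match="empty"):
            train_model(model, rna, meth, PairingPlan(pairs=[]), val,
                        TrainConfig(max_epochs=1))

    def test_same_seed_reproduces_trajectory(self, tiny_cohort):
        rna, meth, _ = tiny_cohort
        train, val = make_plans(rna, meth)
        cfg = TrainConfig(max_epochs=4, seed=9)
        losses = []
        for _ in range(2):
            model = AETransModel(TINY_ARCH, seed=9)
            model, traj = train_model(model, rna, meth, train, val, cfg)
            losses.append([r.train.total for r in traj])
        assert losses[0] == losses[1]


class TestScheduler:
    def test_plateau_reduces_lr_exactly_once_after_patience(self):
        opt = Adam([], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3, min_lr=1e-6)
        sched.step(1.0)  # establishes best
        for _ in range(3):  # three non-improving epochs
            sched.step(1.0)
        assert opt.lr == 0.5 and sched.n_reductions == 1

    def test_improvement_resets_patience(self):
        opt = Adam([], lr=1.0)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2)
        sched.step(1.0)
        sched.step(1.0)
        sched.step(0.5)  # improvement
        sched.step(0.6)
        assert opt.lr == 1.0

    def test_lr_never_drops_below_min(self):
        opt = Adam([], lr=1e-5)
        sched = ReduceLROnPlateau(opt, factor=0.1, patience=1, min_lr=1e-6)
        sched.step(1.0)
        for _ in range(5):
            sched.step(1.0)
        assert opt.lr == pytest.approx(1e-6)


class TestCrossValidate:
    def test_fold_sizes_and_partition(self, tiny_cohort):
        rna, meth, _ = tiny_cohort
        cfg = TrainConfig(max_epochs=2, folds=5, seed=0)
        results, summary = cross_validate(rna, meth, TINY_ARCH, cfg)
        assert len(results) == 5
        val_rna_sets = [r.val_plan.rna_ids() for r in results]
        # validation sample sets are pairwise disjoint and cover the cohort
        union = set().union(*val_rna_sets)
        assert union == set(rna.sample_ids)
        for i in range(5):
            for j in range(i + 1, 5):
                assert val_rna_sets[i].isdisjoint(val_rna_sets[j])

    def test_summary_is_mean_of_fold_metrics(self, tiny_cohort):
        rna, meth, _ = tiny_cohort
        cfg = TrainConfig(max_epochs=2, folds=3, seed=1)
        results, summary = cross_validate(rna, meth, TINY_ARCH, cfg)
        aucs = [r.metrics["per_pair"].auc for r in results]
        assert summary["auc"][0] == pytest.approx(np.mean(aucs))

    def test_class_too_small_for_folds_raises(self):
        from aetrans.data import OmicsMatrix
        from aetrans.pairing import PairingError

        rna = OmicsMatrix(np.zeros((6, 30)), [f"r{i}" for i in range(6)],
                          [f"g{i}" for i in range(30)], [1, 1, 0, 0, 0, 0],
                          "expression")
        meth = OmicsMatrix(np.zeros((6, 30)), [f"m{i}" for i in range(6)],
                           [f"g{i}" for i in range(30)], [1, 1, 1, 0, 0, 0],
                           "methylation")
        with pytest.raises(PairingError):
            cross_validate(rna, meth, TINY_ARCH, TrainConfig(max_epochs=1, folds=5))


class TestFineTuning:
    def test_frozen_groups_unchanged_and_latents_exported(self, trained_tiny, tiny_cohort):
        rna, _, _ = tiny_cohort
        pretrained = trained_tiny["model"]
        pre_state = pretrained.state_dict()
        cfg = TrainConfig(max_epochs=3, seed=0)
        model, latents, traj = fine_tune_single_modality(pretrained, rna, cfg)
        post_state = model.state_dict()
        for name in post_state:
            if name.startswith(("rna_ae.", "meth_ae.", "meth_encoder.",
                                "meth_decoder.", "rna_decoder.")):
                np.testing.assert_array_equal(pre_state[name], post_state[name]), name
        assert latents.shape == (rna.n_samples, TINY_ARCH.effective_fusion_dim)
        assert len(traj) <= cfg.max_epochs

    def test_classifier_head_does_adapt(self, trained_tiny, tiny_cohort):
        rna, _, _ = tiny_cohort
        pretrained = trained_tiny["model"]
        cfg = TrainConfig(max_epochs=3, seed=0)
        model, _, _ = fine_tune_single_modality(pretrained, rna, cfg)
        pre = pretrained.state_dict()
        post = model.state_dict()
        changed = any(
            not np.array_equal(pre[k], post[k])
            for k in post if k.startswith("classifier.")
        )
        assert changed

    def test_methylation_cohort_rejected(self, trained_tiny, tiny_cohort):
        _, meth, _ = tiny_cohort
        with pytest.raises(TrainingError, match="expression"):
            fine_tune_single_modality(trained_tiny["model"], meth, TrainConfig())

    def test_finetuned_beats_fresh_model_on_shared_generative_factors(self, trained_tiny):
        """A model pretrained on the cohort's generative process should give
        better (or equal) RNA-only classification than a fresh model trained
        for the same few epochs, in the majority of seeds."""
        from aetrans.evaluation import roc_auc
        from aetrans.preprocess import standardize_features
        from aetrans.synthdata import SynthConfig, generate_unpaired_cohort

        pretrained = trained_tiny["model"]

        def probe_auc(model, rna_new):
            probs = model.predict_proba(
                rna_new.values, np.zeros((rna_new.n_samples, 30))
            )
            return roc_auc(probs, rna_new.labels)[0]

        wins = 0
        for seed in (0, 1, 2):
            # same seed and feature layout as the pretraining cohort (so the
            # informative genes coincide) but a fresh, larger sample draw
            rna_new, _, _ = generate_unpaired_cohort(
                SynthConfig(n_rna_samples=80 + seed, n_meth_samples=30, n_genes=30,
                            n_informative_rna=6, n_informative_meth=6, seed=11)
            )
            rna_new, _ = standardize_features(rna_new)
            cfg = TrainConfig(max_epochs=5, seed=seed)
            adapted, _, _ = fine_tune_single_modality(pretrained, rna_new, cfg)
            fresh = AETransModel(TINY_ARCH, seed=seed + 50)
            fresh_adapted, _, _ = fine_tune_single_modality(fresh, rna_new, cfg)
            if probe_auc(adapted, rna_new) >= probe_auc(fresh_adapted, rna_new):
                wins += 1
        assert wins >= 2
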
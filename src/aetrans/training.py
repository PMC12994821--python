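"""Optimization loop, five-fold cross-validation and single-modality
fine-tuning.

Training follows the published recipe: Adam (initial learning rate 0.001)
with L2 weight decay, a ReduceLROnPlateau scheduler driven by validation
loss, stratified sample-level folds per modality with pairs enumerated
strictly inside each fold, and early stopping on the best validation loss.
Each epoch makes one pass over the expression training pool in label-
consistent minibatches (a random subset of expression samples, each paired
with a fixed number of same-label methylation samples), which bounds the
pair corpus actually visited per epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .data import EXPRESSION, METHYLATION, OmicsMatrix
from .model import AETransModel, ArchitectureConfig, LossBreakdown
from .nn import Adam, ReduceLROnPlateau
from .pairing import (
    MinibatchSampler,
    PairingPlan,
    pair_corpus,
    stratified_kfold_ids,
    stratified_split,
)
from .evaluation import MetricsReport, evaluate_pairs, predict_pairs, metrics_report


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    l2_strength: float = 1e-5
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-6
    max_epochs: int = 100
    early_stop_patience: int = 15
    folds: int = 5
    rna_per_batch: int = 32
    meth_per_rna: int = 2
    max_val_pairs: int = 1024
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train: LossBreakdown
    val_loss: float
    lr: float


@dataclass
class FoldResult:
    fold: int
    trajectory: List[EpochRecord]
    metrics: Dict[str, MetricsReport]
    best_state: Dict[str, np.ndarray]
    best_epoch: int
    val_plan: Optional[PairingPlan] = None


def _mean_breakdown(records: List[LossBreakdown]) -> LossBreakdown:
    return LossBreakdown(
        **{
            k: float(np.mean([r.terms()[k] for r in records]))
            for k in records[0].terms()
        }
    )


def _subsample_plan(plan: PairingPlan, cap: int, seed: int) -> PairingPlan:
    if len(plan) <= cap:
        return plan
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(plan), size=cap, replace=False)
    return PairingPlan(pairs=[plan.pairs[i] for i in sorted(idx)], role=plan.role)


def _batch_arrays(
    rna: OmicsMatrix, meth: OmicsMatrix, plan: PairingPlan
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    rna_idx = rna.sample_index([p[0] for p in plan.pairs])
    meth_idx = meth.sample_index([p[1] for p in plan.pairs])
    labels = np.array([p[2] for p in plan.pairs], dtype=np.float64)
    return rna.values[rna_idx], meth.values[meth_idx], labels


def _validation_loss(
    model: AETransModel, rna: OmicsMatrix, meth: OmicsMatrix, plan: PairingPlan,
    batch_size: int = 256,
) -> float:
    was_training = model.training
    model.eval()
    x_rna, x_meth, labels = _batch_arrays(rna, meth, plan)
    total, n = 0.0, 0
    for start in range(0, len(labels), batch_size):
        sl = slice(start, start + batch_size)
        out = model.forward(x_rna[sl], x_meth[sl])
        _, breakdown = model.compute_loss(out, labels[sl], x_rna[sl], x_meth[sl])
        total += breakdown.total * (sl.indices(len(labels))[1] - sl.indices(len(labels))[0])
        n += sl.indices(len(labels))[1] - sl.indices(len(labels))[0]
    model.train(was_training)
    return total / max(n, 1)


def train_model(
    model: AETransModel,
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    train_plan: PairingPlan,
    val_plan: PairingPlan,
    config: TrainConfig,
) -> Tuple[AETransModel, List[EpochRecord]]:
    """Optimize the model on the training pair pool, early-stopping and
    checkpointing on validation-pair loss.  Deterministic given config.seed."""
    config.validate()
    if len(train_plan) == 0:
        raise TrainingError("empty training pair set")
    if len(val_plan) == 0:
        raise TrainingError("empty validation pair set")
    train_rna_ids = sorted(train_plan.rna_ids())
    train_meth_ids = sorted(train_plan.meth_ids())
    leak_rna = train_plan.rna_ids() & val_plan.rna_ids()
    leak_meth = train_plan.meth_ids() & val_plan.meth_ids()
    if leak_rna or leak_meth:
        raise TrainingError(
            f"sample leakage between train and validation pairs: "
            f"{sorted(leak_rna) + sorted(leak_meth)}"
        )

    sampler = MinibatchSampler(
        rna, meth, train_rna_ids, train_meth_ids,
        rna_per_batch=min(config.rna_per_batch, len(train_rna_ids)),
        meth_per_rna=config.meth_per_rna,
        seed=config.seed,
    )
    model.mask_rng = np.random.default_rng(config.seed + 7)
    val_plan_eval = _subsample_plan(val_plan, config.max_val_pairs, config.seed + 3)

    optimizer = Adam(
        model.parameters(), lr=config.learning_rate, weight_decay=config.l2_strength
    )
    scheduler = ReduceLROnPlateau(
        optimizer, factor=config.scheduler_factor,
        patience=config.scheduler_patience, min_lr=config.min_lr,
    )
    steps_per_epoch = max(1, math.ceil(len(train_rna_ids) / sampler.rna_per_batch))

    trajectory: List[EpochRecord] = []
    best_val = math.inf
    best_state = model.state_dict()
    best_epoch = 0
    bad_epochs = 0
    model.train()
    for epoch in range(1, config.max_epochs + 1):
        records: List[LossBreakdown] = []
        for _ in range(steps_per_epoch):
            batch = sampler.next_batch()
            x_rna, x_meth, labels = _batch_arrays(rna, meth, batch)
            out = model.forward(x_rna, x_meth)
            loss, breakdown = model.compute_loss(out, labels, x_rna, x_meth)
            if not math.isfinite(breakdown.total):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}: {breakdown.terms()}"
                )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            records.append(breakdown)
        val_loss = _validation_loss(model, rna, meth, val_plan_eval)
        scheduler.step(val_loss)
        trajectory.append(
            EpochRecord(
                epoch=epoch,
                train=_mean_breakdown(records),
                val_loss=val_loss,
                lr=optimizer.lr,
            )
        )
        if val_loss < best_val - 1e-10:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return model, trajectory


def train_test_run(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    arch_config: ArchitectureConfig,
    train_config: TrainConfig,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
) -> Dict[str, object]:
    """80/20 sample-level split, train (with an inner validation carve-out)
    and evaluate on the held-out test pairs."""
    split = stratified_split(rna, meth, test_fraction=test_fraction, seed=train_config.seed)
    rna_trainval = rna.subset_samples(split.rna_train)
    meth_trainval = meth.subset_samples(split.meth_train)
    inner = stratified_split(
        rna_trainval, meth_trainval, test_fraction=val_fraction, seed=train_config.seed + 1
    )
    train_plan = pair_corpus(rna, meth, inner.rna_train, inner.meth_train, role="train")
    val_plan = pair_corpus(rna, meth, inner.rna_test, inner.meth_test, role="val")
    test_plan = pair_corpus(rna, meth, split.rna_test, split.meth_test, role="test")

    model = AETransModel(arch_config, seed=train_config.seed)
    model, trajectory = train_model(model, rna, meth, train_plan, val_plan, train_config)
    return {
        "model": model,
        "split": split,
        "train_plan": train_plan,
        "val_plan": val_plan,
        "test_plan": test_plan,
        "trajectory": trajectory,
        "test_metrics": evaluate_pairs(model, rna, meth, test_plan),
    }


def cross_validate(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    arch_config: ArchitectureConfig,
    train_config: TrainConfig,
) -> Tuple[List[FoldResult], Dict[str, Tuple[float, float]]]:
    """Stratified sample-level k-fold CV per modality; pairs are enumerated
    within each fold's own sample sets, so no pair straddles folds."""
    train_config.validate()
    rna_folds = stratified_kfold_ids(
        rna.sample_ids, rna.labels, train_config.folds, train_config.seed
    )
    meth_folds = stratified_kfold_ids(
        meth.sample_ids, meth.labels, train_config.folds, train_config.seed + 1
    )
    results: List[FoldResult] = []
    for k in range(train_config.folds):
        val_rna = rna_folds[k]
        val_meth = meth_folds[k]
        tr_rna = [s for i, f in enumerate(rna_folds) if i != k for s in f]
        tr_meth = [s for i, f in enumerate(meth_folds) if i != k for s in f]
        train_plan = pair_corpus(rna, meth, tr_rna, tr_meth, role="train")
        val_plan = pair_corpus(rna, meth, val_rna, val_meth, role="val")
        fold_cfg = dc_replace(train_config, seed=train_config.seed + 100 * (k + 1))
        model = AETransModel(arch_config, seed=fold_cfg.seed)
        model, trajectory = train_model(model, rna, meth, train_plan, val_plan, fold_cfg)
        metrics = evaluate_pairs(model, rna, meth, val_plan)
        best_epoch = int(np.argmin([r.val_loss for r in trajectory])) + 1
        results.append(
            FoldResult(
                fold=k,
                trajectory=trajectory,
                metrics=metrics,
                best_state=model.state_dict(),
                best_epoch=best_epoch,
                val_plan=val_plan,
            )
        )
    summary: Dict[str, Tuple[float, float]] = {}
    for key in ("accuracy", "precision", "recall", "f1", "auc"):
        vals = [getattr(r.metrics["per_pair"], key) for r in results]
        summary[key] = (float(np.mean(vals)), float(np.std(vals)))
    return results, summary


def fine_tune_single_modality(
    pretrained: AETransModel,
    rna: OmicsMatrix,
    config: TrainConfig,
    update_fusion: bool = True,
    val_fraction: float = 0.2,
) -> Tuple[AETransModel, np.ndarray, List[Dict[str, float]]]:
    """Adapt a pretrained model to an expression-only cohort.

    Both autoencoders and the whole methylation channel stay frozen; only the
    expression Transformer encoder, the classifier head and (optionally) the
    fusion layer are updated, on classification loss alone with the
    methylation channel fed a zero placeholder.  Returns the adapted model,
    per-sample fused latent vectors (cohort order) and the loss trajectory.
    """
    if rna.modality != EXPRESSION:
        raise TrainingError("fine-tuning expects an expression-modality cohort")
    config.validate()
    model = AETransModel(pretrained.config, seed=config.seed)
    model.load_state_dict(pretrained.state_dict())

    trainable: Dict[str, object] = dict(model.rna_encoder.named_parameters("rna_encoder."))
    trainable.update(model.classifier.named_parameters("classifier."))
    if update_fusion:
        trainable.update(model.fusion.named_parameters("fusion."))
    frozen_names = sorted(set(model.named_parameters()) - set(trainable))

    rng = np.random.default_rng(config.seed)
    ids = np.array(rna.sample_ids)
    labels = rna.labels
    tr_ids, va_ids = [], []
    for cls in (0, 1):
        cls_ids = ids[labels == cls]
        perm = rng.permutation(len(cls_ids))
        n_val = max(1, int(round(val_fraction * len(cls_ids))))
        va_ids.extend(cls_ids[perm[:n_val]])
        tr_ids.extend(cls_ids[perm[n_val:]])
    tr = rna.subset_samples(sorted(tr_ids))
    va = rna.subset_samples(sorted(va_ids))

    optimizer = Adam(
        [trainable[k] for k in sorted(trainable)],
        lr=config.learning_rate,
        weight_decay=config.l2_strength,
    )
    scheduler = ReduceLROnPlateau(
        optimizer, factor=config.scheduler_factor,
        patience=config.scheduler_patience, min_lr=config.min_lr,
    )
    zeros_meth = lambda n: np.zeros((n, model.config.meth_input_dim))

    trajectory: List[Dict[str, float]] = []
    best_val = math.inf
    best_state = model.state_dict()
    bad = 0
    batch = max(8, min(64, tr.n_samples))
    for epoch in range(1, config.max_epochs + 1):
        model.train()
        order = rng.permutation(tr.n_samples)
        losses = []
        for start in range(0, tr.n_samples, batch):
            idx = order[start:start + batch]
            x = tr.values[idx]
            y = tr.labels[idx].astype(float)
            out = model.forward(x, zeros_meth(len(idx)))
            # single-modality adaptation optimizes the classification term only
            from .autograd import Tensor

            p = out["probability"]
            eps = 1e-7
            p_safe = Tensor(np.clip(p.data, eps, 1 - eps), parents=(p,))
            p_safe._backward = lambda g, _p=p: _p._accumulate(g)
            bce = -(Tensor(y) * p_safe.log() + Tensor(1 - y) * (1 - p_safe).log()).mean()
            optimizer.zero_grad()
            model.zero_grad()
            bce.backward()
            optimizer.step()
            losses.append(bce.item())
        model.eval()
        out_val = model.forward(va.values, zeros_meth(va.n_samples))
        pv = np.clip(out_val["probability"].data, 1e-7, 1 - 1e-7)
        yv = va.labels.astype(float)
        val_loss = float(-(yv * np.log(pv) + (1 - yv) * np.log(1 - pv)).mean())
        scheduler.step(val_loss)
        trajectory.append(
            {"epoch": epoch, "train_bce": float(np.mean(losses)), "val_bce": val_loss}
        )
        if val_loss < best_val - 1e-10:
            best_val, best_state, bad = val_loss, model.state_dict(), 0
        else:
            bad += 1
            if bad >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    # freeze contract: restore frozen groups bit-for-bit from the pretrained model
    pre_state = pretrained.state_dict()
    cur = model.state_dict()
    for name in frozen_names:
        cur[name] = pre_state[name]
    model.load_state_dict(cur)
    model.eval()

    out = model.forward(rna.values, zeros_meth(rna.n_samples))
    latents = out["fused"].data.copy()
    return model, latents, trajectory
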
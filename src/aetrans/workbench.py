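"""End-to-end pipeline orchestration and configuration.

One YAML file configures every stage (simulate -> preprocess -> split/pair
-> train -> evaluate -> attribute -> report); every randomized stage derives
its seed deterministically from the single global seed, so one seed
reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import yaml

from . import __version__
from .data import OmicsMatrix, read_omics_matrix, write_omics_matrix
from .model import AETransModel, ArchitectureConfig
from .pairing import pair_corpus, stratified_split
from .preprocess import standardize_features
from .synthdata import SynthConfig, generate_unpaired_cohort, write_cohort
from .training import TrainConfig, train_model
from .attribution import attribute_test_pairs
from .evaluation import evaluate_pairs

# fixed per-stage offsets so stage seeds are decoupled but derived from one seed
_STAGE_OFFSETS = {
    "simulate": 11,
    "split": 23,
    "train": 37,
    "attribute": 53,
}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 101 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    # synthetic mode is on unless both input paths are given
    rna_path: Optional[str] = None
    meth_path: Optional[str] = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    test_fraction: float = 0.2
    val_fraction: float = 0.2
    # architecture (input dims are inferred from the data at run time);
    # defaults mirror desk_reference_architecture / desk_reference_train_config
    ae_hidden_dim: int = 32
    n_tokens: int = 4
    d_model: int = 8
    n_encoder_layers: int = 2
    n_decoder_layers: int = 1
    n_heads: int = 4
    ffn_hidden_dim: int = 32
    mlp_hidden_dims: Tuple[int, ...] = (32,)
    mask_rate: float = 0.1
    loss_weights: Tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    train: TrainConfig = field(
        default_factory=lambda: TrainConfig(
            max_epochs=60, early_stop_patience=12, l2_strength=1e-2
        )
    )
    # attribution
    baseline: str = "zeros"
    n_steps: int = 64
    attribution_max_pairs: int = 32
    aggregation: str = "mean_absolute"

    def architecture(self, rna_dim: int, meth_dim: int) -> ArchitectureConfig:
        return ArchitectureConfig(
            rna_input_dim=rna_dim,
            meth_input_dim=meth_dim,
            ae_hidden_dim=self.ae_hidden_dim,
            n_tokens=self.n_tokens,
            d_model=self.d_model,
            n_encoder_layers=self.n_encoder_layers,
            n_decoder_layers=self.n_decoder_layers,
            n_heads=self.n_heads,
            ffn_hidden_dim=self.ffn_hidden_dim,
            mlp_hidden_dims=tuple(self.mlp_hidden_dims),
            mask_rate=self.mask_rate,
            loss_weights=tuple(self.loss_weights),
        )


def desk_reference_architecture(rna_dim: int, meth_dim: int) -> ArchitectureConfig:
    """The desk-scale reference architecture used throughout the docs:
    small enough to train in seconds on one CPU, same structure as the
    full-size configuration."""
    return ArchitectureConfig(
        rna_input_dim=rna_dim,
        meth_input_dim=meth_dim,
        ae_hidden_dim=32,
        n_tokens=4,
        d_model=8,
        n_encoder_layers=2,
        n_decoder_layers=1,
        n_heads=4,
        ffn_hidden_dim=32,
        mlp_hidden_dims=(32,),
        mask_rate=0.1,
    )


def desk_reference_train_config(seed: int = 0, max_epochs: int = 60) -> TrainConfig:
    """Training settings paired with the desk-scale reference architecture.

    The strong weight decay (1e-2) is what keeps the small network from
    memorizing the modest training cohorts."""
    return TrainConfig(
        max_epochs=max_epochs,
        early_stop_patience=12,
        l2_strength=1e-2,
        seed=seed,
    )


class ConfigError(ValueError):
    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


_KNOWN_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML text into a PipelineConfig, collecting every error.

    Unknown keys produce warnings (forward compatibility); an empty document
    yields the all-defaults synthetic-mode config.
    """
    data = yaml.safe_load(raw_text) or {}
    if not isinstance(data, dict):
        raise ConfigError(["top level of the config must be a mapping"])
    errors: List[str] = []
    for key in sorted(set(data) - _KNOWN_KEYS):
        warnings.warn(f"unknown config key {key!r} ignored")
        data.pop(key)
    if "synth" in data:
        try:
            data["synth"] = SynthConfig(**data["synth"])
            data["synth"].validate()
        except (TypeError, ValueError) as exc:
            errors.append(f"synth: {exc}")
            data.pop("synth", None)
    if "train" in data:
        try:
            data["train"] = TrainConfig(**data["train"])
            data["train"].validate()
        except (TypeError, ValueError) as exc:
            errors.append(f"train: {exc}")
            data.pop("train", None)
    for tup_key in ("mlp_hidden_dims", "loss_weights"):
        if tup_key in data:
            data[tup_key] = tuple(data[tup_key])
    cfg = PipelineConfig(**data)
    if cfg.train.learning_rate <= 0:
        errors.append("train.learning_rate must be positive")
    if not 0 < cfg.test_fraction < 1:
        errors.append("test_fraction must lie in (0, 1)")
    if not 0 <= cfg.mask_rate < 1:
        errors.append("mask_rate must lie in [0, 1)")
    if cfg.n_steps < 1:
        errors.append("n_steps must be >= 1")
    for path_key in ("rna_path", "meth_path"):
        p = getattr(cfg, path_key)
        if p is not None and not Path(p).exists():
            errors.append(f"{path_key}: no such file {p}")
    if (cfg.rna_path is None) != (cfg.meth_path is None):
        errors.append("rna_path and meth_path must be given together")
    if errors:
        raise ConfigError(errors)
    return cfg


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate -> preprocess -> split/pair -> train -> evaluate ->
    attribute -> report; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # 1. simulate or load
    def load_or_simulate():
        if config.rna_path:
            rna = read_omics_matrix(config.rna_path, "expression")
            meth = read_omics_matrix(config.meth_path, "methylation")
        else:
            synth = dataclasses.replace(
                config.synth, seed=stage_seed(config.seed, "simulate")
            )
            rna, meth, truth = generate_unpaired_cohort(synth)
            paths = write_cohort(rna, meth, truth, out / "cohort")
            artifacts.update(paths)
        return rna, meth

    rna_raw, meth_raw = _stage("simulate")(load_or_simulate)

    # 2. split at the sample level, then standardize with train-sample stats
    def split_and_scale():
        split = stratified_split(
            rna_raw, meth_raw,
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, "split"),
        )
        rna_s, stats_r = standardize_features(rna_raw.subset_samples(split.rna_train))
        meth_s, stats_m = standardize_features(meth_raw.subset_samples(split.meth_train))
        rna, _ = standardize_features(rna_raw, stats_r)
        meth, _ = standardize_features(meth_raw, stats_m)
        write_omics_matrix(rna, out / "rna_standardized.tsv")
        write_omics_matrix(meth, out / "meth_standardized.tsv")
        artifacts["rna_standardized"] = str(out / "rna_standardized.tsv")
        artifacts["meth_standardized"] = str(out / "meth_standardized.tsv")
        return split, rna, meth

    split, rna, meth = _stage("preprocess")(split_and_scale)

    # 3. pairing plans
    def make_plans():
        inner = stratified_split(
            rna.subset_samples(split.rna_train),
            meth.subset_samples(split.meth_train),
            test_fraction=config.val_fraction,
            seed=stage_seed(config.seed, "split") + 1,
        )
        train_plan = pair_corpus(rna, meth, inner.rna_train, inner.meth_train, "train")
        val_plan = pair_corpus(rna, meth, inner.rna_test, inner.meth_test, "val")
        test_plan = pair_corpus(rna, meth, split.rna_test, split.meth_test, "test")
        for name, plan in (("train", train_plan), ("val", val_plan), ("test", test_plan)):
            plan.to_tsv(out / f"pairs_{name}.tsv")
            artifacts[f"pairs_{name}"] = str(out / f"pairs_{name}.tsv")
        return train_plan, val_plan, test_plan

    train_plan, val_plan, test_plan = _stage("split")(make_plans)

    # 4. train
    def train():
        arch = config.architecture(rna.n_features, meth.n_features)
        tc = dataclasses.replace(config.train, seed=stage_seed(config.seed, "train"))
        model = AETransModel(arch, seed=tc.seed)
        model, trajectory = train_model(model, rna, meth, train_plan, val_plan, tc)
        model.save(out / "model.npz")
        artifacts["checkpoint"] = str(out / "model.npz")
        with open(out / "training_log.jsonl", "w") as fh:
            for rec in trajectory:
                fh.write(json.dumps(
                    {"epoch": rec.epoch, "val_loss": rec.val_loss, "lr": rec.lr,
                     **{f"train_{k}": v for k, v in rec.train.terms().items()}},
                    default=_json_default) + "\n")
        artifacts["training_log"] = str(out / "training_log.jsonl")
        return model, trajectory

    model, trajectory = _stage("train")(train)

    # 5. evaluate
    def evaluate():
        reports = evaluate_pairs(model, rna, meth, test_plan)
        payload = {k: v.to_dict() for k, v in reports.items()}
        (out / "metrics.json").write_text(
            json.dumps(payload, indent=2, default=_json_default)
        )
        artifacts["metrics"] = str(out / "metrics.json")
        return reports

    reports = _stage("evaluate")(evaluate)

    # 6. attribute
    def attribute():
        result = attribute_test_pairs(
            model, rna, meth, test_plan,
            baseline=config.baseline,
            n_steps=config.n_steps,
            max_pairs=config.attribution_max_pairs,
            aggregation=config.aggregation,
            seed=stage_seed(config.seed, "attribute"),
        )
        result.to_tsv(out / "attributions.tsv")
        artifacts["attributions"] = str(out / "attributions.tsv")
        return result

    _stage("attribute")(attribute)

    # 7. report / manifest
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:16]
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "artifacts": artifacts,
        "n_epochs_run": len(trajectory),
        "first_epoch_total_loss": trajectory[0].train.total,
        "final_epoch_total_loss": trajectory[-1].train.total,
        "best_epoch": int(np.argmin([r.val_loss for r in trajectory])) + 1,
        "cycle_terms_epoch1": {
            "cycle_rna": trajectory[0].train.cycle_rna,
            "cycle_meth": trajectory[0].train.cycle_meth,
        },
        "cycle_terms_best_epoch": {
            "cycle_rna": trajectory[
                int(np.argmin([r.val_loss for r in trajectory]))
            ].train.cycle_rna,
            "cycle_meth": trajectory[
                int(np.argmin([r.val_loss for r in trajectory]))
            ].train.cycle_meth,
        },
        "test_metrics": {k: v.to_dict() for k, v in reports.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_json_default))
    return out
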
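"""Synthetic unpaired two-modality cohorts with known ground truth.

The generator emulates the clinical setting the model targets: two cohorts
measured on *different* individuals (disjoint sample ids, different sizes)
that nevertheless share a label-dependent latent signal.  Per-sample latent
factors are standard normal; the diagnosis shifts the first latent factor by
``latent_shift`` within-class standard deviations in cases; informative
features load on that factor so that their class-conditional means differ by
exactly ``effect_size`` in the linear predictor, before observation noise.  Expression features are a linear map
of the latent factors plus Gaussian noise; methylation features pass the
linear map through a logistic squash (beta values), add noise, and clip to
[0, 1].  Non-informative features have zero loading on every latent factor
and are pure noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Tuple, Union

import numpy as np

from .data import EXPRESSION, METHYLATION, OmicsMatrix, write_omics_matrix


class ConfigurationError(ValueError):
    """A SynthConfig field violates its contract."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one unpaired two-modality cohort."""

    n_rna_samples: int = 200
    n_meth_samples: int = 120
    n_genes: int = 400
    n_informative_rna: int = 20
    n_informative_meth: int = 20
    effect_size: float = 1.5
    latent_shift: float = 3.0  # class separation of the shared factor, in its own sd
    latent_dim: int = 8
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    case_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_rna_samples", "n_meth_samples", "n_genes", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("n_informative_rna", "n_informative_meth"):
            v = getattr(self, name)
            if v < 0 or v > self.n_genes:
                raise ConfigurationError(f"{name}={v} must lie in [0, n_genes={self.n_genes}]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate={self.missing_rate} must lie in [0, 1)")
        if not 0.0 < self.case_fraction < 1.0:
            raise ConfigurationError(f"case_fraction={self.case_fraction} must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd={self.noise_sd} must be nonnegative")
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size={self.effect_size} must be nonnegative")
        if self.latent_shift <= 0:
            raise ConfigurationError(f"latent_shift={self.latent_shift} must be positive")


@dataclass
class GroundTruth:
    """What the generator injected, for validating downstream recovery."""

    informative_rna: List[str]
    informative_meth: List[str]
    latent_rna: np.ndarray  # (n_rna_samples, latent_dim)
    latent_meth: np.ndarray
    labels_rna: np.ndarray
    labels_meth: np.ndarray

    def to_json(self, path: Union[str, Path]) -> None:
        payload = {
            "informative_rna": self.informative_rna,
            "informative_meth": self.informative_meth,
            "latent_rna": self.latent_rna.tolist(),
            "latent_meth": self.latent_meth.tolist(),
            "labels_rna": self.labels_rna.tolist(),
            "labels_meth": self.labels_meth.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _make_labels(n: int, case_fraction: float, rng: np.random.Generator) -> np.ndarray:
    n_case = int(round(n * case_fraction))
    n_case = min(max(n_case, 1), n - 1)
    labels = np.zeros(n, dtype=np.int64)
    labels[:n_case] = 1
    rng.shuffle(labels)
    return labels


def _latent(
    labels: np.ndarray, latent_dim: int, latent_shift: float, rng: np.random.Generator
) -> np.ndarray:
    z = rng.normal(size=(len(labels), latent_dim))
    z[:, 0] += labels * latent_shift  # class shift on the first factor
    return z


def _loadings(
    n_genes: int,
    informative: np.ndarray,
    effect_size: float,
    latent_shift: float,
    latent_dim: int,
    rng: np.random.Generator,
) -> np.ndarray:
    w = np.zeros((latent_dim, n_genes))
    # factor 0 carries a class shift of latent_shift, so this loading makes
    # the class-conditional feature-mean difference exactly effect_size pre-noise
    w[0, informative] = effect_size / latent_shift
    if latent_dim > 1:
        w[1:, informative] = rng.normal(0.0, 0.3, size=(latent_dim - 1, len(informative)))
    return w


def generate_unpaired_cohort(
    config: SynthConfig,
) -> Tuple[OmicsMatrix, OmicsMatrix, GroundTruth]:
    """Draw two unpaired cohorts sharing a label-dependent latent factor.

    Returns the expression cohort, the methylation cohort and the injected
    ground truth.  Pure function of ``config`` (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]

    inf_rna = np.sort(rng.choice(config.n_genes, size=config.n_informative_rna, replace=False))
    inf_meth = np.sort(rng.choice(config.n_genes, size=config.n_informative_meth, replace=False))

    labels_rna = _make_labels(config.n_rna_samples, config.case_fraction, rng)
    labels_meth = _make_labels(config.n_meth_samples, config.case_fraction, rng)
    z_rna = _latent(labels_rna, config.latent_dim, config.latent_shift, rng)
    z_meth = _latent(labels_meth, config.latent_dim, config.latent_shift, rng)

    w_rna = _loadings(
        config.n_genes, inf_rna, config.effect_size, config.latent_shift,
        config.latent_dim, rng,
    )
    w_meth = _loadings(
        config.n_genes, inf_meth, config.effect_size, config.latent_shift,
        config.latent_dim, rng,
    )

    x_rna = z_rna @ w_rna + rng.normal(0.0, config.noise_sd, size=(config.n_rna_samples, config.n_genes))

    # per-gene baseline methylation level in logit space, then squash + noise
    baseline = rng.uniform(-1.5, 1.5, size=config.n_genes)
    eta = z_meth @ w_meth + baseline
    beta = 1.0 / (1.0 + np.exp(-eta))
    x_meth = np.clip(
        beta + rng.normal(0.0, 0.1 * config.noise_sd, size=beta.shape), 0.0, 1.0
    )

    rna = OmicsMatrix(
        values=x_rna,
        sample_ids=[f"R{i:04d}" for i in range(config.n_rna_samples)],
        feature_ids=genes,
        labels=labels_rna,
        modality=EXPRESSION,
    )
    meth = OmicsMatrix(
        values=x_meth,
        sample_ids=[f"M{i:04d}" for i in range(config.n_meth_samples)],
        feature_ids=genes,
        labels=labels_meth,
        modality=METHYLATION,
    )
    if config.missing_rate > 0:
        rna = inject_missingness(rna, config.missing_rate, seed=config.seed + 1)
        meth = inject_missingness(meth, config.missing_rate, seed=config.seed + 2)

    truth = GroundTruth(
        informative_rna=[genes[i] for i in inf_rna],
        informative_meth=[genes[i] for i in inf_meth],
        latent_rna=z_rna,
        latent_meth=z_meth,
        labels_rna=labels_rna,
        labels_meth=labels_meth,
    )
    return rna, meth, truth


def inject_missingness(matrix: OmicsMatrix, rate: float, seed: int) -> OmicsMatrix:
    """Set each entry to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ConfigurationError(f"missingness rate={rate} must lie in [0, 1)")
    if rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.values.shape) < rate
    values = matrix.values.copy()
    values[mask] = np.nan
    return OmicsMatrix(
        values=values,
        sample_ids=matrix.sample_ids,
        feature_ids=matrix.feature_ids,
        labels=matrix.labels,
        modality=matrix.modality,
    )


# fixed tiny fixture used in docs and exact tests: 6 RNA x 8 genes, 4 meth x 8
# genes, first 3 genes informative (cases shifted up in RNA, hypomethylated)
_WORKED_GENES = ["g000", "g001", "g002", "g003", "g004", "g005", "g006", "g007"]
_WORKED_RNA = np.array(
    [
        [2.1, 1.8, 2.4, 0.3, -0.5, 0.1, -0.2, 0.4],
        [1.7, 2.2, 1.9, -0.4, 0.2, -0.1, 0.5, -0.3],
        [2.3, 1.6, 2.0, 0.1, 0.4, -0.6, 0.0, 0.2],
        [0.2, -0.3, 0.1, 0.5, -0.2, 0.3, -0.4, 0.1],
        [-0.1, 0.4, -0.2, -0.3, 0.1, 0.2, 0.3, -0.5],
        [0.3, 0.0, 0.2, 0.2, -0.4, -0.1, 0.1, 0.3],
    ]
)
_WORKED_METH = np.array(
    [
        [0.15, 0.22, 0.18, 0.51, 0.48, 0.55, 0.47, 0.52],
        [0.21, 0.17, 0.24, 0.49, 0.53, 0.46, 0.50, 0.45],
        [0.78, 0.83, 0.75, 0.52, 0.47, 0.51, 0.49, 0.54],
        [0.82, 0.77, 0.85, 0.48, 0.50, 0.53, 0.46, 0.49],
    ]
)


def make_worked_example() -> Tuple[OmicsMatrix, OmicsMatrix]:
    """Fixed tiny two-cohort fixture (6x8 expression, 4x8 methylation)."""
    rna = OmicsMatrix(
        values=_WORKED_RNA.copy(),
        sample_ids=[f"R{i}" for i in range(6)],
        feature_ids=list(_WORKED_GENES),
        labels=np.array([1, 1, 1, 0, 0, 0]),
        modality=EXPRESSION,
    )
    meth = OmicsMatrix(
        values=_WORKED_METH.copy(),
        sample_ids=[f"M{i}" for i in range(4)],
        feature_ids=list(_WORKED_GENES),
        labels=np.array([1, 1, 0, 0]),
        modality=METHYLATION,
    )
    return rna, meth


def write_cohort(
    rna: OmicsMatrix, meth: OmicsMatrix, truth: GroundTruth, out_dir: Union[str, Path]
) -> Dict[str, str]:
    """Write both matrices as TSV plus the ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rna": str(out / "rna.tsv"),
        "meth": str(out / "meth.tsv"),
        "truth": str(out / "ground_truth.json"),
    }
    write_omics_matrix(rna, paths["rna"])
    write_omics_matrix(meth, paths["meth"])
    truth.to_json(paths["truth"])
    return paths
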
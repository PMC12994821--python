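"""Sample-by-feature omics containers and delimited-text I/O.

An :class:`OmicsMatrix` holds one modality's cohort: a samples x features
float matrix (NaN marks a missing measurement), unique sample and feature
identifiers, a binary diagnosis label per sample (1 = case, 0 = control)
and a modality tag.  Methylation matrices carry beta values, so every
observed entry must lie in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

EXPRESSION = "expression"
METHYLATION = "methylation"
MODALITIES = (EXPRESSION, METHYLATION)


@dataclass
class OmicsMatrix:
    values: np.ndarray  # (n_samples, n_features), NaN = missing
    sample_ids: list
    feature_ids: list
    labels: np.ndarray  # binary int per sample
    modality: str
    standardized: bool = False  # z-scored matrices leave the beta range

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {p} columns")
        if len(self.labels) != n:
            raise ValueError("labels length must equal sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != p:
            raise ValueError("duplicate feature ids")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.modality == METHYLATION and not self.standardized:
            obs = self.values[~np.isnan(self.values)]
            if obs.size and (obs.min() < 0 or obs.max() > 1):
                raise ValueError("observed methylation values must lie in [0, 1]")

    # -- convenience ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in sample_ids], dtype=np.int64)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.sample_index(sample_ids)
        return replace(
            self,
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        lookup = {f: j for j, f in enumerate(self.feature_ids)}
        idx = np.array([lookup[f] for f in feature_ids], dtype=np.int64)
        return replace(
            self,
            values=self.values[:, idx],
            feature_ids=[self.feature_ids[j] for j in idx],
        )

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class ProbeAnnotation:
    """Probe-to-gene annotation table.

    ``gene_symbol`` may be empty/NaN (unannotated probe) and a probe_id may
    appear on several rows when it maps to several genes (an *ambiguous*
    probe).  ``tss_offset`` is signed base pairs relative to the gene's
    transcription start site, negative = upstream.
    """

    table: pd.DataFrame  # columns: probe_id, gene_symbol, optional tss_offset

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        self.table = self.table.copy()
        self.table["probe_id"] = self.table["probe_id"].astype(str)

    @property
    def has_tss(self) -> bool:
        return "tss_offset" in self.table.columns


# -- delimited-text I/O -------------------------------------------------------

def _detect_sep(path: Union[str, Path]) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_omics_matrix(path: Union[str, Path], modality: str) -> OmicsMatrix:
    """Read a delimited matrix: first column sample id, a `label` column, features."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    labels = df.pop("label").astype(int).to_numpy()
    return OmicsMatrix(
        values=df.to_numpy(dtype=np.float64),
        sample_ids=list(df.index.astype(str)),
        feature_ids=list(df.columns.astype(str)),
        labels=labels,
        modality=modality,
    )


def write_omics_matrix(matrix: OmicsMatrix, path: Union[str, Path]) -> None:
    df = matrix.to_frame()
    df.insert(0, "label", matrix.labels)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_probe_annotation(path: Union[str, Path]) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep=_detect_sep(path)))
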
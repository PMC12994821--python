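"""Probe-level to gene-level preprocessing.

Pipeline order: collapse probes to genes (expression) or map CpG probes
through the upstream-TSS window (methylation), drop features with more than
30% missing values and zero-impute the rest, intersect the two gene sets,
and z-score per feature with train-set statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .data import METHYLATION, OmicsMatrix, ProbeAnnotation


class PreprocessError(ValueError):
    pass


def _aggregate_by_gene(matrix: OmicsMatrix, probe_to_gene: pd.Series) -> OmicsMatrix:
    """Arithmetic mean of observed probe values per gene, per sample."""
    keep = [p for p in matrix.feature_ids if p in probe_to_gene.index]
    if not keep:
        raise PreprocessError("no probes mappable to genes with the given annotation")
    df = matrix.to_frame()[keep]
    genes = probe_to_gene.loc[keep]
    # groupby-mean over columns skips NaN, so the mean is over observed probes
    # only; a gene with every probe missing in a sample stays missing
    collapsed = df.T.groupby(genes.values).mean().T
    collapsed = collapsed[sorted(collapsed.columns)]
    values = collapsed.to_numpy(dtype=np.float64)
    if matrix.modality == METHYLATION:
        # averaging beta values keeps them in [0,1]; guard against fp drift
        values = np.clip(values, 0.0, 1.0)
    return replace(
        matrix,
        values=values,
        feature_ids=list(collapsed.columns),
    )


def collapse_probes(matrix: OmicsMatrix, annotation: ProbeAnnotation) -> OmicsMatrix:
    """Collapse probe-level rows to gene symbols by arithmetic averaging.

    Probes without a gene annotation are discarded; redundant probes for the
    same gene are averaged over their observed values.
    """
    table = annotation.table.dropna(subset=["gene_symbol"])
    table = table[table["gene_symbol"].astype(str).str.len() > 0]
    mapping = table.drop_duplicates("probe_id").set_index("probe_id")["gene_symbol"]
    return _aggregate_by_gene(matrix, mapping)


def map_cpg_to_genes(
    matrix: OmicsMatrix, annotation: ProbeAnnotation, window_bp: int = 1500
) -> OmicsMatrix:
    """Map CpG probes within ``window_bp`` upstream of a TSS to gene symbols.

    tss_offset is signed base pairs, negative = upstream, so the window keeps
    offsets in [-window_bp, 0].  Probes annotated to more than one gene are
    ambiguous and dropped entirely; retained probes are averaged per gene.
    """
    if matrix.modality != METHYLATION:
        raise PreprocessError("TSS-window mapping applies to the methylation modality")
    if not annotation.has_tss:
        raise PreprocessError("annotation lacks the tss_offset column")
    table = annotation.table.dropna(subset=["gene_symbol", "tss_offset"])
    table = table[table["gene_symbol"].astype(str).str.len() > 0]
    in_window = table[(table["tss_offset"] >= -window_bp) & (table["tss_offset"] <= 0)]
    counts = in_window.groupby("probe_id")["gene_symbol"].nunique()
    ambiguous = set(counts[counts > 1].index)
    unambiguous = in_window[~in_window["probe_id"].isin(ambiguous)]
    if unambiguous.empty:
        raise PreprocessError(f"no unambiguous probes within {window_bp} bp upstream of a TSS")
    mapping = unambiguous.drop_duplicates("probe_id").set_index("probe_id")["gene_symbol"]
    return _aggregate_by_gene(matrix, mapping)


def filter_missing(matrix: OmicsMatrix, max_missing_fraction: float = 0.30) -> OmicsMatrix:
    """Drop features missing in more than the threshold fraction of samples,
    then set every remaining missing entry to exactly zero."""
    frac = matrix.missing_mask().mean(axis=0)
    keep = frac <= max_missing_fraction
    if not keep.any():
        raise PreprocessError(
            f"every feature exceeds the {max_missing_fraction:.0%} missingness threshold"
        )
    values = matrix.values[:, keep].copy()
    values[np.isnan(values)] = 0.0
    return replace(
        matrix,
        values=values,
        feature_ids=[f for f, k in zip(matrix.feature_ids, keep) if k],
    )


def intersect_features(
    rna: OmicsMatrix, meth: OmicsMatrix
) -> Tuple[OmicsMatrix, OmicsMatrix]:
    """Restrict both cohorts to their shared genes, lexicographic column order."""
    shared = sorted(set(rna.feature_ids) & set(meth.feature_ids))
    if not shared:
        raise PreprocessError("the two modalities share no gene symbols")
    return rna.subset_features(shared), meth.subset_features(shared)


@dataclass(frozen=True)
class FeatureStats:
    mean: np.ndarray
    scale: np.ndarray  # std, with zero-variance features forced to 1


def standardize_features(
    matrix: OmicsMatrix, stats: Optional[FeatureStats] = None
) -> Tuple[OmicsMatrix, FeatureStats]:
    """Per-feature z-score; reuse train-set stats for a test-set transform."""
    if np.isnan(matrix.values).any():
        raise PreprocessError("standardization requires a fully imputed matrix")
    if stats is None:
        mean = matrix.values.mean(axis=0)
        scale = matrix.values.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        stats = FeatureStats(mean=mean, scale=scale)
    values = (matrix.values - stats.mean) / stats.scale
    out = replace(matrix, values=values, standardized=True)
    return out, stats


def center_batches(matrix: OmicsMatrix, batches: np.ndarray) -> OmicsMatrix:
    """Per-batch mean-centering hook (simple alternative to empirical-Bayes
    harmonization, which is deliberately out of scope)."""
    batches = np.asarray(batches)
    if len(batches) != matrix.n_samples:
        raise PreprocessError("batch vector length must equal sample count")
    values = matrix.values.copy()
    grand_mean = np.nanmean(values, axis=0)
    for b in np.unique(batches):
        rows = batches == b
        values[rows] += grand_mean - np.nanmean(values[rows], axis=0)
    if matrix.modality == METHYLATION:
        values = np.clip(values, 0.0, 1.0)
    return replace(matrix, values=values)
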
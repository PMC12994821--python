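"""Probe-level preprocessing: collapse, TSS-window mapping, missingness
filter and gene-set intersection.

Expression probes are averaged into gene symbols; methylation CpG probes
are kept only when they fall within 1500 bp upstream of a transcription
start site (ambiguous probes, annotated to several genes, are dropped);
features missing in >30% of samples are removed and the rest zero-imputed;
finally both modalities are restricted to their shared genes.
"""

import numpy as np
import pandas as pd

from aetrans import OmicsMatrix, ProbeAnnotation
from aetrans.preprocess import (
    collapse_probes, filter_missing, intersect_features, map_cpg_to_genes,
)

rna_probes = OmicsMatrix(
    values=np.array([
        [2.0, 4.0, 1.0, 5.0],
        [1.0, 3.0, np.nan, 2.0],
    ]),
    sample_ids=["s1", "s2"],
    feature_ids=["p1", "p2", "p3", "p4"],
    labels=[1, 0],
    modality="expression",
)
rna_annotation = ProbeAnnotation(pd.DataFrame({
    "probe_id": ["p1", "p2", "p3", "p4"],
    "gene_symbol": ["GENE_A", "GENE_A", "GENE_B", None],  # p4 unannotated
}))

meth_probes = OmicsMatrix(
    values=np.array([
        [0.2, 0.4, 0.9, 0.5],
        [0.3, 0.5, 0.8, 0.6],
    ]),
    sample_ids=["m1", "m2"],
    feature_ids=["c1", "c2", "c3", "c4"],
    labels=[1, 0],
    modality="methylation",
)
meth_annotation = ProbeAnnotation(pd.DataFrame({
    "probe_id": ["c1", "c2", "c3", "c4", "c4"],
    "gene_symbol": ["GENE_A", "GENE_A", "GENE_B", "GENE_B", "GENE_C"],
    "tss_offset": [-1000, -400, -2000, -100, -100],  # negative = upstream
}))

rna = collapse_probes(rna_probes, rna_annotation)
print("expression genes after probe collapse:", rna.feature_ids)
print("  GENE_A in s1 = mean(2, 4) =", rna.values[0, rna.feature_ids.index("GENE_A")])

meth = map_cpg_to_genes(meth_probes, meth_annotation, window_bp=1500)
print("methylation genes after TSS-window mapping:", meth.feature_ids)
print("  (c3 is 2000 bp upstream -> outside the window; c4 maps to two genes -> dropped)")

rna = filter_missing(rna, 0.30)
meth = filter_missing(meth, 0.30)
rna, meth = intersect_features(rna, meth)
print("shared gene set after intersection:", rna.feature_ids)
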
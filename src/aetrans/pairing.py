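"""Intra-label combinatorial pairing of two unpaired cohorts.

Because the expression and methylation cohorts come from different
individuals, training pairs are formed by the Cartesian product of samples
within each diagnostic label: every case expression sample is matched with
every case methylation sample, and likewise for controls.  Splits and folds
are drawn at the *sample* level per modality before any pairing, so a
sample's measurements can never appear on both sides of a split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import OmicsMatrix


class PairingError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Train/test sample ids per modality from one stratified sample-level split."""

    rna_train: Tuple[str, ...]
    rna_test: Tuple[str, ...]
    meth_train: Tuple[str, ...]
    meth_test: Tuple[str, ...]
    seed: int
    test_fraction: float


@dataclass
class PairingPlan:
    """(rna_id, meth_id, label) triples, all from one split role."""

    pairs: List[Tuple[str, str, int]]
    role: str = "train"

    def __len__(self) -> int:
        return len(self.pairs)

    def rna_ids(self) -> set:
        return {p[0] for p in self.pairs}

    def meth_ids(self) -> set:
        return {p[1] for p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.pairs, columns=["rna_id", "meth_id", "label"])
        df["role"] = self.role
        return df

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def split_by_label(matrix: OmicsMatrix) -> Tuple[List[str], List[str]]:
    """Partition sample ids into (case, control) subsets."""
    case = [s for s, y in zip(matrix.sample_ids, matrix.labels) if y == 1]
    control = [s for s, y in zip(matrix.sample_ids, matrix.labels) if y == 0]
    if not case or not control:
        raise PairingError("both classes must be present to split by label")
    return case, control


def _stratified_ids(
    ids: Sequence[str], labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> Tuple[List[str], List[str]]:
    train: List[str] = []
    test: List[str] = []
    for cls in (1, 0):
        cls_ids = [s for s, y in zip(ids, labels) if y == cls]
        n_test = max(1, int(round(test_fraction * len(cls_ids))))
        if n_test >= len(cls_ids):
            raise PairingError(
                f"class {cls} has {len(cls_ids)} samples; cannot place >=1 in both sides"
            )
        perm = rng.permutation(len(cls_ids))
        test.extend(cls_ids[i] for i in perm[:n_test])
        train.extend(cls_ids[i] for i in perm[n_test:])
    return sorted(train), sorted(test)


def stratified_split(
    rna: OmicsMatrix, meth: OmicsMatrix, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Per-class 80/20 (by default) sample-level split of both cohorts."""
    if not 0.0 < test_fraction < 1.0:
        raise PairingError(f"test_fraction={test_fraction} must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rna_train, rna_test = _stratified_ids(rna.sample_ids, rna.labels, test_fraction, rng)
    meth_train, meth_test = _stratified_ids(meth.sample_ids, meth.labels, test_fraction, rng)
    return SplitPlan(
        rna_train=tuple(rna_train),
        rna_test=tuple(rna_test),
        meth_train=tuple(meth_train),
        meth_test=tuple(meth_test),
        seed=seed,
        test_fraction=test_fraction,
    )


def enumerate_pairs(
    rna_ids: Sequence[str],
    meth_ids: Sequence[str],
    label: int,
    rna_labels: Dict[str, int] = None,
    meth_labels: Dict[str, int] = None,
    role: str = "train",
) -> PairingPlan:
    """Full Cartesian product of two same-label subsets: |rna| x |meth| pairs."""
    if rna_labels is not None:
        bad = [s for s in rna_ids if rna_labels[s] != label]
        if bad:
            raise PairingError(f"expression samples {bad} do not carry label {label}")
    if meth_labels is not None:
        bad = [s for s in meth_ids if meth_labels[s] != label]
        if bad:
            raise PairingError(f"methylation samples {bad} do not carry label {label}")
    pairs = [(r, m, label) for r in rna_ids for m in meth_ids]
    return PairingPlan(pairs=pairs, role=role)


def pair_corpus(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    rna_ids: Sequence[str],
    meth_ids: Sequence[str],
    role: str = "train",
) -> PairingPlan:
    """Enumerate all intra-label pairs between two same-split sample sets."""
    rna_lab = dict(zip(rna.sample_ids, rna.labels.tolist()))
    meth_lab = dict(zip(meth.sample_ids, meth.labels.tolist()))
    pairs: List[Tuple[str, str, int]] = []
    for label in (1, 0):
        r_sub = [s for s in rna_ids if rna_lab[s] == label]
        m_sub = [s for s in meth_ids if meth_lab[s] == label]
        pairs.extend(enumerate_pairs(r_sub, m_sub, label, role=role).pairs)
    return PairingPlan(pairs=pairs, role=role)


class MinibatchSampler:
    """Label-consistent minibatches from two unpaired sample pools.

    Each batch draws ``rna_per_batch`` expression samples without replacement
    (within the batch) and pairs each with ``meth_per_rna`` same-label
    methylation samples; draws are with replacement across batches.
    """

    def __init__(
        self,
        rna: OmicsMatrix,
        meth: OmicsMatrix,
        rna_ids: Sequence[str],
        meth_ids: Sequence[str],
        rna_per_batch: int = 32,
        meth_per_rna: int = 2,
        seed: int = 0,
    ):
        rna_lab = dict(zip(rna.sample_ids, rna.labels.tolist()))
        meth_lab = dict(zip(meth.sample_ids, meth.labels.tolist()))
        self._rna_ids = list(rna_ids)
        self._rna_labels = {s: rna_lab[s] for s in rna_ids}
        self._meth_by_label = {
            y: [s for s in meth_ids if meth_lab[s] == y] for y in (0, 1)
        }
        if rna_per_batch > len(self._rna_ids):
            raise PairingError(
                f"rna_per_batch={rna_per_batch} exceeds {len(self._rna_ids)} available samples"
            )
        for y in (0, 1):
            if any(self._rna_labels[s] == y for s in self._rna_ids) and not self._meth_by_label[y]:
                raise PairingError(f"no methylation samples available for label {y}")
        self.rna_per_batch = rna_per_batch
        self.meth_per_rna = meth_per_rna
        self.rng = np.random.default_rng(seed)

    def next_batch(self) -> PairingPlan:
        chosen = self.rng.choice(len(self._rna_ids), size=self.rna_per_batch, replace=False)
        pairs: List[Tuple[str, str, int]] = []
        for i in chosen:
            r = self._rna_ids[i]
            y = self._rna_labels[r]
            pool = self._meth_by_label[y]
            take = self.rng.choice(len(pool), size=self.meth_per_rna, replace=len(pool) < self.meth_per_rna)
            pairs.extend((r, pool[j], y) for j in take)
        return PairingPlan(pairs=pairs, role="train")


def stratified_kfold_ids(
    ids: Sequence[str], labels: np.ndarray, n_folds: int, seed: int
) -> List[List[str]]:
    """Assign sample ids to stratified folds; returns one id list per fold."""
    rng = np.random.default_rng(seed)
    folds: List[List[str]] = [[] for _ in range(n_folds)]
    for cls in (1, 0):
        cls_ids = [s for s, y in zip(ids, labels) if y == cls]
        if len(cls_ids) < n_folds:
            raise PairingError(
                f"class {cls} has {len(cls_ids)} samples, fewer than {n_folds} folds"
            )
        perm = rng.permutation(len(cls_ids))
        for k, i in enumerate(perm):
            folds[k % n_folds].append(cls_ids[i])
    return [sorted(f) for f in folds]
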
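"""Classification metrics, ROC/AUC, modality ablation and the sparse
attribution-validated classifier.

AUC is computed by sweeping thresholds over the grouped unique scores and
applying the trapezoidal rule sum_i (FPR_{i+1}-FPR_i)(TPR_{i+1}+TPR_i)/2,
which equals the Mann-Whitney concordance probability with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import OmicsMatrix
from .pairing import PairingPlan


class EvaluationError(ValueError):
    pass


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc_points: List[Tuple[float, float]]
    threshold: float
    undefined_flags: Tuple[str, ...] = ()

    def to_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "threshold": self.threshold,
        }


def confusion_counts(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Tuple[int, int, int, int]:
    """Counts with score >= threshold predicting the positive (case) class."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise EvaluationError("scores and labels must have equal length")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, tn, fp, fn


def classification_metrics(
    tp: int, tn: int, fp: int, fn: int
) -> Tuple[Dict[str, float], Tuple[str, ...]]:
    """Accuracy, precision, recall (TPR) and F1; zero denominators give 0
    with a flag naming the undefined metric."""
    n = tp + tn + fp + fn
    if n == 0:
        raise EvaluationError("no evaluated instances")
    if min(tp, tn, fp, fn) < 0:
        raise EvaluationError("confusion counts must be nonnegative")
    flags: List[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / n
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    if precision + recall == 0:
        flags.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return (
        {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1},
        tuple(flags),
    )


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, List[Tuple[float, float]]]:
    """Trapezoidal AUC over the threshold sweep; equal scores form one step."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    points: List[Tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group tied scores into one step
            j += 1
        tp += int((y[i:j] == 1).sum())
        fp += int((y[i:j] == 0).sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (f0, t0), (f1, t1) in zip(points[:-1], points[1:]):
        auc += (f1 - f0) * (t1 + t0) / 2.0
    return auc, points


def metrics_report(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    tp, tn, fp, fn = confusion_counts(scores, labels, threshold)
    metrics, flags = classification_metrics(tp, tn, fp, fn)
    auc, points = roc_auc(scores, labels)
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=metrics["accuracy"], precision=metrics["precision"],
        recall=metrics["recall"], f1=metrics["f1"],
        auc=auc, roc_points=points, threshold=threshold,
        undefined_flags=flags,
    )


def predict_pairs(
    model, rna: OmicsMatrix, meth: OmicsMatrix, plan: PairingPlan, batch_size: int = 256
) -> Tuple[np.ndarray, np.ndarray]:
    """Score every pair in a plan; returns (probabilities, labels)."""
    rna_idx = rna.sample_index([p[0] for p in plan.pairs])
    meth_idx = meth.sample_index([p[1] for p in plan.pairs])
    labels = np.array([p[2] for p in plan.pairs], dtype=int)
    probs = np.empty(len(plan.pairs))
    for start in range(0, len(plan.pairs), batch_size):
        sl = slice(start, start + batch_size)
        probs[sl] = model.predict_proba(
            rna.values[rna_idx[sl]], meth.values[meth_idx[sl]]
        )
    return probs, labels


def evaluate_pairs(
    model, rna: OmicsMatrix, meth: OmicsMatrix, plan: PairingPlan,
    threshold: float = 0.5,
) -> Dict[str, MetricsReport]:
    """Per-pair metrics (default surface) plus a per-expression-sample view
    where each sample's score is its mean probability over its test pairs."""
    probs, labels = predict_pairs(model, rna, meth, plan)
    per_pair = metrics_report(probs, labels, threshold)
    df = plan.to_frame()
    df["prob"] = probs
    by_sample = df.groupby("rna_id").agg(prob=("prob", "mean"), label=("label", "first"))
    per_sample = metrics_report(
        by_sample["prob"].to_numpy(), by_sample["label"].to_numpy(), threshold
    )
    return {"per_pair": per_pair, "per_sample": per_sample}


# -- modality ablation ---------------------------------------------------------

def modality_ablation(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    arch_config,
    train_config,
    test_fraction: float = 0.2,
    include_cv: bool = False,
    conditions: Sequence[str] = ("fused", "rna_only", "meth_only"),
) -> pd.DataFrame:
    """Train fused, expression-only and methylation-only models under the
    same seed/config and tabulate held-out test metrics (plus, optionally,
    the k-fold cross-validation mean of each metric).

    Single-modality runs feed the withheld channel an all-zero placeholder
    and drop its reconstruction/cycle loss terms, keeping the architecture
    (and parameter count) identical across conditions.
    """
    from dataclasses import replace as dc_replace

    from .training import cross_validate, train_test_run

    rows = []
    for condition in conditions:
        w = list(arch_config.loss_weights)
        rna_c, meth_c = rna, meth
        if condition == "rna_only":
            meth_c = _zeroed(meth)
            w[2] = w[4] = 0.0  # drop methylation recon + cycle terms
        elif condition == "meth_only":
            rna_c = _zeroed(rna)
            w[1] = w[3] = 0.0
        elif condition != "fused":
            raise EvaluationError(f"unknown ablation condition {condition!r}")
        cfg = dc_replace(arch_config, loss_weights=tuple(w))
        result = train_test_run(rna_c, meth_c, cfg, train_config, test_fraction=test_fraction)
        report = result["test_metrics"]["per_pair"]
        row = {"condition": condition, **report.to_dict()}
        if include_cv:
            _, summary = cross_validate(rna_c, meth_c, cfg, train_config)
            row.update({f"cv_{k}": m for k, (m, _) in summary.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _zeroed(matrix: OmicsMatrix) -> OmicsMatrix:
    from dataclasses import replace as dc_replace

    return dc_replace(matrix, values=np.zeros_like(matrix.values))


# -- sparse classifier on top-ranked features ----------------------------------

def _pair_design(
    rna: OmicsMatrix, meth: OmicsMatrix, plan: PairingPlan,
    rna_cols: np.ndarray, meth_cols: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    rna_idx = rna.sample_index([p[0] for p in plan.pairs])
    meth_idx = meth.sample_index([p[1] for p in plan.pairs])
    x = np.hstack(
        [rna.values[np.ix_(rna_idx, rna_cols)], meth.values[np.ix_(meth_idx, meth_cols)]]
    )
    y = np.array([p[2] for p in plan.pairs], dtype=int)
    return x, y


def feature_subset_classifier(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    train_plan: PairingPlan,
    test_plan: PairingPlan,
    ranked_features: Sequence[Tuple[str, str]],
    k: int = 200,
    seed: int = 0,
) -> MetricsReport:
    """L2 logistic regression on the top-k attributed features.

    ``ranked_features`` is a descending-importance list of (feature_id,
    modality) with modality in {expression, methylation}; the pair-level
    design matrix concatenates the selected expression and methylation
    columns of each pair.
    """
    from sklearn.linear_model import LogisticRegression

    total = rna.n_features + meth.n_features
    if k > len(ranked_features):
        raise EvaluationError(f"k={k} exceeds {len(ranked_features)} ranked features")
    if k > total:
        raise EvaluationError(f"k={k} exceeds {total} available features")
    top = list(ranked_features[:k])
    rna_lookup = {f: j for j, f in enumerate(rna.feature_ids)}
    meth_lookup = {f: j for j, f in enumerate(meth.feature_ids)}
    rna_cols = np.array([rna_lookup[f] for f, m in top if m == "expression"], dtype=int)
    meth_cols = np.array([meth_lookup[f] for f, m in top if m == "methylation"], dtype=int)

    x_train, y_train = _pair_design(rna, meth, train_plan, rna_cols, meth_cols)
    x_test, y_test = _pair_design(rna, meth, test_plan, rna_cols, meth_cols)
    clf = LogisticRegression(penalty="l2", C=1.0, max_iter=2000, random_state=seed)
    clf.fit(x_train, y_train)
    return metrics_report(clf.predict_proba(x_test)[:, 1], y_test)


def comparator_rankings(
    rna: OmicsMatrix, meth: OmicsMatrix, train_plan: PairingPlan, seed: int = 0
) -> Dict[str, List[Tuple[str, str]]]:
    """Baseline feature rankings: random order, variance, univariate F-score.

    Computed on the training pairs only, per modality, then interleaved by
    rank so the top-k mixes both modalities like the attribution ranking.
    """
    from sklearn.feature_selection import f_classif

    rng = np.random.default_rng(seed)
    rna_idx = rna.sample_index(sorted(train_plan.rna_ids()))
    meth_idx = meth.sample_index(sorted(train_plan.meth_ids()))
    blocks = {
        "expression": (rna.values[rna_idx], rna.labels[rna_idx], rna.feature_ids),
        "methylation": (meth.values[meth_idx], meth.labels[meth_idx], meth.feature_ids),
    }
    out: Dict[str, List[Tuple[str, str]]] = {}
    for name in ("random", "variance", "f_score"):
        per_mod = {}
        for mod, (x, y, feats) in blocks.items():
            if name == "random":
                score = rng.random(x.shape[1])
            elif name == "variance":
                score = x.var(axis=0)
            else:
                score = np.nan_to_num(f_classif(x, y)[0])
            order = np.argsort(-score)
            per_mod[mod] = [(feats[j], mod) for j in order]
        interleaved: List[Tuple[str, str]] = []
        for a, b in zip(per_mod["expression"], per_mod["methylation"]):
            interleaved.extend([a, b])
        out[name] = interleaved
    return out


def pca_subset_classifier(
    rna: OmicsMatrix,
    meth: OmicsMatrix,
    train_plan: PairingPlan,
    test_plan: PairingPlan,
    n_components: int = 50,
    seed: int = 0,
) -> MetricsReport:
    """Comparator: logistic regression on the top principal components of the
    pair-level concatenated feature matrix."""
    from sklearn.decomposition import PCA
    from sklearn.linear_model import LogisticRegression

    all_rna = np.arange(rna.n_features)
    all_meth = np.arange(meth.n_features)
    x_train, y_train = _pair_design(rna, meth, train_plan, all_rna, all_meth)
    x_test, y_test = _pair_design(rna, meth, test_plan, all_rna, all_meth)
    n_components = min(n_components, min(x_train.shape) - 1)
    pca = PCA(n_components=n_components, random_state=seed)
    z_train = pca.fit_transform(x_train)
    z_test = pca.transform(x_test)
    clf = LogisticRegression(penalty="l2", C=1.0, max_iter=2000, random_state=seed)
    clf.fit(z_train, y_train)
    return metrics_report(clf.predict_proba(z_test)[:, 1], y_test)
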
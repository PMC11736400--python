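"""Clustering-as-classifier evaluation of candidate signatures.

A signature is judged by how well unsupervised hierarchical clustering
(Euclidean distance, tree cut at two clusters) of the feature-restricted
matrix recovers the two study groups: the cluster→label assignment that
maximises accuracy is taken, and the accuracy is referred to an exact
binomial null at the No-Information Rate (the majority-class proportion),
with an exact Clopper–Pearson 95% interval. A grid search evaluates every
subset of a small candidate list this way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .containers import Contrast, OmicsMatrix, SampleSheet, contrast_arrays
from .selection import FeatureSignature


@dataclass
class SignatureEvaluation:
    """Classification metrics of one signature under one contrast."""

    features: list[str]
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    ci_low: float
    ci_high: float
    nir: float
    p_acc_gt_nir: float
    sensitivity: float
    specificity: float
    level: str  # replicate | subject

    def to_dict(self) -> dict:
        return asdict(self)


def nir(labels) -> float:
    """No-Information Rate: the majority-class proportion."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("nir requires non-empty labels")
    _, counts = np.unique(labels, return_counts=True)
    return float(counts.max() / labels.size)


def binomial_acc_test(correct: int, n: int, nir_: float) -> float:
    """One-sided exact binomial p for accuracy exceeding the NIR:
    P(X >= correct), X ~ Binomial(n, nir)."""
    if not 0 <= correct <= n:
        raise ValueError("need 0 <= correct <= n")
    if not 0.0 < nir_ < 1.0:
        raise ValueError("nir must lie in (0, 1)")
    return float(stats.binom.sf(correct - 1, n, nir_))


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


def cluster_classify(
    m: OmicsMatrix,
    features: list[str],
    sheet: SampleSheet,
    contrast: Contrast,
    linkage: str = "complete",
) -> SignatureEvaluation:
    """Evaluate a signature by 2-cluster hierarchical clustering.

    Agglomerative clustering (Euclidean distance, ``linkage`` criterion)
    on the feature-restricted normalised matrix, cut into two clusters;
    clusters are mapped to the contrast's labels by whichever of the two
    assignments maximises accuracy. The positive (disease) class defines
    sensitivity. The evaluation level is inferred from the data: replicate
    when any subject contributes more than one observation, else subject.
    """
    sub = m.subset_features(features)
    X, y, obs, subjects = contrast_arrays(sub, sheet, contrast)
    for cls, grp in ((1, sorted(contrast.positive)), (0, sorted(contrast.negative))):
        if (y == cls).sum() < 2:
            raise ValueError(f"class {grp} has fewer than 2 observations")
    Z = scipy_linkage(X, method=linkage, metric="euclidean")
    clusters = fcluster(Z, t=2, criterion="maxclust")

    best = None
    for positive_cluster in (1, 2):
        pred = (clusters == positive_cluster).astype(int)
        acc = float((pred == y).mean())
        if best is None or acc > best[0]:
            best = (acc, pred)
    acc, pred = best

    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    correct = tp + tn
    nir_ = nir(y)
    lo, hi = clopper_pearson(correct, n)
    level = "replicate" if pd.Series(subjects).duplicated().any() else "subject"
    return SignatureEvaluation(
        features=list(features),
        n=n,
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=correct / n,
        ci_low=lo, ci_high=hi,
        nir=nir_,
        p_acc_gt_nir=binomial_acc_test(correct, n, nir_),
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        level=level,
    )


def grid_search(
    m: OmicsMatrix,
    candidates: list[str],
    sheet: SampleSheet,
    contrast: Contrast,
    max_subset_size: int | None = None,
    linkage: str = "complete",
) -> tuple[FeatureSignature, SignatureEvaluation, pd.DataFrame]:
    """Exhaustively evaluate every non-empty candidate subset.

    Limited to 12 candidates (4095 subsets). The winner maximises
    accuracy; ties break toward the smaller subset, then lexicographic
    feature order — making the result invariant to candidate input order.
    Returns the winning signature, its evaluation, and the full
    leaderboard.
    """
    if not 1 <= len(candidates) <= 12:
        raise ValueError(
            f"grid_search takes 1-12 candidates, got {len(candidates)}; "
            "pre-filter the candidate list first"
        )
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidates must be unique")
    max_subset_size = max_subset_size or len(candidates)
    pool = sorted(candidates)
    rows = []
    best: tuple | None = None
    for size in range(1, min(max_subset_size, len(pool)) + 1):
        for subset in itertools.combinations(pool, size):
            ev = cluster_classify(m, list(subset), sheet, contrast, linkage=linkage)
            rows.append({"features": ";".join(subset), "size": size,
                         "accuracy": ev.accuracy, "p_acc_gt_nir": ev.p_acc_gt_nir,
                         "sensitivity": ev.sensitivity, "specificity": ev.specificity})
            key = (-ev.accuracy, size, subset)
            if best is None or key < best[0]:
                best = (key, subset, ev)
    _, subset, ev = best
    leaderboard = pd.DataFrame(rows).sort_values(
        ["accuracy", "size", "features"], ascending=[False, True, True]
    ).reset_index(drop=True)
    sig = FeatureSignature(list(subset), "grid", {"linkage": linkage,
                                                  "accuracy": ev.accuracy})
    return sig, ev, leaderboard


def clustering_agreement(partition_a, partition_b) -> tuple[float, float]:
    """Adjusted Rand index and normalised mutual information between two
    partitions of the same elements."""
    a = np.asarray(partition_a)
    b = np.asarray(partition_b)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same elements")
    return (
        float(adjusted_rand_score(a, b)),
        float(normalized_mutual_info_score(a, b)),
    )


def pca_scores(m: OmicsMatrix, n_components: int) -> pd.DataFrame:
    """Principal-component scores by SVD of the column-centred matrix.

    Components are ordered by decreasing explained variance; signs follow
    the convention that each loading vector's largest-magnitude entry is
    positive, making the output deterministic.
    """
    X = m.values.to_numpy(dtype=float)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min matrix dimension {min(X.shape)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :n_components] * S[:n_components]
    return pd.DataFrame(
        scores,
        index=m.observation_ids,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
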
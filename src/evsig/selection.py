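"""Triple-algorithm feature selection and consensus.

Three complementary selectors produce candidate marker sets — a serial
k-nearest-neighbour sweep over (k, number of top-ranked features), an
L1-penalised logistic regression, and random-forest impurity importance —
and their intersection forms the consensus signature. When the strict
intersection is empty a lenient set (union of pairwise intersections) is
offered instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import Contrast, OmicsMatrix, SampleSheet, contrast_arrays
from .differential import moderated_t_test

log = logging.getLogger(__name__)


@dataclass
class FeatureSignature:
    """An ordered candidate marker set with its provenance."""

    features: list[str]
    source: str  # knn | lasso | forest | consensus | lenient | grid
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("signature features must be unique")


@dataclass
class SerialKnnResult:
    """Full (k, N) score grid of the serial kNN sweep."""

    grid: pd.DataFrame  # columns: k, n, score
    best_k: int
    best_n: int
    best_score: float
    metric: str
    ranked_features: list[str]

    @property
    def signature(self) -> FeatureSignature:
        return FeatureSignature(
            features=self.ranked_features[: self.best_n],
            source="knn",
            params={"k": self.best_k, "n": self.best_n, "metric": self.metric,
                    "score": self.best_score},
        )


def rank_features_by_de(
    m: OmicsMatrix, sheet: SampleSheet, contrast: Contrast
) -> list[str]:
    """Features ordered by moderated-t p-value ascending (ties by id)."""
    records = moderated_t_test(m, sheet, contrast)
    return [r.feature_id for r in sorted(records, key=lambda r: (r.p_value, r.feature_id))]


def _knn_votes(
    D: np.ndarray, y: np.ndarray, k: int, exclude: list[np.ndarray]
) -> np.ndarray:
    """Leave-out kNN vote fractions.

    ``exclude[i]`` is the boolean mask of training rows withheld when
    observation i is the test point (itself, plus same-subject replicates
    under leave-one-subject-out). Distance ties are broken toward the
    lowest observation index (stable sort on (distance, index))."""
    n = D.shape[0]
    votes = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        cand = idx[~exclude[i]]
        order = np.lexsort((cand, D[i, cand]))
        nearest = cand[order[:k]]
        votes[i] = y[nearest].mean()
    return votes


def serial_knn(
    m: OmicsMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    k_values=(1, 3, 5, 7),
    n_values=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10),
    metric: str = "accuracy",
    cv_mode: str = "loso",
    ranked_features: list[str] | None = None,
) -> SerialKnnResult:
    """Sweep a kNN classifier over neighbourhood size k and signature size N.

    Features are ranked by differential-abundance significance; at each
    grid point the top-N features feed a k-nearest-neighbour classifier
    (Euclidean distance) evaluated by cross-validation: leave-one-subject-out
    (``loso``, default — technical replicates of one subject never straddle
    train/test) or leave-one-observation-out (``loo``, the
    replicate-as-independent convention). Ties in the grid argmax break
    toward smaller N, then smaller k. Only odd k are accepted, so votes
    never tie.
    """
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    if cv_mode not in ("loso", "loo"):
        raise ValueError("cv_mode must be 'loso' or 'loo'")
    for k in k_values:
        if k % 2 == 0:
            raise ValueError(f"k values must be odd, got {k}")
    if ranked_features is None:
        ranked_features = rank_features_by_de(m, sheet, contrast)
    X, y, obs, subjects = contrast_arrays(m.subset_features(ranked_features), sheet, contrast)
    n = len(obs)
    if cv_mode == "loso":
        exclude = [subjects == subjects[i] for i in range(n)]
    else:
        exclude = [np.arange(n) == i for i in range(n)]

    rows = []
    D = np.zeros((n, n))
    from .differential import roc_auc as _auc

    max_n = X.shape[1]
    n_prev = 0
    for N in sorted(set(n_values)):
        if N > max_n:
            log.info("serial_knn: skipping N=%d (> %d available features)", N, max_n)
            continue
        for j in range(n_prev, N):
            col = X[:, j]
            D += (col[:, None] - col[None, :]) ** 2
        n_prev = N
        for k in sorted(set(k_values)):
            max_train = min((~e).sum() for e in exclude)
            if k > max_train:
                log.info("serial_knn: skipping k=%d (only %d training rows)", k, max_train)
                continue
            votes = _knn_votes(D, y, k, exclude)
            if metric == "accuracy":
                score = float(((votes > 0.5).astype(int) == y).mean())
            else:
                score = _auc(votes, y)
            rows.append({"k": k, "n": N, "score": score})

    grid = pd.DataFrame(rows)
    if grid.empty:
        raise ValueError("serial_knn: empty grid (all cells skipped)")
    best = grid.sort_values(["score", "n", "k"], ascending=[False, True, True]).iloc[0]
    return SerialKnnResult(
        grid=grid.reset_index(drop=True),
        best_k=int(best["k"]),
        best_n=int(best["n"]),
        best_score=float(best["score"]),
        metric=metric,
        ranked_features=list(ranked_features),
    )


# ---------------------------------------------------------------------------
# LASSO logistic regression

def lasso_lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that shrinks every coefficient to zero.

    For standardised X and the intercept-only null fit (p̄ = mean(y)),
    this is max_j |Σ_i x_ij (y_i − p̄)|.
    """
    pbar = y.mean()
    return float(np.abs(X.T @ (y - pbar)).max())


def lasso_logistic(
    m: OmicsMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    n_lambda: int = 30,
    cv_folds: int = 5,
    rule: str = "min",
    seed: int = 0,
    lambda_values: list[float] | None = None,
) -> FeatureSignature:
    """L1-penalised logistic regression with cross-validated penalty choice.

    Features are standardised internally (selection is therefore invariant
    to feature rescaling). A decreasing lambda path from the full-shrinkage
    point is scored by ``cv_folds``-fold cross-validated binomial deviance;
    the returned signature holds the features with non-zero coefficients at
    the chosen lambda (rule ``min``: lowest mean deviance; ``1se``: largest
    lambda within one standard error of it).
    """
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    X, y, _, _ = contrast_arrays(m, sheet, contrast)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    yf = y.astype(float)

    if lambda_values is None:
        lmax = lasso_lambda_max(Xs, yf)
        lambdas = np.geomspace(lmax, max(lmax * 1e-3, 1e-10), n_lambda)
    else:
        lambdas = np.sort(np.asarray(lambda_values, dtype=float))[::-1]

    def fit_path(Xtr, ytr):
        # liblinear penalises the intercept; a large intercept_scaling makes
        # that penalty negligible, keeping the full-shrinkage point at the
        # analytic lambda_max
        est = LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=1000, tol=1e-6,
            fit_intercept=True, intercept_scaling=1000.0, random_state=seed,
        )
        coefs = []
        for lam in lambdas:
            est.C = 1.0 / lam
            est.fit(Xtr, ytr)
            coefs.append((est.coef_.ravel().copy(), float(est.intercept_[0])))
        return coefs

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    dev = np.zeros((cv_folds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(Xs, y)):
        for li, (w, b) in enumerate(fit_path(Xs[tr], y[tr])):
            eta = Xs[te] @ w + b
            # mean binomial deviance on the held-out fold
            ll = yf[te] * eta - np.logaddexp(0.0, eta)
            dev[f, li] = float(-2.0 * ll.mean())
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / math.sqrt(cv_folds)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_sel = i_min
    else:
        ok = np.where(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
        i_sel = int(ok.min())  # lambdas are decreasing: min index = largest lambda
    lam_sel = float(lambdas[i_sel])

    final = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=1.0 / lam_sel, max_iter=2000,
        tol=1e-8, fit_intercept=True, intercept_scaling=1000.0,
        random_state=seed,
    ).fit(Xs, y)
    coef = final.coef_.ravel()
    order = np.argsort(-np.abs(coef), kind="stable")
    feats = [m.feature_ids[j] for j in order if abs(coef[j]) > 1e-10]
    return FeatureSignature(
        features=feats,
        source="lasso",
        params={"lambda": lam_sel, "rule": rule, "n_lambda": len(lambdas),
                "cv_folds": cv_folds},
    )


# ---------------------------------------------------------------------------
# random-forest importance

def forest_importance(
    m: OmicsMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    n_trees: int = 500,
    top_fraction: float = 0.10,
    seed: int = 0,
) -> FeatureSignature:
    """Top ``ceil(top_fraction · G)`` features by random-forest
    mean-impurity-decrease importance. Deterministic for a fixed seed;
    importance ties break toward the earlier feature."""
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    X, y, _, _ = contrast_arrays(m, sheet, contrast)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp = rf.feature_importances_
    n_top = math.ceil(top_fraction * m.n_features)
    order = np.argsort(-imp, kind="stable")[:n_top]
    return FeatureSignature(
        features=[m.feature_ids[j] for j in order],
        source="forest",
        params={"n_trees": n_trees, "top_fraction": top_fraction},
    )


# ---------------------------------------------------------------------------
# consensus

def consensus(signatures: list[FeatureSignature]) -> tuple[FeatureSignature, FeatureSignature]:
    """Strict and lenient agreement across selectors.

    Strict: features present in every signature, ordered by mean rank
    across the sources (then by id). Lenient (the fallback when the strict
    intersection is empty): the union of all pairwise intersections — any
    feature at least two selectors agree on — with the same ordering.
    Returns ``(strict, lenient)``.
    """
    if len(signatures) < 2:
        raise ValueError("consensus requires at least 2 signatures")
    sets = [set(s.features) for s in signatures]
    strict = set.intersection(*sets)
    pairwise: set[str] = set()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise |= sets[i] & sets[j]

    def mean_rank(f: str) -> float:
        ranks = [s.features.index(f) for s in signatures if f in s.features]
        return float(np.mean(ranks))

    def ordered(fs: set[str]) -> list[str]:
        return sorted(fs, key=lambda f: (mean_rank(f), f))

    sources = [s.source for s in signatures]
    strict_sig = FeatureSignature(ordered(strict), "consensus", {"sources": sources})
    lenient_sig = FeatureSignature(ordered(pairwise), "lenient", {"sources": sources})
    return strict_sig, lenient_sig
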
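"""Differential abundance and classical statistics.

The workhorse is an empirical-Bayes moderated two-sample t-test: each
feature's sample variance is shrunk toward a prior variance estimated
from all features by moment matching on the log-variance scale, and the
resulting t-statistic gains the prior degrees of freedom. With thousands
of features and few subjects this stabilises the denominators of
low-variance features and is the standard approach in omics differential
expression.

Also provided: Mann-Whitney U, Spearman correlation, rank-based ROC-AUC,
one-way ANOVA recomputed from per-group summary statistics, and Pearson's
chi-squared — the classical tests used for cohort demographics and
marker-level comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import Contrast, OmicsMatrix, SampleSheet, contrast_arrays

P_THRESHOLD = 0.05  # unadjusted significance threshold


@dataclass
class DERecord:
    """Per-feature differential-abundance result.

    ``log2_fc`` is the positive-group minus negative-group mean in
    normalised log2 space; ``t_mod`` the moderated t; ``direction`` the
    sign of the fold change.
    """

    feature_id: str
    log2_fc: float
    t_mod: float
    p_value: float
    direction: str
    significant: bool
    se: float = float("nan")  # posterior standard error of log2_fc
    df: float = float("nan")  # total degrees of freedom (prior + residual)

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the log2 fold change from the moderated
        posterior standard error and total degrees of freedom."""
        if math.isinf(self.df):
            q = stats.norm.ppf(0.5 + level / 2)
        else:
            q = stats.t.ppf(0.5 + level / 2, self.df)
        return self.log2_fc - q * self.se, self.log2_fc + q * self.se


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return polygamma(1, x)


def trigamma_inverse(x: float, max_iter: int = 50, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Returns ``inf`` for x <= 0 (trigamma is positive and decreasing).
    """
    if x <= 0:
        return math.inf
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(_trigamma(y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of the prior df d0 and prior variance s0².

    Works on e_g = log s_g² − ψ(d_g/2) + log(d_g/2), whose mean and excess
    spread identify the scaled-inverse-chi-squared prior: d0 solves
    ψ′(d0/2) = mean[(e_g − ē)²·G/(G−1) − ψ′(d_g/2)], clamped to +∞ when
    the right-hand side is non-positive (no excess spread → infinite
    shrinkage), and log s0² = ē + ψ(d0/2) − log(d0/2).

    Zero variances are excluded from the moment estimation.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.exp(np.log(s2[ok]).mean())) if ok.any() else 0.0
    s2o, dfo = s2[ok], df[ok]
    e = np.log(s2o) - digamma(dfo / 2.0) + np.log(dfo / 2.0)
    ebar = float(e.mean())
    G = e.size
    rhs = float(np.mean((e - ebar) ** 2 * G / (G - 1) - _trigamma(dfo / 2.0)))
    if rhs <= 0:
        d0 = math.inf
        log_s02 = ebar
    else:
        d0 = 2.0 * trigamma_inverse(rhs)
        log_s02 = ebar + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    return d0, float(np.exp(log_s02))


def moderated_t_test(
    m: OmicsMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    prior_df: float | None = None,
    p_threshold: float = P_THRESHOLD,
    adjust: str | None = None,
) -> list[DERecord]:
    """Empirical-Bayes moderated two-sample t-test per feature.

    Requires the normalised_log layer and at least 2 observations per
    group. ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary pooled-variance t exactly; ``inf`` uses the common prior
    variance for every feature). ``adjust='bh'`` applies
    Benjamini-Hochberg to the significance calls (off by default: the
    significance convention here is the unadjusted p < 0.05).
    """
    if m.layer != "normalised_log":
        raise ValueError(f"moderated_t_test expects the normalised_log layer, got {m.layer!r}")
    X, y, _, _ = contrast_arrays(m, sheet, contrast)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    for n, grp in ((n1, sorted(contrast.positive)), (n0, sorted(contrast.negative))):
        if n < 2:
            raise ValueError(f"group {grp} has {n} observation(s); need at least 2")

    X1, X0 = X[y == 1], X[y == 0]
    mean1, mean0 = X1.mean(axis=0), X0.mean(axis=0)
    diff = mean1 - mean0
    dg = float(n1 + n0 - 2)
    s2 = (((X1 - mean1) ** 2).sum(axis=0) + ((X0 - mean0) ** 2).sum(axis=0)) / dg

    df_arr = np.full_like(s2, dg)
    if prior_df is None:
        d0, s02 = estimate_variance_prior(s2, df_arr)
    else:
        d0 = float(prior_df)
        _, s02 = estimate_variance_prior(s2, df_arr)
    if d0 == 0:
        s2_post = s2
        df_total = dg
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    if adjust == "bh":
        sig = _bh_reject(p, p_threshold)
    else:
        sig = p < p_threshold

    records = []
    for j, fid in enumerate(m.feature_ids):
        records.append(
            DERecord(
                feature_id=fid,
                log2_fc=float(diff[j]),
                t_mod=float(t[j]),
                p_value=float(p[j]),
                direction="up" if diff[j] >= 0 else "down",
                significant=bool(sig[j]),
                se=float(se[j]),
                df=float(df_total),
            )
        )
    return records


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    out = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.where(passed)[0])
        out[order[: k + 1]] = True
    return out


def de_table(records: list[DERecord]) -> pd.DataFrame:
    """DE results as a volcano-ready table (adds −log10 p)."""
    df = pd.DataFrame(
        {
            "feature": [r.feature_id for r in records],
            "log2FC": [r.log2_fc for r in records],
            "t": [r.t_mod for r in records],
            "p": [r.p_value for r in records],
            "significant": [r.significant for r in records],
        }
    )
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# classical tests

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    W counts pairs (i, j) with x_i > y_j, plus half of the ties. The p is
    exact by enumeration for n1·n2 ≤ 400 without ties, otherwise the
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (Pearson on mid-ranks) with t-approximate p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length vectors of length >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores, labels) -> float:
    """Probability a positive outscores a negative (ties count half).

    Equivalent to the scaled Mann-Whitney statistic
    W(positives, negatives) / (n₊·n₋), computed from mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    wins = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(wins / (pos.size * neg.size))


def anova_from_summary(ns, means, sds) -> tuple[float, int, int]:
    """One-way ANOVA F recomputed from group sizes, means and SDs.

    F = [Σ nᵢ(x̄ᵢ − x̄)²/(k−1)] / [Σ (nᵢ−1)sᵢ²/(N−k)]; returns
    (F, df_between, df_within). Lets a reader audit a demographics table
    that prints only summary statistics.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if ns.size < 2:
        raise ValueError("anova_from_summary requires at least 2 groups")
    if (ns < 2).any():
        raise ValueError("anova_from_summary requires n >= 2 in every group")
    k = ns.size
    N = float(ns.sum())
    grand = float((ns * means).sum() / N)
    ms_between = float((ns * (means - grand) ** 2).sum() / (k - 1))
    ms_within = float(((ns - 1) * sds**2).sum() / (N - k))
    return ms_between / ms_within, int(k - 1), int(N - k)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence on a 2-D count table
    (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ValueError("chi_square_test requires a 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("all row and column margins must be positive")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
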
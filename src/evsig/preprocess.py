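"""Preprocessing chain for EV feature tables.

Fixed stage order: identification filtering (done at read time) →
missingness filter (features missing in more than 40% of observations
are dropped) → immunoglobulin removal (abundant plasma proteins that mask
low-abundance EV cargo) → iterative random-forest imputation →
log2 transform with per-observation median centring → optional technical
replicate averaging to subject level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .containers import OmicsMatrix, SampleSheet

log = logging.getLogger(__name__)

#: gene-symbol prefixes treated as immunoglobulins (case-insensitive).
#: Configurable; no canonical list exists for this filter.
IG_PATTERNS = ("IGH", "IGK", "IGL", "IGJ", "JCHAIN")


def filter_missing(m: OmicsMatrix, max_fraction: float = 0.40) -> OmicsMatrix:
    """Drop features whose missing fraction strictly exceeds ``max_fraction``.

    The boundary case (missing fraction exactly equal to the threshold) is
    retained. Survivor order is preserved. Idempotent.
    """
    if m.n_observations == 0:
        return m.copy()
    frac = m.values.isna().mean(axis=0)
    keep = [f for f in m.feature_ids if frac[f] <= max_fraction]
    out = m.subset_features(keep)
    log.info("filter_missing: %d -> %d features (threshold > %.2f)",
             m.n_features, out.n_features, max_fraction)
    return out


def remove_immunoglobulins(
    m: OmicsMatrix, patterns: tuple[str, ...] = IG_PATTERNS
) -> tuple[OmicsMatrix, list[str]]:
    """Remove features whose id starts with an immunoglobulin prefix
    (case-insensitive). Returns the filtered matrix and the removal report.
    Idempotent."""
    pats = tuple(p.upper() for p in patterns)
    removed = [f for f in m.feature_ids if f.upper().startswith(pats)]
    keep = [f for f in m.feature_ids if f not in set(removed)]
    log.info("remove_immunoglobulins: removed %d of %d features", len(removed), m.n_features)
    return m.subset_features(keep), removed


def impute_random_forest(
    m: OmicsMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> OmicsMatrix:
    """Iterative random-forest imputation of missing entries (missForest
    scheme).

    Missing entries start at their feature mean. Features are then visited
    in order of increasing missingness; each feature with missing entries
    is regressed on all other features with a random-forest regressor fit
    on its observed rows, and its missing entries are re-predicted. The
    loop stops when the sum of squared changes of the imputed values
    increases, or after ``max_iter`` sweeps. Deterministic for a fixed
    seed.

    Imputed values are forest predictions — averages of observed training
    targets — so they always lie within the observed range of the feature.
    """
    vals = m.values.to_numpy(dtype=float).copy()
    miss = np.isnan(vals)
    if not miss.any():
        return m.with_values(m.values.copy(), layer="imputed")
    n_missing_per_feature = miss.sum(axis=0)
    fully_missing = np.where(n_missing_per_feature == vals.shape[0])[0]
    if fully_missing.size:
        name = m.feature_ids[fully_missing[0]]
        raise ValueError(
            f"feature {name!r} has no observed values; apply filter_missing first"
        )

    col_means = np.nanmean(vals, axis=0)
    for j in range(vals.shape[1]):
        vals[miss[:, j], j] = col_means[j]

    order = np.argsort(n_missing_per_feature, kind="stable")
    order = [j for j in order if n_missing_per_feature[j] > 0]
    rng = np.random.default_rng(seed)
    prev_change = math.inf
    prev_vals = vals.copy()
    for it in range(max_iter):
        for j in order:
            obs_rows = ~miss[:, j]
            other = np.delete(np.arange(vals.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(vals[obs_rows][:, other], vals[obs_rows, j])
            vals[miss[:, j], j] = rf.predict(vals[miss[:, j]][:, other])
        change = float(((vals[miss] - prev_vals[miss]) ** 2).sum())
        log.info("impute_random_forest: sweep %d, sum sq change %.4g", it + 1, change)
        if change > prev_change:
            vals = prev_vals  # revert the diverging sweep
            break
        prev_change = change
        prev_vals = vals.copy()
        if change == 0.0:
            break
    out = m.values.copy()
    out.iloc[:, :] = vals
    return m.with_values(out, layer="imputed")


def normalize_and_log(m: OmicsMatrix) -> OmicsMatrix:
    """log2-transform, then centre each observation at its median.

    Per-observation median centring removes sample-loading differences
    (a uniform scaling of one observation becomes an additive log shift,
    which the median removes). Requires the imputed layer and strictly
    positive values.
    """
    vals = m.values.to_numpy(dtype=float)
    bad = np.argwhere(~(vals > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value {vals[i, j]!r} at observation "
            f"{m.observation_ids[i]!r}, feature {m.feature_ids[j]!r}"
        )
    logv = np.log2(vals)
    logv = logv - np.median(logv, axis=1, keepdims=True)
    out = m.values.copy()
    out.iloc[:, :] = logv
    return m.with_values(out, layer="normalised_log")


def average_replicates(m: OmicsMatrix, sheet: SampleSheet) -> tuple[OmicsMatrix, SampleSheet]:
    """Collapse technical replicates to one observation per subject
    (arithmetic mean per feature), mirroring the convention of averaging
    duplicate measurements into a single representative value.

    Excluded observations are dropped before averaging. The returned
    sample sheet has one row per subject, keyed by subject id, with
    replicate_index 1.
    """
    act = sheet.active().set_index("observation_id")
    obs = [o for o in m.observation_ids if o in act.index]
    sub = act.loc[obs, "subject_id"]
    df = m.values.loc[obs].groupby(sub.to_numpy()).mean()
    # keep first-appearance subject order
    seen: list[str] = []
    for s in sub:
        if s not in seen:
            seen.append(s)
    df = df.loc[seen]
    collapsed = m.with_values(df)

    rows = []
    for s in seen:
        r = act.loc[act["subject_id"] == s].iloc[0]
        rows.append({
            "observation_id": s,
            "subject_id": s,
            "group": r["group"],
            "replicate_index": 1,
            "age": r.get("age", np.nan),
        })
    return collapsed, SampleSheet(pd.DataFrame(rows))


@dataclass
class PreprocessReport:
    """Feature counts in/out of each preprocessing stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append({"stage": stage, "features_in": n_in, "features_out": n_out, **extra})
        log.info("%s: %d -> %d features", stage, n_in, n_out)


def preprocess(
    m: OmicsMatrix,
    max_missing_fraction: float = 0.40,
    drop_immunoglobulins: bool | None = None,
    impute_trees: int = 100,
    impute_max_iter: int = 10,
    seed: int = 0,
) -> tuple[OmicsMatrix, PreprocessReport]:
    """Run the full preprocessing chain on one matrix.

    Immunoglobulin removal defaults to on for protein matrices and off for
    metabolite tables. Returns the normalised_log-layer matrix and a
    per-stage feature-count report.
    """
    report = PreprocessReport()
    if drop_immunoglobulins is None:
        drop_immunoglobulins = (m.feature_kind == "protein").all()

    n0 = m.n_features
    m = filter_missing(m, max_missing_fraction)
    report.record("filter_missing", n0, m.n_features, threshold=max_missing_fraction)

    if drop_immunoglobulins:
        n0 = m.n_features
        m, removed = remove_immunoglobulins(m)
        report.record("remove_immunoglobulins", n0, m.n_features, removed=removed)

    n0 = m.n_features
    m = impute_random_forest(m, n_trees=impute_trees, max_iter=impute_max_iter, seed=seed)
    report.record("impute_random_forest", n0, m.n_features, n_trees=impute_trees)

    m = normalize_and_log(m)
    report.record("normalize_and_log", m.n_features, m.n_features,
                  method="log2 + per-observation median centring")
    return m, report
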
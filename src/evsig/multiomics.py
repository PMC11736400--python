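"""Proteo-metabolomic integration.

Integration is deliberately simple concatenation: protein replicates are
averaged to subject level, the subject-aligned protein and metabolite
tables are joined feature-wise, and cross-omic structure is read off a
Spearman similarity matrix of the features (distance 1 − ρ, hierarchical
clustering, tree cut into k partitions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .containers import OmicsMatrix, SampleSheet
from .preprocess import average_replicates


@dataclass
class SimilarityPartition:
    """A k-way partition of features by correlation similarity."""

    feature_ids: list[str]
    labels: dict[str, int]
    k: int
    linkage: str
    distance: str = "1 - spearman rho"


def combine_omics(
    proteins: OmicsMatrix, metabolites: OmicsMatrix, sheet: SampleSheet
) -> tuple[OmicsMatrix, SampleSheet]:
    """Concatenate protein and metabolite features at subject level.

    Either matrix still carrying technical replicates is averaged to one
    observation per subject first. The subject sets must then match
    exactly; a mismatch is rejected naming the differing subjects.
    Feature kinds and classes are preserved.
    """
    if proteins.layer != "normalised_log" or metabolites.layer != "normalised_log":
        raise ValueError("combine_omics expects both matrices in the normalised_log layer")

    def to_subject(m: OmicsMatrix) -> tuple[OmicsMatrix, SampleSheet]:
        act = sheet.active().set_index("observation_id")
        obs = [o for o in m.observation_ids if o in act.index]
        if pd.Series(act.loc[obs, "subject_id"]).duplicated().any():
            return average_replicates(m, sheet)
        # already one observation per subject: re-key by subject id
        vals = m.values.loc[obs].copy()
        vals.index = list(act.loc[obs, "subject_id"])
        sub_sheet = SampleSheet(pd.DataFrame({
            "observation_id": vals.index,
            "subject_id": vals.index,
            "group": act.loc[obs, "group"].to_numpy(),
            "replicate_index": 1,
            "age": act.loc[obs, "age"].to_numpy() if "age" in act.columns else np.nan,
        }))
        return m.with_values(vals), sub_sheet

    p_sub, p_sheet = to_subject(proteins)
    m_sub, _ = to_subject(metabolites)

    p_set, m_set = set(p_sub.observation_ids), set(m_sub.observation_ids)
    if p_set != m_set:
        only_p = sorted(p_set - m_set)
        only_m = sorted(m_set - p_set)
        raise ValueError(
            "subject sets differ between omics: "
            f"proteins-only {only_p}, metabolites-only {only_m}"
        )
    order = p_sub.observation_ids
    values = pd.concat([p_sub.values, m_sub.values.loc[order]], axis=1)
    kind = pd.concat([p_sub.feature_kind, m_sub.feature_kind])
    cls_p = p_sub.feature_class if p_sub.feature_class is not None else pd.Series(
        index=p_sub.values.columns, dtype=object)
    cls_m = m_sub.feature_class if m_sub.feature_class is not None else pd.Series(
        index=m_sub.values.columns, dtype=object)
    combined = OmicsMatrix(
        values=values,
        feature_kind=kind,
        feature_class=pd.concat([cls_p, cls_m]),
        layer="normalised_log",
    )
    return combined, p_sheet


def spearman_similarity_partition(
    m: OmicsMatrix,
    features: list[str] | None = None,
    k: int = 6,
    linkage: str = "complete",
) -> SimilarityPartition:
    """Partition features by hierarchical clustering of 1 − Spearman ρ.

    Anticorrelated features are treated as far apart (the distance is
    1 − ρ, not 1 − |ρ|). A constant feature, whose correlation is
    undefined, is assigned ρ = 0 to every other feature, with a warning.
    Rank-based, hence invariant to strictly monotone transforms of any
    feature.
    """
    sub = m if features is None else m.subset_features(features)
    if not 1 <= k <= sub.n_features:
        raise ValueError(f"need 1 <= k <= {sub.n_features} features, got k={k}")
    vals = sub.values
    const = vals.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant feature(s) {list(vals.columns[const])}: "
            "Spearman correlation undefined, using rho = 0",
            stacklevel=2,
        )
    rho = vals.corr(method="spearman").to_numpy()
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    if sub.n_features == 1:
        labels = np.array([1])
    else:
        Z = scipy_linkage(squareform(dist, checks=False), method=linkage)
        labels = fcluster(Z, t=k, criterion="maxclust")
    return SimilarityPartition(
        feature_ids=sub.feature_ids,
        labels=dict(zip(sub.feature_ids, map(int, labels))),
        k=k,
        linkage=linkage,
    )


def co_partitioned(partition: SimilarityPartition, a: str, b: str) -> bool:
    """True iff features a and b fall in the same partition."""
    for f in (a, b):
        if f not in partition.labels:
            raise KeyError(f"feature {f!r} not in partition")
    return partition.labels[a] == partition.labels[b]


def partition_table(partition: SimilarityPartition, kind: pd.Series | None = None) -> pd.DataFrame:
    """Partition as an exportable table {feature, kind, partition}."""
    df = pd.DataFrame({
        "feature": partition.feature_ids,
        "partition": [partition.labels[f] for f in partition.feature_ids],
    })
    if kind is not None:
        df.insert(1, "kind", [kind.get(f) for f in partition.feature_ids])
    return df
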
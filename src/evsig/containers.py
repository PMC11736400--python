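"""Core in-memory containers for the discovery pipeline.

An :class:`OmicsMatrix` is an observations × features table (LFQ protein
intensities or metabolite concentrations in µM) tagged with a processing
``layer``; a :class:`SampleSheet` maps observations to subjects, study
groups and technical-replicate indices; a :class:`Contrast` names a
two-group comparison and the level (technical replicate vs subject) at
which it is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("primary", "metastatic", "control")
LAYERS = ("raw", "imputed", "normalised_log")
FEATURE_KINDS = ("protein", "metabolite")


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


@dataclass
class OmicsMatrix:
    """Observations × features numeric matrix with per-feature metadata.

    Parameters
    ----------
    values
        DataFrame with observation ids as index and feature ids as columns.
        Missing entries are NaN (only permitted in the ``raw`` layer).
    feature_kind
        Per-feature kind, ``protein`` or ``metabolite``.
    feature_class
        Optional per-feature class label (e.g. ``glycerophospholipid``,
        ``sphingolipid`` for the targeted-metabolomics panel).
    layer
        One of ``raw``, ``imputed``, ``normalised_log``.
    """

    values: pd.DataFrame
    feature_kind: pd.Series
    feature_class: pd.Series | None = None
    layer: str = "raw"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate observation id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        self.feature_kind = pd.Series(self.feature_kind, dtype=object)
        if not self.feature_kind.index.equals(self.values.columns):
            self.feature_kind = self.feature_kind.reindex(self.values.columns)
        bad = set(self.feature_kind.dropna()) - set(FEATURE_KINDS)
        if bad:
            raise ValueError(f"unknown feature kind(s) {sorted(bad)}")
        if self.feature_class is not None:
            self.feature_class = pd.Series(self.feature_class, dtype=object).reindex(
                self.values.columns
            )
        vals = self.values.to_numpy(dtype=float)
        if self.layer != "raw" and np.isnan(vals).any():
            raise ValueError(f"layer {self.layer!r} must not contain missing values")
        if self.layer == "raw":
            observed = vals[~np.isnan(vals)]
            if observed.size and (observed < 0).any():
                raise ValueError("raw-layer values must be >= 0 where observed")

    # -- convenience accessors -------------------------------------------------

    @property
    def observation_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_observations(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [f for f in feature_ids if f not in self.values.columns]
        if missing:
            raise KeyError(f"feature(s) not in matrix: {missing}")
        return OmicsMatrix(
            values=self.values.loc[:, list(feature_ids)].copy(),
            feature_kind=self.feature_kind.loc[list(feature_ids)].copy(),
            feature_class=None
            if self.feature_class is None
            else self.feature_class.loc[list(feature_ids)].copy(),
            layer=self.layer,
        )

    def subset_observations(self, observation_ids: Sequence[str]) -> "OmicsMatrix":
        missing = [o for o in observation_ids if o not in self.values.index]
        if missing:
            raise KeyError(f"observation(s) not in matrix: {missing}")
        return OmicsMatrix(
            values=self.values.loc[list(observation_ids)].copy(),
            feature_kind=self.feature_kind.copy(),
            feature_class=None if self.feature_class is None else self.feature_class.copy(),
            layer=self.layer,
        )

    def with_values(self, values: pd.DataFrame, layer: str | None = None) -> "OmicsMatrix":
        """Return a copy with replaced values (and optionally a new layer)."""
        return OmicsMatrix(
            values=values,
            feature_kind=self.feature_kind.copy(),
            feature_class=None if self.feature_class is None else self.feature_class.copy(),
            layer=self.layer if layer is None else layer,
        )

    def copy(self) -> "OmicsMatrix":
        return self.with_values(self.values.copy())


@dataclass
class SampleSheet:
    """Observation ↔ subject/group/replicate/age metadata.

    ``excluded`` observations (e.g. outlier samples removed from the study)
    never enter analysis operations: :meth:`active` drops them.
    """

    table: pd.DataFrame

    REQUIRED = ("observation_id", "subject_id", "group", "replicate_index")

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        if "age" not in t.columns:
            t["age"] = np.nan
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclusion_reason" not in t.columns:
            t["exclusion_reason"] = ""
        t["excluded"] = t["excluded"].astype(bool)
        if t["observation_id"].duplicated().any():
            dup = t.loc[t["observation_id"].duplicated(), "observation_id"].iloc[0]
            raise ValueError(f"duplicate observation id {dup!r} in sample sheet")
        bad = set(t["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group(s) {sorted(bad)}; expected {GROUPS}")
        self.table = t.reset_index(drop=True)

    def active(self) -> pd.DataFrame:
        """Rows for non-excluded observations."""
        return self.table.loc[~self.table["excluded"]].reset_index(drop=True)

    def observations_in(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        act = self.active()
        return list(act.loc[act["group"].isin(groups), "observation_id"])

    def group_of(self, observation_ids: Sequence[str]) -> pd.Series:
        lookup = self.table.set_index("observation_id")["group"]
        return lookup.loc[list(observation_ids)]

    def subject_of(self, observation_ids: Sequence[str]) -> pd.Series:
        lookup = self.table.set_index("observation_id")["subject_id"]
        return lookup.loc[list(observation_ids)]

    def exclude(self, observation_ids: Sequence[str], reason: str = "") -> "SampleSheet":
        t = self.table.copy()
        mask = t["observation_id"].isin(observation_ids)
        t.loc[mask, "excluded"] = True
        t.loc[mask, "exclusion_reason"] = reason
        return SampleSheet(t)

    def copy(self) -> "SampleSheet":
        return SampleSheet(self.table.copy())


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison.

    ``positive`` minus ``negative`` defines the sign of fold changes;
    ``level`` states whether evaluation treats each technical replicate as
    an observation or collapses to one observation per subject.
    """

    name: str
    positive: frozenset[str]
    negative: frozenset[str]
    level: str = "subject"

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("contrast groups must be non-empty")
        if self.positive & self.negative:
            raise ValueError("contrast groups must be disjoint")
        if self.level not in ("replicate", "subject"):
            raise ValueError("level must be 'replicate' or 'subject'")

    def label_of(self, group: str) -> int | None:
        """+1 for the positive class, 0 for negative, None if outside."""
        if group in self.positive:
            return 1
        if group in self.negative:
            return 0
        return None


#: melanoma (primary + metastatic) versus healthy controls
MELANOMA_VS_CONTROL = Contrast(
    name="melanoma_vs_control",
    positive=frozenset({"primary", "metastatic"}),
    negative=frozenset({"control"}),
)

#: metastatic versus primary disease
METASTATIC_VS_PRIMARY = Contrast(
    name="metastatic_vs_primary",
    positive=frozenset({"metastatic"}),
    negative=frozenset({"primary"}),
)


def contrast_arrays(
    m: OmicsMatrix, sheet: SampleSheet, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Restrict a matrix to a contrast's observations.

    Returns ``(X, y, observation_ids, subject_ids)`` where ``y`` is 1 for
    the positive class. Excluded observations are dropped; observation
    order follows the matrix.
    """
    act = sheet.active().set_index("observation_id")
    obs = [o for o in m.observation_ids if o in act.index]
    labels, kept = [], []
    for o in obs:
        lab = contrast.label_of(act.loc[o, "group"])
        if lab is not None:
            kept.append(o)
            labels.append(lab)
    if not kept:
        raise ValueError(f"no observations fall in contrast {contrast.name!r}")
    X = m.values.loc[kept].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    subjects = act.loc[kept, "subject_id"].to_numpy()
    return X, y, kept, subjects
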
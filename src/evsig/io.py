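"""Readers and writers for feature tables and sample sheets.

Supports the MaxQuant ``proteinGroups.txt`` dialect (tab-delimited, one
``LFQ intensity <observation>`` column per observation, zero meaning "not
quantified") and generic CSV/TSV feature tables where missing values are
empty cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FormatError, OmicsMatrix, SampleSheet

MAXQUANT_REQUIRED = ("Protein IDs", "Reverse", "Potential contaminant")
MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")
LFQ_PREFIX = "LFQ intensity "


def read_maxquant_protein_groups(path: str | Path, filter_ids: bool = True) -> OmicsMatrix:
    """Read a MaxQuant proteinGroups table into a raw-layer protein matrix.

    Features are keyed by gene name, falling back to the protein-group id
    when the gene name is blank. When ``filter_ids`` is set, protein
    groups flagged ``Reverse`` (decoy), ``Potential contaminant`` or
    ``Only identified by site`` are dropped — the standard
    unreliable-identification exclusion. LFQ intensities of 0 are re-coded
    as missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in MAXQUANT_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"proteinGroups file is missing mandatory column {col!r}")
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise FormatError(f"proteinGroups file has no {LFQ_PREFIX!r}* columns")

    if filter_ids:
        keep = np.ones(len(df), dtype=bool)
        for col in MAXQUANT_FLAG_COLUMNS:
            if col in df.columns:
                keep &= df[col].str.strip() != "+"
        df = df.loc[keep]

    gene = df["Gene names"].str.strip() if "Gene names" in df.columns else pd.Series("", index=df.index)
    ids = gene.where(gene != "", df["Protein IDs"].str.strip())
    # first gene symbol of a multi-gene group identifies the feature
    ids = ids.str.split(";").str[0]
    if ids.duplicated().any():
        # disambiguate duplicate gene names with the protein-group id
        dup = ids.duplicated(keep=False)
        ids = ids.where(~dup, ids + "|" + df["Protein IDs"].str.strip())

    obs = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    vals = df[lfq_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float).T
    vals[vals == 0.0] = np.nan  # 0 denotes "not quantified" in this dialect
    values = pd.DataFrame(vals, index=obs, columns=list(ids))
    return OmicsMatrix(
        values=values,
        feature_kind=pd.Series("protein", index=values.columns),
        layer="raw",
    )


def read_feature_table(
    path: str | Path,
    kind: str = "metabolite",
    feature_class: dict[str, str] | None = None,
    layer: str = "raw",
) -> OmicsMatrix:
    """Read a features × observations CSV/TSV table.

    The first column holds feature ids; remaining columns are
    observations. Empty cells are missing; non-numeric cells are rejected
    with their coordinates. A ``class`` column, if present, supplies
    per-feature class labels.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    cls = None
    if "class" in df.columns:
        cls = df["class"]
        df = df.drop(columns=["class"])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate observation id {dup!r} in {path}")
    vals = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            s = raw.strip()
            if s == "":
                continue
            try:
                vals[i, j] = float(s)
            except ValueError:
                raise FormatError(
                    f"non-numeric cell {raw!r} at feature {df.index[i]!r}, "
                    f"observation {col!r} in {path}"
                ) from None
    values = pd.DataFrame(vals.T, index=list(df.columns), columns=list(df.index))
    fclass = None
    if cls is not None:
        fclass = pd.Series(cls.to_numpy(), index=values.columns)
    elif feature_class is not None:
        fclass = pd.Series({f: feature_class.get(f) for f in values.columns})
    return OmicsMatrix(
        values=values,
        feature_kind=pd.Series(kind, index=values.columns),
        feature_class=fclass,
        layer=layer,
    )


def write_feature_table(
    m: OmicsMatrix, path: str | Path, orient: str = "features_by_observations"
) -> None:
    """Write a matrix as CSV/TSV, features as rows by default.

    Values are written with 12 significant digits so a write/read
    round-trip preserves them; missing entries become empty cells.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = m.values.T if orient == "features_by_observations" else m.values
    out = df.copy()
    if orient == "features_by_observations" and m.feature_class is not None:
        out.insert(0, "class", m.feature_class.reindex(out.index))
    out.to_csv(path, sep=sep, float_format="%.12g", na_rep="")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a sample-sheet CSV (observation_id, subject_id, group,
    replicate_index, optional age/excluded columns)."""
    df = pd.read_csv(path)
    return SampleSheet(df)
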
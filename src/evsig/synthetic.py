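"""Seeded generator of study-shaped EV proteomic + metabolomic cohorts.

The study whose design this emulates profiled plasma extracellular-vesicle
(EV) cargo from 24 primary-melanoma, 12 metastatic-melanoma and 13
healthy-control subjects, each measured in technical duplicate: ~257
label-free-quantified proteins and an 88-metabolite targeted panel
dominated by glycerophospholipids (72/88) and sphingolipids (14/88). No
raw data were deposited, so this module generates cohorts with the same
shape and known ground truth (spiked group effects, intensity-dependent
missingness, an age-coupled marker) for calibration and
parameter-recovery testing.

All distributional choices are stand-ins: the source study does not
describe its data distribution, and log-normal intensities/concentrations
are the field convention for LFQ and targeted assays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from .containers import (
    GROUPS,
    Contrast,
    MELANOMA_VS_CONTROL,
    METASTATIC_VS_PRIMARY,
    OmicsMatrix,
    SampleSheet,
)

CONTRASTS: dict[str, Contrast] = {
    MELANOMA_VS_CONTROL.name: MELANOMA_VS_CONTROL,
    METASTATIC_VS_PRIMARY.name: METASTATIC_VS_PRIMARY,
}

#: group-wise age distributions (mean, sd in years), matching the cohort's
#: demographics: both melanoma groups are substantially older than controls.
AGE_PARAMS = {
    "primary": (62.67, 15.66),
    "metastatic": (62.42, 22.48),
    "control": (34.76, 14.07),
}

#: immunoglobulin-style decoy gene names; these are abundant plasma proteins
#: that real EV studies strip out, so the removal filter is testable by name.
IG_PREFIXES = ("IGHG", "IGHA", "IGHM", "IGKC", "IGLC", "IGKV", "IGLV", "JCHAIN")

#: centre of the logistic low-intensity dropout, in global log2 SD units.
MNAR_CENTER = -0.5


@dataclass(frozen=True)
class MarkerEffect:
    """A spiked group effect: ``feature`` is multiplied by ``2**log2fc`` in
    the positive group of ``contrast``."""

    feature: str
    contrast: str
    log2fc: float


#: default spiked markers. Protein markers carry the effect size used
#: throughout the recovery benchmarks (log2FC 1.5 ≈ 2.8-fold); metabolite
#: markers are weaker, and the metastatic-vs-primary contrast is harder
#: (smaller groups), mirroring the study's reported difficulty ordering.
DEFAULT_EFFECTS = (
    MarkerEffect("PRG4", "melanoma_vs_control", 1.5),
    MarkerEffect("APOC4", "melanoma_vs_control", 1.5),
    MarkerEffect("HPR", "melanoma_vs_control", 1.0),
    MarkerEffect("PC ae C34:3", "melanoma_vs_control", -1.0),
    MarkerEffect("lysoPC a C18:2", "melanoma_vs_control", -0.8),
    MarkerEffect("VWF", "metastatic_vs_primary", 1.2),
    MarkerEffect("SERPIND1", "metastatic_vs_primary", 1.0),
    MarkerEffect("PC aa C38:0", "metastatic_vs_primary", 0.8),
    MarkerEffect("PC ae C44:3", "metastatic_vs_primary", 0.8),
)

PROTEIN_MARKERS = ("PRG4", "APOC4", "HPR", "VWF", "SERPIND1")
METABOLITE_MARKERS = ("PC ae C34:3", "lysoPC a C18:2", "PC aa C38:0", "PC ae C44:3")


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the profiled study's design: 24/12/13 subjects in
    technical duplicate, 257 proteins, 88 metabolites (72
    glycerophospholipids, 14 sphingolipids, one biogenic amine, one amino
    acid), intensity-dependent dropout, and one marker (PRG4) weakly
    rank-correlated with age (target Spearman ρ = 0.34).
    """

    n_primary: int = 24
    n_metastatic: int = 12
    n_control: int = 13
    n_replicates: int = 2
    n_proteins: int = 257
    n_metabolites: int = 88
    n_immunoglobulin_decoys: int = 15
    marker_effects: tuple[MarkerEffect, ...] = DEFAULT_EFFECTS
    mcar_rate: float = 0.02
    mnar_slope: float = 3.0
    replicate_cv: float = 0.15
    age_marker: str = "PRG4"
    age_marker_rho: float = 0.34
    seed: int = 0

    def validate(self) -> None:
        for fld in (
            "n_primary", "n_metastatic", "n_control", "n_replicates",
            "n_proteins", "n_metabolites", "n_immunoglobulin_decoys",
        ):
            v = getattr(self, fld)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"config field {fld!r} must be a non-negative integer, got {v!r}")
        if self.n_replicates < 1:
            raise ValueError("config field 'n_replicates' must be >= 1")
        for fld in ("mcar_rate",):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field {fld!r} must lie in [0, 1], got {v!r}")
        if self.mnar_slope < 0:
            raise ValueError(f"config field 'mnar_slope' must be >= 0, got {self.mnar_slope!r}")
        if self.replicate_cv < 0:
            raise ValueError(f"config field 'replicate_cv' must be >= 0, got {self.replicate_cv!r}")
        if not -1.0 <= self.age_marker_rho <= 1.0:
            raise ValueError("config field 'age_marker_rho' must lie in [-1, 1]")
        if self.n_immunoglobulin_decoys > self.n_proteins:
            raise ValueError(
                "config field 'n_immunoglobulin_decoys' exceeds 'n_proteins'"
            )
        feature_names = set(protein_names(self)) | set(metabolite_names(self)[0])
        for eff in self.marker_effects:
            if eff.contrast not in CONTRASTS:
                raise ValueError(
                    f"config field 'marker_effects' references unknown contrast "
                    f"{eff.contrast!r}; known: {sorted(CONTRASTS)}"
                )
            if eff.feature not in feature_names:
                raise ValueError(
                    f"config field 'marker_effects' references feature "
                    f"{eff.feature!r} absent from the generated matrices"
                )


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    effects: list[MarkerEffect]
    baseline_log2_mean: dict[str, float]
    baseline_log2_sd: dict[str, float]
    mcar_rate: float
    mnar_slope: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        d = {
            "effects": [asdict(e) for e in self.effects],
            "baseline_log2_mean": self.baseline_log2_mean,
            "baseline_log2_sd": self.baseline_log2_sd,
            "mcar_rate": self.mcar_rate,
            "mnar_slope": self.mnar_slope,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    def markers_for(self, contrast_name: str) -> list[MarkerEffect]:
        return [e for e in self.effects if e.contrast == contrast_name and e.log2fc != 0]


# ---------------------------------------------------------------------------
# feature naming

def protein_names(cfg: CohortConfig) -> list[str]:
    """Marker genes, then immunoglobulin decoys, then filler gene symbols."""
    names = [m for m in PROTEIN_MARKERS][: cfg.n_proteins]
    igs = []
    i = 0
    while len(igs) < cfg.n_immunoglobulin_decoys:
        prefix = IG_PREFIXES[i % len(IG_PREFIXES)]
        igs.append(f"{prefix}{1 + i // len(IG_PREFIXES)}")
        i += 1
    names += igs[: max(0, cfg.n_proteins - len(names))]
    k = 1
    while len(names) < cfg.n_proteins:
        names.append(f"PROT{k:03d}")
        k += 1
    return names[: cfg.n_proteins]


def metabolite_names(cfg: CohortConfig) -> tuple[list[str], list[str]]:
    """Metabolite ids and class labels with the study panel's composition.

    For the default 88-metabolite panel: 72 glycerophospholipids, 14
    sphingolipids, 1 biogenic amine (Spermidine), 1 amino acid (Serine).
    Other sizes scale the class counts proportionally (largest remainder).
    """
    n = cfg.n_metabolites
    base = {"glycerophospholipid": 72, "sphingolipid": 14, "biogenic_amine": 1, "amino_acid": 1}
    if n == 88:
        counts = dict(base)
    else:
        quotas = {k: v * n / 88 for k, v in base.items()}
        counts = {k: int(q) for k, q in quotas.items()}
        rem = n - sum(counts.values())
        for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)[:rem]:
            counts[k] += 1
    glyc = [m for m in METABOLITE_MARKERS][: counts["glycerophospholipid"]]
    i = 0
    while len(glyc) < counts["glycerophospholipid"]:
        kind = ("PC aa", "PC ae", "lysoPC a")[i % 3]
        glyc.append(f"{kind} C{28 + 2 * (i // 3 % 10)}:{i % 5}")
        i += 1
    sph = [f"SM C{14 + 2 * (i % 7)}:{i // 7}" for i in range(counts["sphingolipid"])]
    amines = ["Spermidine", "Putrescine", "Taurine"][: counts["biogenic_amine"]] + [
        f"Amine{i}" for i in range(max(0, counts["biogenic_amine"] - 3))
    ]
    aas = ["Serine", "Glycine", "Alanine"][: counts["amino_acid"]] + [
        f"AA{i}" for i in range(max(0, counts["amino_acid"] - 3))
    ]
    ids = glyc + sph + amines + aas
    classes = (
        ["glycerophospholipid"] * len(glyc)
        + ["sphingolipid"] * len(sph)
        + ["biogenic_amine"] * len(amines)
        + ["amino_acid"] * len(aas)
    )
    # uniqueness guard for unusual sizes
    seen: dict[str, int] = {}
    uniq = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            uniq.append(f"{name}#{seen[name]}")
        else:
            seen[name] = 0
            uniq.append(name)
    return uniq, classes


# ---------------------------------------------------------------------------
# generation

def _subject_sheet(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    specs = [("P", "primary", cfg.n_primary), ("M", "metastatic", cfg.n_metastatic),
             ("C", "control", cfg.n_control)]
    for code, group, n in specs:
        mu, sd = AGE_PARAMS[group]
        ages = np.clip(rng.normal(mu, sd, size=n), 18.0, 95.0)
        for i in range(n):
            rows.append({"subject_id": f"{code}{i + 1:02d}", "group": group,
                         "age": float(np.round(ages[i], 1))})
    return pd.DataFrame(rows)


def _baseline_matrix(
    n_subjects: int,
    names: list[str],
    mean_center: float,
    mean_spread: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject-level log2 abundances: per-feature log-normal baselines.

    Per-feature log2 means are Normal(center, spread); per-feature log2 SDs
    are Gamma(shape=2, scale=0.25) (mean 0.5), a right-skewed spread of
    biological variability. Designated markers are pinned slightly above
    the average intensity so that low-intensity dropout never removes them.
    """
    G = len(names)
    mu = rng.normal(mean_center, mean_spread, size=G)
    sd = rng.gamma(shape=2.0, scale=0.25, size=G)
    sd = np.maximum(sd, 0.05)
    marker_set = set(PROTEIN_MARKERS) | set(METABOLITE_MARKERS)
    for j, name in enumerate(names):
        if name in marker_set:
            mu[j] = mean_center + 0.5 * mean_spread
            sd[j] = max(sd[j], 0.4)
    z = rng.standard_normal((n_subjects, G))
    log2v = mu[None, :] + sd[None, :] * z
    return log2v, mu, sd


def _apply_effects_log2(
    log2v: np.ndarray,
    names: list[str],
    groups: pd.Series,
    effects: tuple[MarkerEffect, ...],
) -> np.ndarray:
    out = log2v.copy()
    col = {n: j for j, n in enumerate(names)}
    for eff in effects:
        if eff.feature not in col:
            continue
        contrast = CONTRASTS[eff.contrast]
        mask = groups.isin(contrast.positive).to_numpy()
        out[mask, col[eff.feature]] += eff.log2fc
    return out


def _couple_marker_to_age(
    log2v: np.ndarray,
    names: list[str],
    ages: np.ndarray,
    groups: np.ndarray,
    marker: str,
    target_rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blend age signal into one marker until Spearman ρ is near target.

    The marker's subject values are re-ordered according to a latent rank
    ``w·z(age) + sqrt(1-w²)·noise``; ``w`` is found by bisection on the
    realised ρ (w may be negative, to cancel correlation already induced
    by group effects on an age-structured cohort). Re-ordering happens
    within study groups only, so group means — and any spiked effect —
    are preserved exactly while the marginal distribution is unchanged.
    The realised ρ is an approximation to the target.
    """
    if marker not in names:
        return log2v
    j = names.index(marker)
    v = log2v[:, j].copy()
    za = (ages - ages.mean()) / (ages.std() + 1e-12)
    noise = rng.standard_normal(len(v))

    def realised(w: float) -> np.ndarray:
        latent = w * za + np.sqrt(max(0.0, 1 - w * w)) * noise
        out = v.copy()
        for g in np.unique(groups):
            idx = np.where(groups == g)[0]
            ranks = latent[idx].argsort().argsort()
            out[idx] = np.sort(v[idx])[ranks]
        return out

    lo, hi = -1.0, 1.0
    best_v, best_gap = v, abs(spearmanr(v, ages).statistic - target_rho)
    for _ in range(25):
        w = 0.5 * (lo + hi)
        cand = realised(w)
        rho = spearmanr(cand, ages).statistic
        gap = abs(rho - target_rho)
        if gap < best_gap:
            best_v, best_gap = cand, gap
        if rho < target_rho:
            lo = w
        else:
            hi = w
        if gap < 0.01:
            break
    log2v = log2v.copy()
    log2v[:, j] = best_v
    return log2v


def _replicate_matrix(
    subject_log2: np.ndarray,
    subject_ids: list[str],
    n_replicates: int,
    cv: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Expand subject truth into technical replicates.

    Replicates are multiplicative log-normal jitter of the subject value
    with coefficient of variation ``cv`` (log-space sigma
    ``sqrt(ln(1+cv²))``).
    """
    n, G = subject_log2.shape
    sigma_ln = np.sqrt(np.log1p(cv * cv))
    sigma_log2 = sigma_ln / np.log(2.0)
    obs_log2, obs_ids, reps = [], [], []
    for i, sid in enumerate(subject_ids):
        for r in range(1, n_replicates + 1):
            jitter = sigma_log2 * rng.standard_normal(G) if cv > 0 else np.zeros(G)
            obs_log2.append(subject_log2[i] + jitter)
            obs_ids.append(f"{sid}_r{r}")
            reps.append(r)
    return np.asarray(obs_log2), obs_ids, reps


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[OmicsMatrix, OmicsMatrix, SampleSheet, SyntheticTruth]:
    """Generate a full cohort: protein and metabolite matrices, sample
    sheet and ground truth.

    Fully reproducible: identical ``cfg`` (including ``cfg.seed``) gives
    bit-identical outputs.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    subjects = _subject_sheet(cfg, rng)
    sub_ids = list(subjects["subject_id"])
    ages = subjects["age"].to_numpy(dtype=float)

    prot_names = protein_names(cfg)
    met_names, met_classes = metabolite_names(cfg)

    # LFQ intensities live around 2^25; metabolite concentrations around 1 µM
    prot_log2, prot_mu, prot_sd = _baseline_matrix(len(sub_ids), prot_names, 25.0, 2.0, rng)
    met_log2, met_mu, met_sd = _baseline_matrix(len(sub_ids), met_names, 0.0, 1.5, rng)

    prot_log2 = _apply_effects_log2(prot_log2, prot_names, subjects["group"], cfg.marker_effects)
    met_log2 = _apply_effects_log2(met_log2, met_names, subjects["group"], cfg.marker_effects)

    if cfg.age_marker and abs(cfg.age_marker_rho) > 0:
        grp = subjects["group"].to_numpy()
        if cfg.age_marker in prot_names:
            prot_log2 = _couple_marker_to_age(
                prot_log2, prot_names, ages, grp, cfg.age_marker, cfg.age_marker_rho, rng
            )
        elif cfg.age_marker in met_names:
            met_log2 = _couple_marker_to_age(
                met_log2, met_names, ages, grp, cfg.age_marker, cfg.age_marker_rho, rng
            )

    prot_obs, obs_ids, reps = _replicate_matrix(
        prot_log2, sub_ids, cfg.n_replicates, cfg.replicate_cv, rng
    )
    met_obs, obs_ids2, _ = _replicate_matrix(
        met_log2, sub_ids, cfg.n_replicates, cfg.replicate_cv, rng
    )
    assert obs_ids == obs_ids2

    proteins = OmicsMatrix(
        values=pd.DataFrame(np.exp2(prot_obs), index=obs_ids, columns=prot_names),
        feature_kind=pd.Series("protein", index=prot_names),
        layer="raw",
    )
    metabolites = OmicsMatrix(
        values=pd.DataFrame(np.exp2(met_obs), index=obs_ids, columns=met_names),
        feature_kind=pd.Series("metabolite", index=met_names),
        feature_class=pd.Series(met_classes, index=met_names),
        layer="raw",
    )

    if cfg.mcar_rate > 0 or cfg.mnar_slope > 0:
        keep = set(PROTEIN_MARKERS) | set(METABOLITE_MARKERS)
        proteins = inject_missing(
            proteins, cfg.mcar_rate, cfg.mnar_slope,
            seed=int(rng.integers(2**31)), protected=keep,
        )
        metabolites = inject_missing(
            metabolites, cfg.mcar_rate, cfg.mnar_slope,
            seed=int(rng.integers(2**31)), protected=keep,
        )

    sheet_rows = []
    sub_lookup = subjects.set_index("subject_id")
    for oid, rep in zip(obs_ids, reps):
        sid = oid.rsplit("_r", 1)[0]
        sheet_rows.append({
            "observation_id": oid,
            "subject_id": sid,
            "group": sub_lookup.loc[sid, "group"],
            "replicate_index": rep,
            "age": sub_lookup.loc[sid, "age"],
        })
    sheet = SampleSheet(pd.DataFrame(sheet_rows))

    truth = SyntheticTruth(
        effects=list(cfg.marker_effects),
        baseline_log2_mean={**dict(zip(prot_names, map(float, prot_mu))),
                            **dict(zip(met_names, map(float, met_mu)))},
        baseline_log2_sd={**dict(zip(prot_names, map(float, prot_sd))),
                          **dict(zip(met_names, map(float, met_sd)))},
        mcar_rate=cfg.mcar_rate,
        mnar_slope=cfg.mnar_slope,
        seed=cfg.seed,
    )
    return proteins, metabolites, sheet, truth


# ---------------------------------------------------------------------------
# standalone perturbation operations

def inject_missing(
    m: OmicsMatrix,
    mcar_rate: float,
    mnar_slope: float,
    seed: int,
    protected: set[str] | None = None,
) -> OmicsMatrix:
    """Mask entries completely at random and by low-intensity dropout.

    Each observed entry is masked with probability ``mcar_rate`` plus,
    when ``mnar_slope > 0``, a logistic term
    ``(1 - mcar_rate) * expit(-mnar_slope * (z - c))`` decreasing in the
    entry's standardised log2 intensity ``z`` (``c`` = ``MNAR_CENTER``
    global log2-SD units). With ``mnar_slope = 0`` the mechanism is pure
    MCAR. Features in ``protected`` are never masked (used to keep spiked
    markers above the missingness filter).
    """
    if not 0.0 <= mcar_rate <= 1.0:
        raise ValueError(f"mcar_rate must lie in [0, 1], got {mcar_rate!r}")
    if mnar_slope < 0:
        raise ValueError(f"mnar_slope must be >= 0, got {mnar_slope!r}")
    if m.layer != "raw":
        raise ValueError("inject_missing expects a raw-layer matrix")
    if mcar_rate == 0 and mnar_slope == 0:
        return m.copy()
    rng = np.random.default_rng(seed)
    vals = m.values.to_numpy(dtype=float).copy()
    obs_mask = ~np.isnan(vals)
    with np.errstate(divide="ignore", invalid="ignore"):
        logv = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), -np.inf)
    finite = obs_mask & np.isfinite(logv)
    if finite.any():
        mu, sd = logv[finite].mean(), logv[finite].std() + 1e-12
        z = (logv - mu) / sd
    else:
        z = np.zeros_like(vals)
    p = np.full_like(vals, mcar_rate)
    if mnar_slope > 0:
        p = p + (1.0 - mcar_rate) * expit(-mnar_slope * (z - MNAR_CENTER))
    p = np.clip(p, 0.0, 1.0)
    if protected:
        for j, name in enumerate(m.feature_ids):
            if name in protected:
                p[:, j] = 0.0
    drop = (rng.random(vals.shape) < p) & obs_mask
    vals[drop] = np.nan
    out = m.values.copy()
    out.iloc[:, :] = vals
    return m.with_values(out, layer="raw")


def spike_effects(
    m: OmicsMatrix,
    sheet: SampleSheet,
    effects: list[MarkerEffect] | tuple[MarkerEffect, ...],
    truth: SyntheticTruth | None = None,
) -> OmicsMatrix:
    """Multiply named features by ``2**log2fc`` in each effect's positive
    group. Updates ``truth.effects`` in place when a truth record is given.
    """
    col = {n: j for j, n in enumerate(m.feature_ids)}
    groups = sheet.table.set_index("observation_id")["group"]
    vals = m.values.to_numpy(dtype=float).copy()
    for eff in effects:
        if eff.feature not in col:
            raise ValueError(f"unknown feature {eff.feature!r}")
        if eff.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {eff.contrast!r}")
        contrast = CONTRASTS[eff.contrast]
        row_mask = np.asarray(
            [groups.get(o) in contrast.positive for o in m.observation_ids]
        )
        vals[row_mask, col[eff.feature]] *= 2.0 ** eff.log2fc
        if truth is not None:
            truth.effects.append(eff)
    out = m.values.copy()
    out.iloc[:, :] = vals
    return m.with_values(out)


# ---------------------------------------------------------------------------
# on-disk emission (MaxQuant proteinGroups dialect, CSV tables, JSON truth)

def write_maxquant_protein_groups(
    m: OmicsMatrix,
    path: str | Path,
    n_reverse: int = 0,
    n_contaminant: int = 0,
    n_site_only: int = 0,
) -> None:
    """Write a matrix as a MaxQuant ``proteinGroups.txt``-style table.

    One row per protein group, one ``LFQ intensity <obs>`` column per
    observation; missing values are written as 0 per that format's
    convention. Optional decoy rows flagged ``Reverse`` / ``Potential
    contaminant`` / ``Only identified by site`` exercise the
    identification filter.
    """
    rows = []
    vals = m.values.to_numpy(dtype=float)
    for j, name in enumerate(m.feature_ids):
        row = {
            "Protein IDs": f"SYN|{name}",
            "Gene names": name,
            "Reverse": "",
            "Potential contaminant": "",
            "Only identified by site": "",
        }
        for i, oid in enumerate(m.observation_ids):
            v = vals[i, j]
            row[f"LFQ intensity {oid}"] = 0.0 if np.isnan(v) else v
        rows.append(row)

    def decoy(tag_col: str, k: int, label: str) -> None:
        for i in range(k):
            row = {
                "Protein IDs": f"{label}{i + 1}",
                "Gene names": f"{label}{i + 1}",
                "Reverse": "",
                "Potential contaminant": "",
                "Only identified by site": "",
            }
            row[tag_col] = "+"
            for oid in m.observation_ids:
                row[f"LFQ intensity {oid}"] = 0.0
            rows.append(row)

    decoy("Reverse", n_reverse, "REV__")
    decoy("Potential contaminant", n_contaminant, "CON__")
    decoy("Only identified by site", n_site_only, "SITE__")
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def emit_cohort(cfg: CohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a cohort and write all four artifacts to ``outdir``."""
    from .io import write_feature_table  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins, metabolites, sheet, truth = generate_cohort(cfg)
    paths = {
        "proteins": outdir / "proteinGroups.txt",
        "metabolites": outdir / "metabolites.csv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "truth": outdir / "truth.json",
    }
    write_maxquant_protein_groups(proteins, paths["proteins"])
    write_feature_table(metabolites, paths["metabolites"], orient="features_by_observations")
    write_sample_sheet(sheet, paths["sample_sheet"])
    truth.to_json(paths["truth"])
    return paths
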
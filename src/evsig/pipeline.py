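"""End-to-end discovery runs: configuration, orchestration, run report.

A run executes, for each of the two study contrasts (melanoma vs healthy
control; metastatic vs primary disease): data generation or ingestion →
preprocessing → differential abundance → triple-algorithm feature
selection → consensus → exhaustive grid search with
clustering-as-classifier evaluation → multi-omic integration and
similarity partitioning. One integer seed governs every stochastic stage,
so a report is regenerable from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import (
    MELANOMA_VS_CONTROL,
    METASTATIC_VS_PRIMARY,
    Contrast,
    OmicsMatrix,
    SampleSheet,
)
from .differential import de_table, moderated_t_test
from .evaluate import cluster_classify, grid_search
from .io import read_feature_table, read_maxquant_protein_groups, read_sample_sheet
from .multiomics import combine_omics, partition_table, spearman_similarity_partition
from .preprocess import average_replicates, preprocess
from .selection import (
    FeatureSignature,
    consensus,
    forest_importance,
    lasso_logistic,
    rank_features_by_de,
    serial_knn,
)
from .synthetic import CohortConfig, MarkerEffect, generate_cohort

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {"synthetic": {}},
    "preprocess": {"max_missing_fraction": 0.40, "impute_trees": 100, "impute_max_iter": 10},
    "differential": {"p_threshold": 0.05},
    "selection": {
        "k_values": [1, 3, 5, 7],
        "n_values": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        "metric": "accuracy",
        "cv_mode": "loso",
        "n_lambda": 30,
        "cv_folds": 5,
        "lambda_rule": "min",
        "forest_trees": 500,
        "top_fraction": 0.10,
        # the study's grid searches never exceeded six candidate features
        "max_candidates": 6,
    },
    "evaluation": {"linkage": "complete", "max_subset_size": None,
                   "protein_level": "replicate", "combined_level": "subject"},
    "integration": {"partition_k": 6},
    "output": {},
}

_RANGE_CHECKS = {
    ("data", "synthetic", "mcar_rate"): (0.0, 1.0),
    ("data", "synthetic", "replicate_cv"): (0.0, None),
    ("data", "synthetic", "mnar_slope"): (0.0, None),
    ("preprocess", "max_missing_fraction"): (0.0, 1.0),
    ("differential", "p_threshold"): (0.0, 1.0),
    ("selection", "top_fraction"): (0.0, 1.0),
}

#: keys a synthetic-data section must state explicitly
_SYNTHETIC_REQUIRED = ("n_primary", "n_metastatic", "n_control")


def load_config(path_or_dict) -> dict:
    """Load a YAML config and overlay it on the defaults."""
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for section, content in user.items():
        if isinstance(content, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(content)
        else:
            cfg[section] = content
    return cfg


def validate_config(path_or_dict) -> list[str]:
    """Schema findings (unknown keys, missing keys, range violations)
    without running anything. Empty list = valid."""
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    findings: list[str] = []
    for section, content in user.items():
        if section not in DEFAULT_CONFIG:
            findings.append(f"unknown section {section!r}")
            continue
        if section == "data":
            for key in content:
                if key not in ("synthetic", "files"):
                    findings.append(f"unknown key 'data.{key}'")
            if "synthetic" in content:
                syn = content["synthetic"] or {}
                cohort_fields = {f.name for f in dataclasses.fields(CohortConfig)}
                for key in syn:
                    if key not in cohort_fields:
                        findings.append(f"unknown key 'data.synthetic.{key}'")
                for key in _SYNTHETIC_REQUIRED:
                    if key not in syn:
                        findings.append(f"missing key 'data.synthetic.{key}'")
            if "files" in content:
                for key in ("proteins", "metabolites", "sample_sheet"):
                    if key not in content["files"]:
                        findings.append(f"missing key 'data.files.{key}'")
        elif isinstance(content, dict):
            for key in content:
                if key not in DEFAULT_CONFIG[section]:
                    findings.append(f"unknown key '{section}.{key}'")
    for path, (lo, hi) in _RANGE_CHECKS.items():
        node = user
        for part in path[:-1]:
            node = node.get(part, {}) if isinstance(node, dict) else {}
        if isinstance(node, dict) and path[-1] in node:
            v = node[path[-1]]
            if not isinstance(v, (int, float)) or (lo is not None and v < lo) or (
                hi is not None and v > hi
            ):
                bound = f"[{lo}, {hi}]" if hi is not None else f">= {lo}"
                findings.append(f"key '{'.'.join(path)}' = {v!r} outside range {bound}")
    return findings


@dataclass
class RunReport:
    """Machine-readable record of one discovery run."""

    version: str
    seed: int
    config: dict
    preprocess: dict = field(default_factory=dict)
    contrasts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _signature_dict(sig: FeatureSignature) -> dict:
    return {"source": sig.source, "params": sig.params, "features": sig.features}


def _load_data(cfg: dict, seed: int) -> tuple[OmicsMatrix, OmicsMatrix, SampleSheet]:
    data = cfg["data"]
    if "files" in data:
        f = data["files"]
        proteins = read_maxquant_protein_groups(f["proteins"], filter_ids=True)
        metabolites = read_feature_table(f["metabolites"], kind="metabolite")
        sheet = read_sample_sheet(f["sample_sheet"])
        return proteins, metabolites, sheet
    syn = dict(data.get("synthetic") or {})
    if "marker_effects" in syn:
        syn["marker_effects"] = tuple(
            MarkerEffect(**e) if isinstance(e, dict) else MarkerEffect(*e)
            for e in syn["marker_effects"]
        )
    syn["seed"] = seed
    cohort = CohortConfig(**syn)
    proteins, metabolites, sheet, _ = generate_cohort(cohort)
    return proteins, metabolites, sheet


def _select_candidates(
    m: OmicsMatrix,
    sheet: SampleSheet,
    contrast: Contrast,
    sel_cfg: dict,
    seeds: dict[str, int],
) -> dict:
    """Run the three selectors + consensus; return signatures and the
    candidate list for the grid search."""
    ranked = rank_features_by_de(m, sheet, contrast)
    knn_res = serial_knn(
        m, sheet, contrast,
        k_values=tuple(sel_cfg["k_values"]),
        n_values=tuple(sel_cfg["n_values"]),
        metric=sel_cfg["metric"],
        cv_mode=sel_cfg["cv_mode"],
        ranked_features=ranked,
    )
    lasso_sig = lasso_logistic(
        m, sheet, contrast,
        n_lambda=sel_cfg["n_lambda"],
        cv_folds=sel_cfg["cv_folds"],
        rule=sel_cfg["lambda_rule"],
        seed=seeds["lasso"],
    )
    forest_sig = forest_importance(
        m, sheet, contrast,
        n_trees=sel_cfg["forest_trees"],
        top_fraction=sel_cfg["top_fraction"],
        seed=seeds["forest"],
    )
    strict, lenient = consensus([knn_res.signature, lasso_sig, forest_sig])
    cap = sel_cfg["max_candidates"]
    rank_pos = {f: i for i, f in enumerate(ranked)}
    if strict.features:
        candidates, basis = strict.features, "consensus"
    elif lenient.features:
        candidates, basis = lenient.features, "lenient"
    else:
        candidates, basis = ranked[: min(4, len(ranked))], "de_rank_fallback"
    candidates = sorted(candidates, key=lambda f: rank_pos.get(f, 10**6))[:cap]
    return {
        "knn": knn_res,
        "signatures": {
            "knn": _signature_dict(knn_res.signature),
            "lasso": _signature_dict(lasso_sig),
            "forest": _signature_dict(forest_sig),
            "consensus": _signature_dict(strict),
            "lenient": _signature_dict(lenient),
        },
        "candidates": candidates,
        "candidate_basis": basis,
    }


def joint_candidates(
    protein_candidates: list[str],
    metabolite_candidates: list[str],
    cap: int,
    available: set[str] | None = None,
) -> list[str]:
    """Pool candidates from both omics for the combined grid search.

    Half the slots go to each omic (proteins get the odd spare); unused
    slots are refilled from the other omic's remainder, preserving each
    list's own ranking."""
    if available is not None:
        protein_candidates = [f for f in protein_candidates if f in available]
        metabolite_candidates = [f for f in metabolite_candidates if f in available]
    n_prot = min(len(protein_candidates), cap - cap // 2)
    n_met = min(len(metabolite_candidates), cap - n_prot)
    n_prot = min(len(protein_candidates), cap - n_met)
    return protein_candidates[:n_prot] + metabolite_candidates[:n_met]


def run_discovery(
    config=None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> RunReport:
    """Execute the full discovery pipeline and return the run report.

    ``config`` may be a YAML path, a dict, or None (defaults: a synthetic
    study-shaped cohort). ``seed`` overrides the config seed. When
    ``outdir`` is given, the report, stage tables and signatures are
    written beneath it.
    """
    cfg = load_config(config if config is not None else {})
    if seed is not None:
        cfg["seed"] = int(seed)
    master = int(cfg["seed"])
    rng = np.random.default_rng(master)
    seeds = {name: int(rng.integers(2**31)) for name in
             ("cohort", "impute_prot", "impute_met", "lasso", "forest")}

    report = RunReport(version=__version__, seed=master, config=cfg)

    proteins_raw, metabolites_raw, sheet = _load_data(cfg, seeds["cohort"])
    pp = cfg["preprocess"]
    proteins, prot_rep = preprocess(
        proteins_raw, pp["max_missing_fraction"], drop_immunoglobulins=True,
        impute_trees=pp["impute_trees"], impute_max_iter=pp["impute_max_iter"],
        seed=seeds["impute_prot"],
    )
    metabolites, met_rep = preprocess(
        metabolites_raw, pp["max_missing_fraction"], drop_immunoglobulins=False,
        impute_trees=pp["impute_trees"], impute_max_iter=pp["impute_max_iter"],
        seed=seeds["impute_met"],
    )
    report.preprocess = {
        "proteins": prot_rep.stages,
        "metabolites": met_rep.stages,
        "decisions": {
            "normalisation": "log2 + per-observation median centring",
            "cv_mode": cfg["selection"]["cv_mode"],
            "linkage": cfg["evaluation"]["linkage"],
            "protein_level": cfg["evaluation"]["protein_level"],
            "combined_level": cfg["evaluation"]["combined_level"],
        },
    }

    prot_subj, sheet_subj = average_replicates(proteins, sheet)
    met_subj, _ = average_replicates(metabolites, sheet)
    linkage = cfg["evaluation"]["linkage"]
    max_subset = cfg["evaluation"]["max_subset_size"]
    sel_cfg = cfg["selection"]
    p_threshold = cfg["differential"]["p_threshold"]

    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        (outdir / "tables").mkdir(parents=True, exist_ok=True)
        (outdir / "signatures").mkdir(parents=True, exist_ok=True)

    for contrast in (MELANOMA_VS_CONTROL, METASTATIC_VS_PRIMARY):
        entry: dict = {}
        # differential abundance at subject level (replicates are correlated)
        de = {}
        for name, mat in (("proteins", prot_subj), ("metabolites", met_subj)):
            records = moderated_t_test(mat, sheet_subj, contrast, p_threshold=p_threshold)
            table = de_table(records)
            sig_up = int(((table["p"] < p_threshold) & (table["log2FC"] > 0)).sum())
            sig_down = int(((table["p"] < p_threshold) & (table["log2FC"] < 0)).sum())
            de[name] = {"n_features": len(records), "n_significant": sig_up + sig_down,
                        "n_up": sig_up, "n_down": sig_down}
            if outdir is not None:
                table.to_csv(outdir / "tables" / f"de_{name}_{contrast.name}.tsv",
                             sep="\t", index=False)
        entry["differential"] = de

        # selection: proteins at replicate level (the duplicate-as-independent
        # convention), metabolites at subject level
        prot_sel = _select_candidates(proteins, sheet, contrast, sel_cfg, seeds)
        met_sel = _select_candidates(met_subj, sheet_subj, contrast, sel_cfg, seeds)
        entry["selection"] = {
            "proteins": {**prot_sel["signatures"],
                         "candidates": prot_sel["candidates"],
                         "candidate_basis": prot_sel["candidate_basis"]},
            "metabolites": {**met_sel["signatures"],
                            "candidates": met_sel["candidates"],
                            "candidate_basis": met_sel["candidate_basis"]},
        }

        # grid-searched evaluations
        evaluations: dict = {}
        prot_eval_m = proteins if cfg["evaluation"]["protein_level"] == "replicate" else prot_subj
        prot_eval_s = sheet if cfg["evaluation"]["protein_level"] == "replicate" else sheet_subj
        sig, ev, board = grid_search(prot_eval_m, prot_sel["candidates"], prot_eval_s,
                                     contrast, max_subset_size=max_subset, linkage=linkage)
        evaluations["proteins"] = {"signature": _signature_dict(sig),
                                   "evaluation": ev.to_dict()}
        if outdir is not None:
            board.to_csv(outdir / "tables" / f"grid_proteins_{contrast.name}.tsv",
                         sep="\t", index=False)

        sig_m, ev_m, board_m = grid_search(met_subj, met_sel["candidates"], sheet_subj,
                                           contrast, max_subset_size=max_subset,
                                           linkage=linkage)
        evaluations["metabolites"] = {"signature": _signature_dict(sig_m),
                                      "evaluation": ev_m.to_dict()}
        if outdir is not None:
            board_m.to_csv(outdir / "tables" / f"grid_metabolites_{contrast.name}.tsv",
                           sep="\t", index=False)

        # multi-omic integration at subject level; the joint candidate pool
        # draws from both omics (half the slots each, spares refilled)
        combined, comb_sheet = combine_omics(proteins, metabolites, sheet)
        joint = joint_candidates(
            prot_sel["candidates"], met_sel["candidates"],
            cap=sel_cfg["max_candidates"], available=set(combined.feature_ids),
        )
        sig_c, ev_c, board_c = grid_search(combined, joint, comb_sheet, contrast,
                                           max_subset_size=max_subset, linkage=linkage)
        evaluations["combined"] = {"signature": _signature_dict(sig_c),
                                   "evaluation": ev_c.to_dict()}
        if outdir is not None:
            board_c.to_csv(outdir / "tables" / f"grid_combined_{contrast.name}.tsv",
                           sep="\t", index=False)
        entry["evaluations"] = evaluations

        # cross-omic similarity structure of the candidate features
        part_k = min(cfg["integration"]["partition_k"], len(joint))
        partition = spearman_similarity_partition(combined, joint, k=part_k,
                                                  linkage=linkage)
        entry["similarity_partition"] = {
            "k": partition.k,
            "labels": partition.labels,
        }
        if outdir is not None:
            partition_table(partition, combined.feature_kind).to_csv(
                outdir / "tables" / f"partition_{contrast.name}.tsv", sep="\t", index=False
            )
            for name, sig_d in entry["selection"]["proteins"].items():
                if isinstance(sig_d, dict) and "features" in sig_d:
                    p = outdir / "signatures" / f"{contrast.name}_proteins_{name}.json"
                    p.write_text(json.dumps(sig_d, indent=1))

        report.contrasts[contrast.name] = entry

    if outdir is not None:
        report.to_json(outdir / "report.json")
    return report
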
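"""End-to-end pipeline orchestration with provenance.

Stages (``simulate``, ``perturb``, ``select``, ``cluster``, ``classify``,
``ssea``) read and write plain-text artifacts under an output directory and
record a JSON manifest (seeds, input hashes, shapes) after every run. Stage
dependencies are checked up front so a missing upstream output fails with a
message naming the stage to run first.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .classifiers import (
    assign_cohort,
    build_miniclassifier,
    dqda_fit,
    dqda_predict,
    sam_screen,
    train_shrunken_centroid,
)
from .containers import NORMAL_LABEL, TUMOR_LABEL
from .edge_selection import (
    differential_edge_test,
    select_representative_network,
    tumor_variability,
)
from .perturbation import build_perturbation, dispersion_compare
from .simdata import SimConfig, simulate_cohort
from .ssea import read_gmt, run_ssea
from .subtyping import cdf_table, select_k, silhouette_core, sweep_k

logger = logging.getLogger(__name__)

STAGES = ("simulate", "perturb", "select", "cluster", "classify", "ssea")

_DEPENDENCIES = {
    "perturb": [("expression.tsv", "simulate"), ("phenotype.tsv", "simulate"), ("network.tsv", "simulate")],
    "select": [("perturbation.tsv", "perturb"), ("phenotype.tsv", "simulate")],
    "cluster": [("perturbation.tsv", "perturb"), ("selected_edges.txt", "select")],
    "classify": [("expression.tsv", "simulate"), ("cluster_labels.tsv", "cluster")],
    "ssea": [("expression.tsv", "simulate"), ("cluster_labels.tsv", "cluster")],
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths + per-stage parameter blocks + global seed."""

    outdir: Path
    expression: Optional[Path] = None
    phenotype: Optional[Path] = None
    network: Optional[Path] = None
    genesets: Optional[Path] = None
    seed: int = 0
    simdata: Dict = field(default_factory=dict)
    perturbation: Dict = field(default_factory=dict)
    selection: Dict = field(default_factory=dict)
    subtyping: Dict = field(default_factory=dict)
    classifiers: Dict = field(default_factory=dict)
    ssea: Dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        paths = raw.get("paths", {})
        return cls(
            outdir=Path(paths.get("outdir", "netpert_out")),
            expression=_opt_path(paths.get("expression")),
            phenotype=_opt_path(paths.get("phenotype")),
            network=_opt_path(paths.get("network")),
            genesets=_opt_path(paths.get("genesets")),
            seed=int(raw.get("seed", 0)),
            simdata=raw.get("simdata", {}),
            perturbation=raw.get("perturbation", {}),
            selection=raw.get("selection", {}),
            subtyping=raw.get("subtyping", {}),
            classifiers=raw.get("classifiers", {}),
            ssea=raw.get("ssea", {}),
        )


def _opt_path(p) -> Optional[Path]:
    return Path(p) if p else None


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str]) -> Dict:
    """Execute the requested stages in order; return the run manifest."""
    for s in stages:
        if s not in STAGES:
            raise PipelineError(f"unknown stage {s!r}; choose from {STAGES}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    manifest["seed"] = cfg.seed

    for stage in stages:
        _check_dependencies(cfg, out, stage)
        info = _STAGE_FUNCS[stage](cfg, out)
        info["inputs"] = {
            name: _hash_file(out / name)
            for name, _ in _DEPENDENCIES.get(stage, [])
            if (out / name).exists()
        }
        manifest["stages"][stage] = info
        manifest["last_run"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("stage %s done: %s", stage, {k: v for k, v in info.items() if k != "inputs"})
    return manifest


def _check_dependencies(cfg: PipelineConfig, out: Path, stage: str) -> None:
    for fname, producer in _DEPENDENCIES.get(stage, []):
        if (out / fname).exists():
            continue
        # external inputs may substitute for the simulate stage
        attr = {"expression.tsv": "expression", "phenotype.tsv": "phenotype", "network.tsv": "network"}.get(fname)
        if attr and getattr(cfg, attr) is not None:
            continue
        raise PipelineError(
            f"stage {stage!r} needs {fname}, which is produced by stage "
            f"{producer!r}; run that stage first (or point the config at an "
            "external file)"
        )


def _load_inputs(cfg: PipelineConfig, out: Path):
    expr_path = cfg.expression or out / "expression.tsv"
    phen_path = cfg.phenotype or out / "phenotype.tsv"
    net_path = cfg.network or out / "network.tsv"
    expr = nio.read_expression(expr_path)
    phen = nio.read_phenotype(phen_path)
    net = nio.read_network(net_path)
    return expr, phen, net


def _stage_simulate(cfg: PipelineConfig, out: Path) -> Dict:
    params = dict(cfg.simdata)
    params.setdefault("seed", cfg.seed)
    sim_cfg = SimConfig(**params)
    cohort = simulate_cohort(sim_cfg)
    nio.write_expression(cohort.expr, out / "expression.tsv")
    nio.write_phenotype(cohort.phenotype, out / "phenotype.tsv")
    nio.write_phenotype(cohort.truth, out / "truth.tsv")
    nio.write_network(cohort.net, out / "network.tsv")
    (out / "sim_config.json").write_text(sim_cfg.to_json())
    truth_edges = {k: v for k, v in cohort.perturbed_edges.items()}
    (out / "truth_edges.json").write_text(json.dumps(truth_edges, indent=2))
    return {
        "n_genes": int(cohort.expr.shape[0]),
        "n_samples": int(cohort.expr.shape[1]),
        "n_edges": cohort.net.n_edges,
        "seed": sim_cfg.seed,
    }


def _stage_perturb(cfg: PipelineConfig, out: Path) -> Dict:
    expr, phen, net = _load_inputs(cfg, out)
    pert = build_perturbation(expr, phen, net, **cfg.perturbation)
    pert.values.to_csv(out / "perturbation.tsv", sep="\t", index_label="edge_id")
    (out / "benchmark.json").write_text(
        json.dumps(
            {
                "n_normals": pert.n_normals,
                "normal_ids_hash": pert.normal_ids_hash,
                "benchmark": {e: float(v) for e, v in pert.benchmark.items()},
            }
        )
    )
    disp = dispersion_compare(pert, phen, method=cfg.perturbation.get("dispersion_method", "cv"))
    disp.table.to_csv(out / "dispersion.tsv", sep="\t", index_label="edge_id")
    return {
        "n_edges": int(pert.values.shape[0]),
        "n_samples": int(pert.values.shape[1]),
        "fraction_tumor_more_dispersed": disp.fraction_tumor_greater,
    }


def _read_pert(out: Path) -> pd.DataFrame:
    return pd.read_csv(out / "perturbation.tsv", sep="\t", index_col=0)


def _stage_select(cfg: PipelineConfig, out: Path) -> Dict:
    pert = _read_pert(out)
    phen = nio.read_phenotype(cfg.phenotype or out / "phenotype.tsv")
    net_path = cfg.network or out / "network.tsv"
    net = nio.read_network(net_path)
    sel_cfg = dict(cfg.selection)
    stats = differential_edge_test(pert, phen, method=sel_cfg.pop("method", "combined"))
    var = tumor_variability(pert, phen)
    result = select_representative_network(stats, var, net, **sel_cfg)
    result.stats.to_csv(out / "edge_stats.tsv", sep="\t", index_label="edge_id")
    nio.write_network(result.network, out / "reduced_network.tsv")
    (out / "selected_edges.txt").write_text("\n".join(result.selected_edge_ids) + "\n")
    return {
        "n_selected_edges": result.n_edges,
        "n_selected_genes": result.n_genes,
        "scale_free_r": None if result.fit is None else result.fit.r,
    }


def _stage_cluster(cfg: PipelineConfig, out: Path) -> Dict:
    pert = _read_pert(out)
    phen = nio.read_phenotype(cfg.phenotype or out / "phenotype.tsv")
    edges = (out / "selected_edges.txt").read_text().split()
    sub_cfg = dict(cfg.subtyping)
    k_min = int(sub_cfg.pop("k_min", 2))
    k_max = int(sub_cfg.pop("k_max", 8))
    threshold = float(sub_cfg.pop("silhouette_threshold", 0.0))
    sub_cfg.setdefault("n_reps", 100)
    tumors = [s for s in pert.columns if phen.get(s) == TUMOR_LABEL]
    X = pert.loc[edges, tumors].T
    runs = sweep_k(X, range(k_min, k_max + 1), seed=cfg.seed, **sub_cfg)
    best_k = select_k(runs)
    best = next(r for r in runs if r.k == best_k)
    core = silhouette_core(best, threshold=threshold)

    pd.DataFrame(
        {"K": [r.k for r in runs], "pac": [r.pac for r in runs]}
    ).to_csv(out / "pac_by_k.csv", index=False)
    cdf_table(runs).to_csv(out / "consensus_cdf.csv")
    best.consensus.to_csv(out / "consensus_matrix.tsv", sep="\t", index_label="sample_id")
    labels = pd.DataFrame(
        {
            "cluster": best.labels,
            "silhouette": core.silhouette,
            "core": core.core,
        }
    )
    labels.to_csv(out / "cluster_labels.tsv", sep="\t", index_label="sample_id")
    return {
        "k": best_k,
        "pac": best.pac,
        "n_core": core.core_count,
        "n_clustered": int(len(best.labels)),
    }


def _stage_classify(cfg: PipelineConfig, out: Path) -> Dict:
    expr = nio.read_expression(cfg.expression or out / "expression.tsv")
    labels_df = pd.read_csv(out / "cluster_labels.tsv", sep="\t", index_col=0)
    cls_cfg = dict(cfg.classifiers)
    core_only = bool(cls_cfg.pop("core_only", True))
    use = labels_df.index[labels_df["core"]] if core_only else labels_df.index
    labels = labels_df.loc[use, "cluster"].astype(str)
    sub_expr = expr[list(use)]

    sam = sam_screen(
        sub_expr, labels,
        n_perm=int(cls_cfg.pop("sam_perms", 100)),
        fdr=float(cls_cfg.pop("sam_fdr", 0.05)),
        seed=cfg.seed,
    )
    genes = sam.union_genes
    if len(genes) < 2:
        raise PipelineError("SAM screen kept <2 genes; relax sam_fdr")
    nsc = train_shrunken_centroid(
        sub_expr.loc[genes], labels,
        cv_folds=int(cls_cfg.pop("pam_cv_folds", 5)),
        seed=cfg.seed,
    )
    panel = nsc.survivors_
    dqda = dqda_fit(sub_expr.loc[panel], labels)
    (out / "dqda_model.json").write_text(dqda.to_json())
    (out / "pam_model.json").write_text(nsc.to_json())
    assigned = assign_cohort(dqda, expr, mode=cls_cfg.pop("mode", "dqda"))
    assigned.to_csv(out / "assignments.tsv", sep="\t", index_label="sample_id")

    mini_info = {}
    if bool(cls_cfg.pop("miniclassifier", True)):
        mini = build_miniclassifier(
            sub_expr.loc[genes], labels,
            n_boot=int(cls_cfg.pop("n_boot", 200)),
            n_trees=int(cls_cfg.pop("n_trees", 500)),
            seed=cfg.seed,
        )
        mini_info = {
            "panel_size": len(mini.panel),
            "n_robust": len(mini.robust_genes),
            "misclassification_train": mini.misclassification_train,
            "misclassification_test": mini.misclassification_test,
        }
        (out / "miniclassifier_panel.txt").write_text("\n".join(mini.panel) + "\n")
    return {
        "n_sam_genes": len(genes),
        "pam_panel_size": len(panel),
        "pam_cv_error": float(nsc.cv_errors_.min()) if nsc.cv_errors_ is not None else None,
        **mini_info,
    }


def _stage_ssea(cfg: PipelineConfig, out: Path) -> Dict:
    expr = nio.read_expression(cfg.expression or out / "expression.tsv")
    labels_df = pd.read_csv(out / "cluster_labels.tsv", sep="\t", index_col=0)
    labels = labels_df["cluster"].astype(str)
    ssea_cfg = dict(cfg.ssea)
    if cfg.genesets:
        genesets = read_gmt(cfg.genesets)
    else:
        # default: whole measured transcriptome as a single "pathway"
        genesets = {"ALL_GENES": list(expr.index)}
    table = run_ssea(
        expr[list(labels.index)], labels, genesets,
        weight=int(ssea_cfg.pop("weight", 1)),
        n_perm=int(ssea_cfg.pop("n_perm", 200)),
        seed=cfg.seed,
    )
    table.to_csv(out / "ssea_results.tsv", sep="\t", index=False)
    return {"n_tests": int(len(table))}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "perturb": _stage_perturb,
    "select": _stage_select,
    "cluster": _stage_cluster,
    "classify": _stage_classify,
    "ssea": _stage_ssea,
}
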
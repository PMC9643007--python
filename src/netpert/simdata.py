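"""Synthetic-cohort generator with ground truth.

The generator emulates the statistical structure the perturbation analysis
assumes: a scale-free (preferential-attachment) background network; a
homogeneous normal group whose gene-pair rank relations are conserved up to
independent noise; and K tumor subtypes, each defined by rank-order-flipping
expression shifts on a subtype-specific, endpoint-disjoint set of edges.

Expression is generated on a log2-microarray-like scale: per-gene baselines
``mu_g ~ Normal(baseline_mean, baseline_sd)`` plus independent Gaussian
noise. Each subtype perturbs its edges by *swapping* the two endpoint
baselines, choosing edges whose baseline gap lies between
``shift_magnitude`` and ``max_shift_magnitude`` noise units: every shifted
endpoint therefore moves by at least ``shift_magnitude * noise_sd`` (the
rank flip survives the noise) and the template's value multiset is
identical to the baseline's, so the ranks of all unswapped genes are
untouched and no spurious cohort-wide rank compression is introduced. The
planted edge, whose endpoints move in opposite directions, carries exactly
twice the delta-rank displacement of any other edge incident to a swapped
gene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .containers import NORMAL_LABEL, TUMOR_LABEL, InteractionNetwork, edge_id

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_network",
    "simulate_cohort",
    "add_batch_effects",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration (defaults emulate the study conditions)."""

    n_genes: int = 1000
    attachment_m: int = 2
    n_normals: int = 60
    n_tumors: int = 300
    n_subtypes: int = 6
    edges_per_subtype: int = 40
    shift_magnitude: float = 3.0  # min endpoint displacement, noise_sd units
    noise_sd: float = 1.0  # per-gene independent noise, log2 units
    baseline_mean: float = 8.0  # log2-intensity-like baseline location
    baseline_sd: float = 3.0  # spread of baselines across genes
    max_shift_magnitude: float = 7.0  # perturbable-pair gap cap, noise_sd units
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.n_genes, self.n_normals, self.n_tumors, self.edges_per_subtype) < 1:
            raise ValueError("all counts must be positive")
        if self.n_subtypes < 2:
            raise ValueError("need K >= 2 subtypes")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")
        if self.noise_sd < 0 or self.baseline_sd <= 0:
            raise ValueError("invalid noise/baseline parameters")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SyntheticCohort:
    """Generated cohort with ground truth for recovery tests."""

    expr: pd.DataFrame  # genes x samples
    net: InteractionNetwork
    phenotype: pd.Series  # normal/tumor per sample
    truth: pd.Series  # "normal" for normals, subtype label for tumors
    perturbed_edges: Dict[str, List[str]]  # subtype -> edge ids
    informative_genes: Dict[str, List[str]]  # subtype -> swapped genes
    config: SimConfig
    baseline: Optional[pd.Series] = None  # per-gene noiseless baseline
    templates: Optional[pd.DataFrame] = None  # genes x subtypes noiseless templates

    @property
    def tumor_samples(self) -> List[str]:
        return list(self.phenotype.index[self.phenotype == TUMOR_LABEL])

    @property
    def normal_samples(self) -> List[str]:
        return list(self.phenotype.index[self.phenotype == NORMAL_LABEL])

    @property
    def all_perturbed_edges(self) -> List[str]:
        out = []
        for edges in self.perturbed_edges.values():
            out.extend(edges)
        return sorted(out)

    @property
    def all_informative_genes(self) -> List[str]:
        out = set()
        for genes in self.informative_genes.values():
            out.update(genes)
        return sorted(out)


def _gene_ids(n: int) -> List[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_network(n_genes: int, m: int = 2, seed: Optional[int] = None) -> InteractionNetwork:
    """Preferential-attachment (Barabasi-Albert) background network."""
    if not (n_genes > m >= 1):
        raise ValueError("need n_genes > m >= 1")
    g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    ids = _gene_ids(n_genes)
    return InteractionNetwork.from_edges((ids[a], ids[b]) for a, b in g.edges())


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate expression, phenotype and ground-truth subtype structure."""
    rng = np.random.default_rng(cfg.seed)
    net_seed = None if cfg.seed is None else int(cfg.seed) % (2**31 - 1)
    net = simulate_network(cfg.n_genes, cfg.attachment_m, seed=net_seed)
    genes = _gene_ids(cfg.n_genes)
    gpos = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    n_needed = cfg.n_subtypes * cfg.edges_per_subtype
    if n_needed > net.n_edges:
        raise ValueError(
            f"need {n_needed} perturbable edges but the network has {net.n_edges}"
        )
    subtypes = [f"S{k+1}" for k in range(cfg.n_subtypes)]
    # candidate edges: baseline gap inside the displacement window so a swap
    # flips the pair robustly; endpoint-disjoint so each subtype's signature
    # is its own
    gaps = np.array(
        [abs(baseline[gpos[a]] - baseline[gpos[b]]) for a, b in net.edges]
    )
    if cfg.noise_sd > 0:
        lo_cap = cfg.shift_magnitude * cfg.noise_sd
        hi_cap = cfg.max_shift_magnitude * cfg.noise_sd
    else:
        lo_cap, hi_cap = 0.0, np.inf
    in_window = np.where((gaps >= lo_cap) & (gaps <= hi_cap))[0]
    mid = (lo_cap + hi_cap) / 2 if np.isfinite(hi_cap) else lo_cap
    outside = np.array(
        sorted((i for i in range(len(gaps)) if i not in set(in_window)),
               key=lambda i: abs(gaps[i] - mid)),
        dtype=int,
    )
    order = np.concatenate([rng.permutation(in_window), outside]).astype(int)
    used_genes: set = set()
    chosen: List[List[tuple]] = [[] for _ in subtypes]
    k = 0
    for i in order:
        a, b = net.edges[i]
        if a in used_genes or b in used_genes:
            continue
        chosen[k].append((a, b))
        used_genes.update((a, b))
        if len(chosen[k]) == cfg.edges_per_subtype:
            k += 1
            if k == cfg.n_subtypes:
                break
    if k < cfg.n_subtypes:
        raise ValueError(
            "could not find enough endpoint-disjoint edges; "
            "reduce edges_per_subtype or enlarge the network"
        )

    perturbed_edges: Dict[str, List[str]] = {}
    informative: Dict[str, List[str]] = {}
    templates = {}
    for st, edges in zip(subtypes, chosen):
        template = baseline.copy()
        edge_ids_, inf_genes = [], []
        for a, b in edges:
            ia, ib = gpos[a], gpos[b]
            if cfg.shift_magnitude > 0:
                # pure swap: flips the pair's rank order while leaving the
                # template's value multiset (hence all other ranks) intact
                template[ia], template[ib] = baseline[ib], baseline[ia]
                inf_genes.extend((a, b))
            edge_ids_.append(edge_id(a, b))
        templates[st] = template
        perturbed_edges[st] = sorted(edge_ids_)
        informative[st] = sorted(inf_genes)

    normal_ids = [f"N{i:04d}" for i in range(1, cfg.n_normals + 1)]
    tumor_ids = [f"T{i:04d}" for i in range(1, cfg.n_tumors + 1)]
    # near-even subtype sizes
    assignment = np.array(
        [subtypes[i % cfg.n_subtypes] for i in range(cfg.n_tumors)], dtype=object
    )

    normals = baseline[:, None] + rng.normal(0, cfg.noise_sd, size=(cfg.n_genes, cfg.n_normals))
    tumors = np.empty((cfg.n_genes, cfg.n_tumors))
    for j, st in enumerate(assignment):
        tumors[:, j] = templates[st] + rng.normal(0, cfg.noise_sd, size=cfg.n_genes)

    expr = pd.DataFrame(
        np.hstack([normals, tumors]), index=genes, columns=normal_ids + tumor_ids
    )
    phenotype = pd.Series(
        [NORMAL_LABEL] * cfg.n_normals + [TUMOR_LABEL] * cfg.n_tumors,
        index=expr.columns,
        name="phenotype",
    )
    truth = pd.Series(
        [NORMAL_LABEL] * cfg.n_normals + list(assignment),
        index=expr.columns,
        name="subtype",
    )
    return SyntheticCohort(
        expr=expr,
        net=net,
        phenotype=phenotype,
        truth=truth,
        perturbed_edges=perturbed_edges,
        informative_genes=informative,
        config=cfg,
        baseline=pd.Series(baseline, index=genes, name="baseline"),
        templates=pd.DataFrame({st: templates[st] for st in subtypes}, index=genes),
    )


def resample_cohort(
    cohort: SyntheticCohort,
    n_normals: Optional[int] = None,
    n_tumors: Optional[int] = None,
    seed: Optional[int] = None,
    prefix: str = "V",
) -> SyntheticCohort:
    """Draw a fresh cohort from the same latent templates (a second cohort
    with the same subtype definitions but new samples/noise)."""
    if cohort.templates is None or cohort.baseline is None:
        raise ValueError("cohort lacks stored templates; regenerate with simulate_cohort")
    cfg = cohort.config
    n_normals = cfg.n_normals if n_normals is None else n_normals
    n_tumors = cfg.n_tumors if n_tumors is None else n_tumors
    rng = np.random.default_rng(seed)
    genes = list(cohort.baseline.index)
    subtypes = list(cohort.templates.columns)
    normal_ids = [f"{prefix}N{i:04d}" for i in range(1, n_normals + 1)]
    tumor_ids = [f"{prefix}T{i:04d}" for i in range(1, n_tumors + 1)]
    assignment = np.array(
        [subtypes[i % len(subtypes)] for i in range(n_tumors)], dtype=object
    )
    base = cohort.baseline.to_numpy()
    normals = base[:, None] + rng.normal(0, cfg.noise_sd, size=(len(genes), n_normals))
    tumors = np.empty((len(genes), n_tumors))
    for j, st in enumerate(assignment):
        tumors[:, j] = cohort.templates[st].to_numpy() + rng.normal(
            0, cfg.noise_sd, size=len(genes)
        )
    expr = pd.DataFrame(
        np.hstack([normals, tumors]), index=genes, columns=normal_ids + tumor_ids
    )
    phenotype = pd.Series(
        [NORMAL_LABEL] * n_normals + [TUMOR_LABEL] * n_tumors,
        index=expr.columns,
        name="phenotype",
    )
    truth = pd.Series(
        [NORMAL_LABEL] * n_normals + list(assignment), index=expr.columns, name="subtype"
    )
    return SyntheticCohort(
        expr=expr,
        net=cohort.net,
        phenotype=phenotype,
        truth=truth,
        perturbed_edges=cohort.perturbed_edges,
        informative_genes=cohort.informative_genes,
        config=cfg,
        baseline=cohort.baseline,
        templates=cohort.templates,
    )


def add_batch_effects(
    expr: pd.DataFrame, batch_sd: float = 0.5, seed: Optional[int] = None
) -> pd.DataFrame:
    """Add a constant per-gene offset (platform/batch shift) to a cohort."""
    rng = np.random.default_rng(seed)
    shifts = rng.normal(0, batch_sd, size=expr.shape[0])
    return expr.add(pd.Series(shifts, index=expr.index), axis=0)
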
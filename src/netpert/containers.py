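"""Shared data containers for the interaction-perturbation pipeline.

Conventions used throughout the package:

* Expression matrices are :class:`pandas.DataFrame` objects with genes as
  rows (index) and samples as columns.
* Phenotype / subtype labels are :class:`pandas.Series` indexed by sample id.
* Edge-level matrices (delta ranks, perturbations) are DataFrames whose index
  holds canonical edge ids of the form ``"geneA|geneB"`` with
  ``geneA < geneB`` lexicographically.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

NORMAL_LABEL = "normal"
TUMOR_LABEL = "tumor"

EDGE_SEP = "|"


def canonical_edge(a: str, b: str) -> Tuple[str, str]:
    """Canonical (lexicographic) orientation of an undirected gene pair."""
    return (a, b) if a <= b else (b, a)


def edge_id(a: str, b: str) -> str:
    a, b = canonical_edge(a, b)
    return f"{a}{EDGE_SEP}{b}"


def split_edge_id(eid: str) -> Tuple[str, str]:
    a, _, b = eid.partition(EDGE_SEP)
    return a, b


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected background network whose edges index perturbation features.

    Edges are stored deduplicated, self-loop free, in canonical lexicographic
    orientation, sorted for deterministic iteration order.
    """

    edges: Tuple[Tuple[str, str], ...]
    node_set: frozenset = field(init=False)

    def __post_init__(self):
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop edge ({a},{b}) in network")
            if a > b:
                raise ValueError(f"edge ({a},{b}) not in canonical orientation")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in network")
        object.__setattr__(
            self, "node_set", frozenset(g for e in self.edges for g in e)
        )

    @classmethod
    def from_edges(cls, pairs: Iterable[Tuple[str, str]]) -> "InteractionNetwork":
        """Build a network from raw pairs: canonicalize, drop self-loops, dedup."""
        seen = set()
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                continue
            seen.add(canonical_edge(a, b))
        return cls(edges=tuple(sorted(seen)))

    @property
    def edge_ids(self) -> List[str]:
        return [f"{a}{EDGE_SEP}{b}" for a, b in self.edges]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.node_set)

    def __len__(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.node_set))
        g.add_edges_from(self.edges)
        return g

    def subnetwork(self, edge_ids: Iterable[str]) -> "InteractionNetwork":
        """Restrict to a subset of edges given by ``"a|b"`` ids."""
        keep = set(edge_ids)
        return InteractionNetwork(
            edges=tuple(e for e in self.edges if f"{e[0]}{EDGE_SEP}{e[1]}" in keep)
        )


@dataclass(frozen=True)
class ScaleFreeFit:
    """Least-squares fit of log10(frequency) against log10(degree)."""

    slope: float
    r: float
    p_value: float
    n_points: int

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("correlation outside [-1, 1]")
        if self.n_points < 2:
            raise ValueError("fit needs at least 2 points")


@dataclass
class PerturbationMatrix:
    """Edges x samples matrix of benchmark-subtracted delta ranks.

    ``values`` rows are canonical edge ids, columns are sample ids.
    ``benchmark`` is the normal-tissue delta-rank vector that was subtracted.
    """

    values: pd.DataFrame
    benchmark: pd.Series
    n_normals: int
    normal_ids_hash: str

    @staticmethod
    def hash_sample_ids(ids: Iterable[str]) -> str:
        h = hashlib.sha256()
        for s in sorted(map(str, ids)):
            h.update(s.encode())
            h.update(b"\0")
        return h.hexdigest()[:16]

    @property
    def edge_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)


@dataclass
class DispersionReport:
    """Per-edge tumor vs normal dispersion comparison."""

    table: pd.DataFrame  # columns: tumor, normal (dispersion per edge)
    fraction_tumor_greater: float
    method: str
    p_value: float
    n_guarded: int = 0  # edges where the near-zero-mean CV guard fired


@dataclass
class EdgeSelectionResult:
    """Representative-edge selection outcome."""

    stats: pd.DataFrame  # per-edge: statistic, p, q, sd, mad, selected
    network: InteractionNetwork  # reduced network over selected edges
    q_threshold: float
    variability_cutoff: float
    fit: Optional[ScaleFreeFit]  # degree fit of the reduced network (None if degenerate)

    @property
    def n_edges(self) -> int:
        return self.network.n_edges

    @property
    def n_genes(self) -> int:
        return self.network.n_nodes

    @property
    def selected_edge_ids(self) -> List[str]:
        return list(self.stats.index[self.stats["selected"]])


@dataclass
class ConsensusRun:
    """One consensus-clustering run at a fixed cluster number K."""

    k: int
    consensus: pd.DataFrame  # samples x samples, entries in [0, 1]
    co_sampled: pd.DataFrame  # integer co-sampling counts
    labels: pd.Series  # final per-sample cluster in 1..K
    pac: float
    seed: Optional[int] = None
    params: Dict = field(default_factory=dict)

    def offdiag_entries(self) -> np.ndarray:
        """Upper-triangle off-diagonal consensus entries (the CDF support)."""
        m = self.consensus.to_numpy()
        iu = np.triu_indices_from(m, k=1)
        return m[iu]

    def cdf(self, u: float) -> float:
        e = self.offdiag_entries()
        return float(np.mean(e <= u))


@dataclass
class CoreSet:
    """Silhouette-based representative ('core') sample set."""

    silhouette: pd.Series  # per-sample silhouette width, in [-1, 1]
    core: pd.Series  # boolean flag per sample
    threshold: float

    @property
    def core_count(self) -> int:
        return int(self.core.sum())

    @property
    def core_samples(self) -> List[str]:
        return list(self.core.index[self.core])


@dataclass
class SamResult:
    """One-vs-rest SAM screen across subtypes.

    ``d``, ``q`` are genes x subtypes DataFrames; ``s0`` maps subtype to its
    fudge factor (median of the per-gene pooled sd vector for that contrast).
    """

    d: pd.DataFrame
    q: pd.DataFrame
    s: pd.DataFrame
    s0: Dict[str, float]
    selected: Dict[str, List[str]]
    n_perm: int

    @property
    def union_genes(self) -> List[str]:
        out = set()
        for genes in self.selected.values():
            out.update(genes)
        return sorted(out)


@dataclass
class SseaResult:
    """GSEA-style enrichment of a sample set in a ranked sample list."""

    es: float
    p_value: float
    n_perm: int
    leading_edge: List[str]
    ranked_samples: List[str] = field(default_factory=list)
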
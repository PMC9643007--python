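"""Interaction-perturbation construction.

The core representation: per sample, genes are ranked by expression
(ascending, average ties). For every network edge (a, b) in canonical
orientation the *delta rank* is ``rank(a) - rank(b)``. The *benchmark vector*
is the delta rank of the per-gene mean expression over all normal samples —
gene-pair rank relations are highly conserved in normal tissue, so this
single pseudo-sample captures the normal interaction structure. Subtracting
the benchmark from every sample's delta-rank column yields the
*interaction-perturbation matrix*: how far each gene pair's rank relation in
each individual deviates from normal tissue.

Because everything is rank-based, the representation is invariant under any
strictly increasing per-sample transform of expression.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import (
    NORMAL_LABEL,
    DispersionReport,
    EDGE_SEP,
    InteractionNetwork,
    PerturbationMatrix,
)

logger = logging.getLogger(__name__)


def rank_transform(
    expr: pd.DataFrame,
    net: Optional[InteractionNetwork] = None,
    restrict_to_network: bool = True,
) -> pd.DataFrame:
    """Per-sample expression ranks (ascending, rank 1 = lowest; ties averaged).

    By default ranks are computed over the intersection of measured genes and
    network genes, so results do not depend on off-network probes. Pass
    ``restrict_to_network=False`` to rank over all measured genes.
    """
    if net is not None and restrict_to_network:
        shared = sorted(set(expr.index) & set(net.node_set))
    else:
        shared = sorted(expr.index)
    if len(shared) < 2:
        raise ValueError(
            f"need at least 2 shared genes between expression and network, got {len(shared)}"
        )
    sub = expr.loc[shared]
    ranks = stats.rankdata(sub.to_numpy(), axis=0, method="average")
    return pd.DataFrame(ranks, index=sub.index, columns=sub.columns)


def delta_rank_matrix(ranks: pd.DataFrame, net: InteractionNetwork) -> pd.DataFrame:
    """Edges x samples matrix of within-sample rank differences.

    For canonical edge (a, b) with a < b: ``delta = rank(a) - rank(b)``.
    Edges with an unmeasured endpoint are dropped with a warning.
    """
    present = set(ranks.index)
    kept = [(a, b) for a, b in net.edges if a in present and b in present]
    dropped = net.n_edges - len(kept)
    if dropped:
        logger.warning("dropping %d edges with unmeasured endpoints", dropped)
    if not kept:
        raise ValueError("no network edge has both endpoints measured")
    pos = {g: i for i, g in enumerate(ranks.index)}
    ia = np.fromiter((pos[a] for a, _ in kept), dtype=int, count=len(kept))
    ib = np.fromiter((pos[b] for _, b in kept), dtype=int, count=len(kept))
    vals = ranks.to_numpy()
    deltas = vals[ia, :] - vals[ib, :]
    idx = [f"{a}{EDGE_SEP}{b}" for a, b in kept]
    return pd.DataFrame(deltas, index=idx, columns=ranks.columns)


def benchmark_vector(
    expr_normals: pd.DataFrame,
    net: InteractionNetwork,
    restrict_to_network: bool = True,
    mode: str = "mean_expression",
) -> pd.Series:
    """Normal-tissue benchmark delta-rank vector (one value per edge).

    Two averaging conventions are supported:

    * ``"mean_expression"`` (default): rank the per-gene *mean expression*
      over normals as a single pseudo-sample and take its delta ranks.
    * ``"mean_delta_rank"``: average the normals' per-sample delta-rank
      columns. This averages the interactions themselves, and it is the mode
      under which the whole perturbation matrix is exactly invariant to
      per-sample monotone transforms (the mean-expression profile's ranks
      are not transform-invariant).
    """
    if expr_normals.shape[1] < 1:
        raise ValueError("benchmark requires normal samples")
    if mode == "mean_expression":
        mean = expr_normals.mean(axis=1).to_frame(name="benchmark")
        ranks = rank_transform(mean, net, restrict_to_network=restrict_to_network)
        return delta_rank_matrix(ranks, net)["benchmark"]
    if mode == "mean_delta_rank":
        ranks = rank_transform(expr_normals, net, restrict_to_network=restrict_to_network)
        deltas = delta_rank_matrix(ranks, net)
        out = deltas.mean(axis=1)
        out.name = "benchmark"
        return out
    raise ValueError(f"unknown benchmark mode {mode!r}")


def perturbation_matrix(deltas: pd.DataFrame, bench: pd.Series) -> pd.DataFrame:
    """Subtract the benchmark vector from every delta-rank column."""
    if len(deltas.index) != len(bench.index) or (deltas.index != bench.index).any():
        mism = deltas.index.symmetric_difference(bench.index)
        first = mism[0] if len(mism) else deltas.index[np.argmax(deltas.index != bench.index)]
        raise ValueError(f"edge mismatch between delta matrix and benchmark: {first!r}")
    return deltas.sub(bench, axis=0)


def build_perturbation(
    expr: pd.DataFrame,
    phenotype: pd.Series,
    net: InteractionNetwork,
    restrict_to_network: bool = True,
    benchmark_mode: str = "mean_expression",
) -> PerturbationMatrix:
    """Full pipeline: ranks -> delta ranks -> normal benchmark -> perturbations.

    ``phenotype`` maps every sample column of ``expr`` to ``"normal"`` or
    ``"tumor"``; the benchmark is built from the normal columns, and the
    perturbation matrix covers all samples.
    """
    phenotype = phenotype.reindex(expr.columns)
    if phenotype.isna().any():
        missing = list(phenotype.index[phenotype.isna()])[:3]
        raise ValueError(f"samples missing phenotype labels: {missing}")
    normal_ids = list(phenotype.index[phenotype == NORMAL_LABEL])
    if not normal_ids:
        raise ValueError("benchmark requires normal samples")
    ranks = rank_transform(expr, net, restrict_to_network=restrict_to_network)
    deltas = delta_rank_matrix(ranks, net)
    bench = benchmark_vector(
        expr[normal_ids], net,
        restrict_to_network=restrict_to_network,
        mode=benchmark_mode,
    )
    pert = perturbation_matrix(deltas, bench)
    return PerturbationMatrix(
        values=pert,
        benchmark=bench,
        n_normals=len(normal_ids),
        normal_ids_hash=PerturbationMatrix.hash_sample_ids(normal_ids),
    )


_CV_GUARD = 1e-8


def dispersion_compare(
    pert: Union[pd.DataFrame, PerturbationMatrix],
    phenotype: pd.Series,
    method: str = "cv",
) -> DispersionReport:
    """Compare per-edge perturbation dispersion between tumor and normal.

    ``cv`` uses sd/|mean| with near-zero means guarded at 1e-8 (perturbations
    are centred near 0 by construction, so the guard matters and ``sd`` is
    offered as the robust alternative). Reports the fraction of edges whose
    tumor dispersion strictly exceeds the normal one, plus a paired Wilcoxon
    signed-rank p-value across edges.
    """
    if method not in {"cv", "sd"}:
        raise ValueError(f"unknown dispersion method {method!r}")
    values = pert.values if isinstance(pert, PerturbationMatrix) else pert
    phenotype = phenotype.reindex(values.columns)
    groups = {}
    for name in (NORMAL_LABEL, "tumor"):
        ids = list(phenotype.index[phenotype == name])
        if len(ids) < 2:
            raise ValueError(f"dispersion comparison needs >=2 {name} samples")
        groups[name] = values[ids].to_numpy()

    n_guarded = 0

    def disp(mat: np.ndarray) -> np.ndarray:
        sd = mat.std(axis=1, ddof=1)
        if method == "sd":
            return sd
        mean = np.abs(mat.mean(axis=1))
        nonlocal n_guarded
        n_guarded += int((mean < _CV_GUARD).sum())
        return sd / np.maximum(mean, _CV_GUARD)

    d_norm = disp(groups[NORMAL_LABEL])
    d_tum = disp(groups["tumor"])
    if n_guarded:
        logger.info("CV near-zero-mean guard applied on %d group-edge cells", n_guarded)
    frac = float(np.mean(d_tum > d_norm))
    diff = d_tum - d_norm
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(d_tum, d_norm, zero_method="wilcox").pvalue)
    table = pd.DataFrame({"tumor": d_tum, "normal": d_norm}, index=values.index)
    return DispersionReport(
        table=table,
        fraction_tumor_greater=frac,
        method=method,
        p_value=p,
        n_guarded=n_guarded,
    )


class PerturbationTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: samples x genes -> samples x edges.

    ``fit`` learns the benchmark delta-rank vector from a matrix of *normal*
    samples; ``transform`` maps any cohort measured on (a superset of) the
    same genes into interaction-perturbation space.

    Parameters
    ----------
    network : InteractionNetwork
        Background interaction network indexing the edge features.
    restrict_to_network : bool, default True
        Rank over network∩measured genes only.
    """

    def __init__(self, network: InteractionNetwork, restrict_to_network: bool = True):
        self.network = network
        self.restrict_to_network = restrict_to_network

    def fit(self, X: pd.DataFrame, y=None) -> "PerturbationTransformer":
        X = self._as_frame(X)
        self.genes_ = sorted(
            set(X.columns) & set(self.network.node_set)
            if self.restrict_to_network
            else X.columns
        )
        self.benchmark_ = benchmark_vector(
            X.T, self.network, restrict_to_network=self.restrict_to_network
        )
        self.n_normals_ = X.shape[0]
        self.edge_ids_ = list(self.benchmark_.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "benchmark_"):
            raise ValueError("PerturbationTransformer is not fitted")
        X = self._as_frame(X)
        expr = X.T
        ranks = rank_transform(expr, self.network, self.restrict_to_network)
        if list(ranks.index) != self.genes_:
            raise ValueError(
                "transform gene set differs from the fitted gene set; "
                "rank spaces would not be comparable"
            )
        deltas = delta_rank_matrix(ranks, self.network)
        return perturbation_matrix(deltas, self.benchmark_).T

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x genes DataFrame with gene-id columns")
        return X
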
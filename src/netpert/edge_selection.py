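"""Representative-edge selection.

Clustering operates on edges that (i) significantly separate tumor from
normal perturbation values and (ii) stay variable within tumors. Because
each latent subtype perturbs its own edge set, the tumor group on a truly
perturbed edge is a mixture (most tumors near the benchmark, one subtype far
from it): a pure location test has bounded power against such alternatives,
so the default differential test combines a location component (Wilcoxon
rank-sum) with a scale component (Brown-Forsythe) via a Bonferroni-combined
p-value. Either component can be used alone.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .containers import (
    NORMAL_LABEL,
    EdgeSelectionResult,
    InteractionNetwork,
    PerturbationMatrix,
)
from .io import degree_distribution_fit

logger = logging.getLogger(__name__)


def _as_values(pert: Union[pd.DataFrame, PerturbationMatrix]) -> pd.DataFrame:
    return pert.values if isinstance(pert, PerturbationMatrix) else pert


def _split_groups(values: pd.DataFrame, phenotype: pd.Series, min_n: int):
    phenotype = phenotype.reindex(values.columns)
    tum = values.loc[:, (phenotype == "tumor").to_numpy()]
    nor = values.loc[:, (phenotype == NORMAL_LABEL).to_numpy()]
    if tum.shape[1] < min_n or nor.shape[1] < min_n:
        raise ValueError(
            f"need >= {min_n} samples per group "
            f"(tumor={tum.shape[1]}, normal={nor.shape[1]})"
        )
    return tum.to_numpy(), nor.to_numpy()


def _brown_forsythe(x: np.ndarray, y: np.ndarray):
    """Vectorised Brown-Forsythe (median-centred Levene) test per row."""
    dx = np.abs(x - np.median(x, axis=1, keepdims=True))
    dy = np.abs(y - np.median(y, axis=1, keepdims=True))
    nx, ny = dx.shape[1], dy.shape[1]
    mx, my = dx.mean(axis=1), dy.mean(axis=1)
    grand = (dx.sum(axis=1) + dy.sum(axis=1)) / (nx + ny)
    between = nx * (mx - grand) ** 2 + ny * (my - grand) ** 2
    within = ((dx - mx[:, None]) ** 2).sum(axis=1) + ((dy - my[:, None]) ** 2).sum(axis=1)
    dof = nx + ny - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = between / (within / dof)
    f = np.where(within > 0, f, np.where(between > 0, np.inf, 0.0))
    p = stats.f.sf(f, 1, dof)
    return f, p


def differential_edge_test(
    pert: Union[pd.DataFrame, PerturbationMatrix],
    phenotype: pd.Series,
    method: str = "combined",
) -> pd.DataFrame:
    """Per-edge tumor vs normal test with BH-adjusted q-values.

    ``method`` is one of:

    * ``"wilcoxon"`` — two-sided Wilcoxon rank-sum (location only)
    * ``"levene"`` — Brown-Forsythe (scale only)
    * ``"combined"`` (default) — Bonferroni combination
      ``p = min(1, 2 min(p_location, p_scale))``

    Returns a DataFrame indexed by edge with columns ``statistic``,
    ``p_location``, ``p_scale``, ``p``, ``q``.
    """
    if method not in {"wilcoxon", "levene", "combined"}:
        raise ValueError(f"unknown test method {method!r}")
    values = _as_values(pert)
    tum, nor = _split_groups(values, phenotype, min_n=3)

    p_loc = np.full(values.shape[0], np.nan)
    stat = np.full(values.shape[0], np.nan)
    if method in {"wilcoxon", "combined"}:
        res = stats.mannwhitneyu(tum, nor, axis=1, alternative="two-sided")
        stat, p_loc = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
    p_sc = np.full(values.shape[0], np.nan)
    if method in {"levene", "combined"}:
        f, p_sc = _brown_forsythe(tum, nor)
        if method == "levene":
            stat = f

    if method == "wilcoxon":
        p = p_loc
    elif method == "levene":
        p = p_sc
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_loc, p_sc))
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stat, "p_location": p_loc, "p_scale": p_sc, "p": p, "q": q},
        index=values.index,
    )


def tumor_variability(
    pert: Union[pd.DataFrame, PerturbationMatrix],
    phenotype: pd.Series,
) -> pd.DataFrame:
    """Per-edge sd (ddof=1) and scaled MAD over tumor samples."""
    values = _as_values(pert)
    tum, _ = _split_groups(values, phenotype, min_n=2)
    sd = tum.std(axis=1, ddof=1)
    mad = 1.4826 * np.median(np.abs(tum - np.median(tum, axis=1, keepdims=True)), axis=1)
    return pd.DataFrame({"sd": sd, "mad": mad}, index=values.index)


def select_representative_network(
    stats_df: pd.DataFrame,
    variability: pd.DataFrame,
    net: InteractionNetwork,
    q_threshold: float = 0.05,
    variability_quantile: float = 0.5,
    variability_cutoff: Optional[float] = None,
    variability_measure: str = "sd",
) -> EdgeSelectionResult:
    """Keep edges that are significant AND variable; rebuild the network.

    The variability cutoff defaults to the ``variability_quantile`` quantile
    of the *significant-edge* variability distribution; pass an absolute
    ``variability_cutoff`` to bypass the quantile rule.
    """
    if not (0 < q_threshold <= 1):
        raise ValueError("q_threshold must be in (0, 1]")
    if variability_cutoff is None and not (0 <= variability_quantile <= 1):
        raise ValueError("variability_quantile must be in [0, 1]")
    stats_df, variability = stats_df.align(variability, join="inner", axis=0)
    var = variability[variability_measure].to_numpy()
    sig = (stats_df["q"] <= q_threshold).to_numpy()
    if variability_cutoff is None:
        if not sig.any():
            raise ValueError(
                "no significant edges at q_threshold="
                f"{q_threshold}; relax the threshold"
            )
        # quantile=0 must behave as a no-op cutoff (>= min always true)
        variability_cutoff = float(np.quantile(var[sig], variability_quantile))
        selected = sig & (var >= variability_cutoff)
    else:
        selected = sig & (var >= float(variability_cutoff))
    if not selected.any():
        raise ValueError(
            "selection is empty; relax q_threshold or the variability cutoff"
        )
    out = stats_df.copy()
    out[variability_measure] = var
    out["selected"] = selected
    reduced = net.subnetwork(out.index[selected])
    try:
        fit = degree_distribution_fit(reduced)
    except ValueError:
        logger.warning("reduced network has a degenerate degree distribution")
        fit = None
    logger.info(
        "selected %d/%d edges covering %d genes",
        reduced.n_edges,
        len(out),
        reduced.n_nodes,
    )
    return EdgeSelectionResult(
        stats=out,
        network=reduced,
        q_threshold=q_threshold,
        variability_cutoff=float(variability_cutoff),
        fit=fit,
    )


class RepresentativeEdgeSelector(TransformerMixin, BaseEstimator):
    """Sklearn-style feature selector over edge columns.

    ``fit`` expects X as samples x edges (the output orientation of
    :class:`~netpert.perturbation.PerturbationTransformer`) and
    ``y`` as per-sample phenotype labels ("normal"/"tumor").
    """

    def __init__(
        self,
        network: InteractionNetwork,
        q_threshold: float = 0.05,
        variability_quantile: float = 0.5,
        method: str = "combined",
    ):
        self.network = network
        self.q_threshold = q_threshold
        self.variability_quantile = variability_quantile
        self.method = method

    def fit(self, X: pd.DataFrame, y) -> "RepresentativeEdgeSelector":
        pert = X.T
        phen = pd.Series(np.asarray(y, dtype=object), index=X.index)
        stats_df = differential_edge_test(pert, phen, method=self.method)
        var = tumor_variability(pert, phen)
        self.result_ = select_representative_network(
            stats_df,
            var,
            self.network,
            q_threshold=self.q_threshold,
            variability_quantile=self.variability_quantile,
        )
        self.selected_edges_ = self.result_.selected_edge_ids
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_edges_"):
            raise ValueError("RepresentativeEdgeSelector is not fitted")
        return X[self.selected_edges_]

    def get_support(self) -> np.ndarray:
        return self.result_.stats["selected"].to_numpy()
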
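"""Consensus clustering with CDF/PAC model selection and silhouette core set.

For each candidate cluster number K, many subsampled runs of a base
clustering algorithm are accumulated into a consensus matrix: entry (i, j)
is the fraction of runs in which samples i and j co-clustered, among runs
where both were drawn. A clean K yields a near-binary consensus matrix; the
proportion of ambiguous clustering, PAC = CDF(u2) - CDF(u1) over the
off-diagonal consensus entries, quantifies the intermediate mass, and the K
minimising PAC is selected. Final labels come from an average-linkage
hierarchical cut of (1 - consensus), which is deterministic given the
matrix. Representative ("core") samples are those with positive silhouette
width under the 1 - consensus distance.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import pairwise_distances, silhouette_samples

from .containers import ConsensusRun, CoreSet, PerturbationMatrix

logger = logging.getLogger(__name__)


def _kmedoids(X: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 50) -> np.ndarray:
    """Plain alternating k-medoids (PAM-lite) on Euclidean distances."""
    d = pairwise_distances(X)
    n = d.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    labels = np.argmin(d[:, medoids], axis=1)
    for _ in range(n_iter):
        new_medoids = medoids.copy()
        for j in range(k):
            members = np.where(labels == j)[0]
            if members.size == 0:
                continue
            costs = d[np.ix_(members, members)].sum(axis=0)
            new_medoids[j] = members[np.argmin(costs)]
        new_labels = np.argmin(d[:, new_medoids], axis=1)
        if np.array_equal(new_medoids, medoids) and np.array_equal(new_labels, labels):
            break
        medoids, labels = new_medoids, new_labels
    return labels


def _base_cluster(
    X: np.ndarray, k: int, base: str, rng: np.random.Generator, n_init: int = 1
) -> np.ndarray:
    if base == "kmeans":
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed)
        return km.fit_predict(X)
    if base == "hclust":
        return AgglomerativeClustering(n_clusters=k, linkage="average").fit_predict(X)
    if base == "kmedoids":
        return _kmedoids(X, k, rng)
    raise ValueError(f"unknown base clustering method {base!r}")


def consensus_cluster(
    X: Union[pd.DataFrame, np.ndarray],
    k: int,
    n_reps: int = 500,
    subsample_fraction: float = 0.8,
    base: str = "kmeans",
    seed: Optional[int] = None,
    pac_window: tuple = (0.1, 0.9),
    n_init: int = 1,
) -> ConsensusRun:
    """Consensus clustering at a fixed K.

    ``X`` is samples x features (transpose an edges x samples perturbation
    matrix before calling). Runs are bit-reproducible for a fixed seed.

    ``n_init=1`` (a single k-means++ start per subsample) is deliberate:
    consensus clustering needs run-to-run diversity, and multi-restart
    k-means collapses every rep onto the same local optimum, making wrong K
    values look spuriously stable.
    """
    if isinstance(X, PerturbationMatrix):
        X = X.values.T
    if isinstance(X, pd.DataFrame):
        sample_ids = list(X.index)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        sample_ids = [f"s{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n <= k:
        raise ValueError(f"need more samples ({n}) than clusters ({k})")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0 < subsample_fraction <= 1):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if np.allclose(mat.std(axis=0), 0):
        raise ValueError("zero-variance feature matrix")

    rng = np.random.default_rng(seed)
    m = math.ceil(subsample_fraction * n)
    co_cluster = np.zeros((n, n), dtype=np.int32)
    co_sampled = np.zeros((n, n), dtype=np.int32)
    ever_drawn = np.zeros(n, dtype=bool)
    for _ in range(n_reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        ever_drawn[idx] = True
        labels = _base_cluster(mat[idx], k, base, rng, n_init=n_init)
        co_sampled[np.ix_(idx, idx)] += 1
        for c in np.unique(labels):
            members = idx[labels == c]
            co_cluster[np.ix_(members, members)] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        consensus = np.where(co_sampled > 0, co_cluster / np.maximum(co_sampled, 1), 0.0)
    np.fill_diagonal(consensus, np.where(ever_drawn, 1.0, 0.0))

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")

    run = ConsensusRun(
        k=k,
        consensus=pd.DataFrame(consensus, index=sample_ids, columns=sample_ids),
        co_sampled=pd.DataFrame(co_sampled, index=sample_ids, columns=sample_ids),
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        pac=np.nan,
        seed=seed,
        params={
            "n_reps": n_reps,
            "subsample_fraction": subsample_fraction,
            "base": base,
        },
    )
    run.pac = pac(run, *pac_window)
    return run


def pac(
    run: Union[ConsensusRun, Sequence[float]],
    u1: float = 0.1,
    u2: float = 0.9,
) -> float:
    """Proportion of ambiguous clustering: CDF(u2) - CDF(u1).

    The empirical CDF is taken over the off-diagonal upper-triangle consensus
    entries. Accepts a :class:`ConsensusRun` or a flat entry sequence.
    """
    if not (0 <= u1 < u2 <= 1):
        raise ValueError("need 0 <= u1 < u2 <= 1")
    if isinstance(run, ConsensusRun):
        entries = run.offdiag_entries()
    else:
        entries = np.asarray(list(run), dtype=float)
    if entries.size == 0:
        raise ValueError("no consensus entries")
    return float(np.mean(entries <= u2) - np.mean(entries <= u1))


def select_k(runs: Iterable[ConsensusRun]) -> int:
    """K minimising PAC; ties broken toward the smaller K."""
    runs = list(runs)
    if not runs:
        raise ValueError("no consensus runs supplied")
    best = min(runs, key=lambda r: (r.pac, r.k))
    return best.k


def cdf_table(runs: Iterable[ConsensusRun], grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Empirical consensus CDF per K on a common grid (for inspection/plots)."""
    if grid is None:
        grid = np.linspace(0, 1, 101)
    out = {}
    for run in runs:
        e = run.offdiag_entries()
        out[run.k] = [float(np.mean(e <= u)) for u in grid]
    df = pd.DataFrame(out, index=pd.Index(grid, name="u"))
    df.columns.name = "K"
    return df


def silhouette_core(run: ConsensusRun, threshold: float = 0.0) -> CoreSet:
    """Silhouette widths under distance = 1 - consensus; core = s(i) > threshold.

    Samples in singleton clusters get s(i) = 0 by convention (logged).
    """
    labels = run.labels.to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires >= 2 clusters")
    counts = pd.Series(labels).value_counts()
    if (counts == 1).any():
        logger.warning(
            "%d singleton clusters; their members get silhouette 0",
            int((counts == 1).sum()),
        )
    dist = 1.0 - run.consensus.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    s = silhouette_samples(dist, labels, metric="precomputed")
    sil = pd.Series(s, index=run.consensus.index, name="silhouette")
    core = sil > threshold
    core.name = "core"
    return CoreSet(silhouette=sil, core=core, threshold=threshold)


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Sklearn-style consensus clustering estimator.

    Parameters mirror :func:`consensus_cluster`. After ``fit``:

    * ``labels_`` — final cluster labels (1..K)
    * ``consensus_`` — the consensus matrix (DataFrame)
    * ``pac_`` — PAC score of the run
    """

    def __init__(
        self,
        n_clusters: int = 2,
        n_reps: int = 500,
        subsample_fraction: float = 0.8,
        base: str = "kmeans",
        random_state: Optional[int] = None,
        pac_window: tuple = (0.1, 0.9),
        n_init: int = 1,
    ):
        self.n_clusters = n_clusters
        self.n_reps = n_reps
        self.subsample_fraction = subsample_fraction
        self.base = base
        self.random_state = random_state
        self.pac_window = pac_window
        self.n_init = n_init

    def fit(self, X, y=None) -> "ConsensusClustering":
        run = consensus_cluster(
            X,
            k=self.n_clusters,
            n_reps=self.n_reps,
            subsample_fraction=self.subsample_fraction,
            base=self.base,
            seed=self.random_state,
            pac_window=self.pac_window,
            n_init=self.n_init,
        )
        self.run_ = run
        self.labels_ = run.labels.to_numpy()
        self.consensus_ = run.consensus
        self.pac_ = run.pac
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def sweep_k(
    X,
    k_values: Sequence[int],
    seed: Optional[int] = None,
    **kwargs,
) -> List[ConsensusRun]:
    """Run consensus clustering for each K with per-K seeds spawned from ``seed``."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(list(k_values)))
    runs = []
    for k, child in zip(k_values, children):
        child_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        runs.append(consensus_cluster(X, k=k, seed=child_seed, **kwargs))
    return runs
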
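"""Readers and writers for expression matrices, phenotype labels and
interaction networks, plus scale-free degree-distribution diagnostics.

Expression files are TSV/CSV with gene ids in the first column and sample ids
in the header row. Networks are two-column edge-list TSVs or SIF files.
Phenotype files are two-column TSVs (sample id, label). All writers emit
deterministic row/column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .containers import InteractionNetwork, ScaleFreeFit

logger = logging.getLogger(__name__)

_SEPS = {"tsv": "\t", "csv": ","}


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


def read_expression(
    path: Union[str, Path],
    fmt: str = "tsv",
    log_transform: bool = False,
    na_action: str = "error",
) -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Duplicate gene rows are collapsed to the row with the highest mean
    expression (logged). Missing or non-numeric cells raise a
    :class:`LoadError` naming the offending cell unless ``na_action`` is
    ``"row_mean"``, in which case they are imputed by the gene's row mean.

    Parameters
    ----------
    log_transform:
        If True, apply ``log2(x + 1)`` after loading (for count-like input).
    """
    path = Path(path)
    if fmt not in _SEPS:
        raise LoadError(f"unknown expression format {fmt!r}")
    if not path.exists():
        raise LoadError(f"expression file not found: {path}")
    try:
        df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"empty expression file: {path}") from exc
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise LoadError(f"expression file {path} has no genes or no samples")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise LoadError(f"duplicate sample id {dup!r} in header of {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        if na_action == "row_mean":
            n_bad = int(bad.to_numpy().sum())
            logger.warning("imputing %d missing cells by row mean", n_bad)
            numeric = numeric.apply(lambda row: row.fillna(row.mean()), axis=1)
            if numeric.isna().to_numpy().any():
                raise LoadError("imputation failed: a gene row is entirely missing")
        else:
            i, j = np.argwhere(bad.to_numpy())[0]
            raise LoadError(
                f"non-numeric or missing value at gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r} in {path}"
            )
    df = numeric

    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        logger.warning(
            "collapsing %d duplicated gene ids by highest mean expression: %s",
            len(dups),
            ", ".join(dups[:5]),
        )
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        df = df.sort_index()

    if log_transform:
        if (df.to_numpy() < 0).any():
            raise LoadError("log transform requested but matrix has negative values")
        df = np.log2(df + 1.0)
    return df


def write_expression(df: pd.DataFrame, path: Union[str, Path], fmt: str = "tsv") -> None:
    df.to_csv(Path(path), sep=_SEPS[fmt], index_label="gene_id")


def read_phenotype(path: Union[str, Path]) -> pd.Series:
    """Read a two-column (sample id, label) TSV into a Series."""
    df = pd.read_csv(Path(path), sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise LoadError(f"phenotype file {path} needs two columns")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="label")
    if s.index.duplicated().any():
        raise LoadError(f"duplicate sample ids in phenotype file {path}")
    return s


def write_phenotype(labels: pd.Series, path: Union[str, Path]) -> None:
    out = labels.rename("label").rename_axis("sample_id").reset_index()
    out.to_csv(Path(path), sep="\t", index=False)


def read_network(path: Union[str, Path], fmt: str = "edge_tsv") -> InteractionNetwork:
    """Read an undirected interaction network.

    ``edge_tsv`` files have one gene pair per row (extra columns ignored).
    ``sif`` rows are ``source<tab>relation<tab>target [target2 ...]``.
    Self-loop rows are dropped with a warning; duplicates (in either
    orientation) collapse onto the canonical lexicographic edge.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"network file not found: {path}")
    pairs = []
    n_self = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or line.startswith("#"):
                continue
            if ln == 1 and fields[0].lower() in {"gene_a", "source", "from", "node1"}:
                continue  # header row
            if fmt == "edge_tsv":
                if len(fields) < 2:
                    raise LoadError(f"network row {ln} has fewer than two columns")
                targets = [(fields[0], fields[1])]
            elif fmt == "sif":
                if len(fields) < 3:
                    # SIF permits isolated nodes (single field); skip them
                    continue
                targets = [(fields[0], t) for t in fields[2:]]
            else:
                raise LoadError(f"unknown network format {fmt!r}")
            for a, b in targets:
                if a == b:
                    n_self += 1
                    continue
                pairs.append((a, b))
    if n_self:
        logger.warning("dropped %d self-loop rows from %s", n_self, path)
    if not pairs:
        raise LoadError(f"network file {path} contains no usable edges")
    return InteractionNetwork.from_edges(pairs)


def write_network(net: InteractionNetwork, path: Union[str, Path]) -> None:
    with open(Path(path), "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in net.edges:
            fh.write(f"{a}\t{b}\n")


def degree_histogram(net: InteractionNetwork) -> Dict[int, int]:
    """Observed degree -> node count, zero-count degrees omitted."""
    g = net.to_networkx()
    degs = [d for _, d in g.degree()]
    vals, counts = np.unique(degs, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, counts) if v > 0}


def fit_degree_histogram(hist: Dict[int, int]) -> ScaleFreeFit:
    """Least-squares regression of log10(count) on log10(degree).

    A scale-free network shows an approximately linear decreasing relation;
    the Pearson r of the fit is the headline diagnostic.
    """
    pts = sorted((k, c) for k, c in hist.items() if k > 0 and c > 0)
    if len(pts) < 2:
        raise ValueError("degenerate degree distribution: <2 distinct degrees")
    x = np.log10([k for k, _ in pts])
    y = np.log10([c for _, c in pts])
    res = stats.linregress(x, y)
    return ScaleFreeFit(
        slope=float(res.slope),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_points=len(pts),
    )


def degree_distribution_fit(net: InteractionNetwork) -> ScaleFreeFit:
    """Scale-free diagnostic for a network (see :func:`fit_degree_histogram`)."""
    return fit_degree_histogram(degree_histogram(net))
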
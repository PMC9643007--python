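"""Sample Set Enrichment Analysis (SSEA).

For a pathway and a subtype, each sample gets an *integrated score*: the
mean expression of pathway genes positively correlated with subtype
membership minus the mean over the negatively correlated genes. Samples are
then ranked by this score and the GSEA running-sum statistic is applied to
the ranked *sample* list, testing whether the subtype's sample set
concentrates at high ranks. Significance comes from permuting the sample
set (random same-size sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import SseaResult

logger = logging.getLogger(__name__)


@dataclass
class IntegratedScore:
    """Per-sample integrated pathway score with gene-set provenance."""

    scores: pd.Series
    pos_genes: List[str]
    neg_genes: List[str]
    pathway: Optional[str] = None


def subtype_correlated_genes(
    expr: pd.DataFrame,
    labels: pd.Series,
    subtype: str,
    q_threshold: float = 0.05,
) -> Tuple[List[str], List[str]]:
    """Split genes into positively / negatively subtype-correlated sets.

    Point-biserial correlation (Pearson against the membership indicator),
    BH-adjusted across genes; constant genes are excluded (logged).
    """
    labels = labels.reindex(expr.columns)
    if subtype not in set(labels):
        raise ValueError(f"subtype {subtype!r} absent from labels")
    y = (labels == subtype).to_numpy(dtype=float)
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean()
    sx = np.sqrt((xm**2).sum(axis=1))
    sy = float(np.sqrt((ym**2).sum()))
    constant = sx == 0
    if constant.any():
        logger.info("excluding %d constant genes from correlation", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ ym) / (sx * sy)
    valid = ~constant & np.isfinite(r)
    r_valid = np.clip(r[valid], -1 + 1e-15, 1 - 1e-15)
    t = r_valid * np.sqrt((n - 2) / (1 - r_valid**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    q = multipletests(p, method="fdr_bh")[1]
    genes = expr.index[valid]
    pos = sorted(genes[(q <= q_threshold) & (r_valid > 0)])
    neg = sorted(genes[(q <= q_threshold) & (r_valid < 0)])
    if not pos and not neg:
        raise ValueError(f"no genes correlated with subtype {subtype!r} at q<={q_threshold}")
    return pos, neg


def integrated_score(
    expr: pd.DataFrame,
    pos: Sequence[str],
    neg: Sequence[str],
    pathway: Optional[str] = None,
) -> IntegratedScore:
    """score(s) = mean over pos genes - mean over neg genes, per sample."""
    pos, neg = list(pos), list(neg)
    if set(pos) & set(neg):
        raise ValueError("pos and neg gene sets must be disjoint")
    pos_m = [g for g in pos if g in expr.index]
    neg_m = [g for g in neg if g in expr.index]
    if not pos_m and not neg_m:
        raise ValueError("no measured genes in either set")
    pos_term = expr.loc[pos_m].mean(axis=0) if pos_m else 0.0
    if neg_m:
        neg_term = expr.loc[neg_m].mean(axis=0)
    else:
        logger.info("empty/unmeasured negative set; second term is 0")
        neg_term = 0.0
    scores = pos_term - neg_term
    scores.name = "integrated_score"
    return IntegratedScore(scores=scores, pos_genes=pos_m, neg_genes=neg_m, pathway=pathway)


def _running_es(order_is_hit: np.ndarray, weights: np.ndarray) -> Tuple[float, int]:
    """Signed maximal deviation of the GSEA running sum; returns (ES, peak)."""
    n = order_is_hit.size
    n_hit = int(order_is_hit.sum())
    hit_w = np.where(order_is_hit, weights, 0.0)
    total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~order_is_hit) / (n - n_hit)
    running = p_hit - p_miss
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def ssea_enrichment(
    scores: Union[pd.Series, IntegratedScore],
    sample_set: Iterable[str],
    weight: int = 1,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> SseaResult:
    """GSEA-style enrichment of a sample set in the score-ranked sample list.

    Samples are ranked by decreasing score. The running sum increments by
    ``|score|^weight / sum(|score|^weight over the set)`` at member samples
    (``weight=0`` gives the unweighted Kolmogorov-Smirnov form) and
    decrements by ``1/(N - N_set)`` elsewhere; ES is the signed maximal
    deviation. The p-value is the add-one-smoothed fraction of ``n_perm``
    random same-size sample sets with ``|ES|`` at least as large.
    """
    if isinstance(scores, IntegratedScore):
        scores = scores.scores
    if weight not in (0, 1):
        raise ValueError("weight must be 0 or 1")
    sample_set = list(dict.fromkeys(sample_set))
    if not sample_set:
        raise ValueError("sample_set is empty")
    missing = [s for s in sample_set if s not in scores.index]
    if missing:
        raise ValueError(f"sample-set members not in scores: {missing[:5]}")
    n = len(scores)
    if len(sample_set) >= n:
        raise ValueError("sample_set must be a strict subset of all samples")

    # decreasing score; ties broken by sample id for determinism
    tmp = scores.rename("score").rename_axis("sample").reset_index()
    tmp = tmp.sort_values(["score", "sample"], ascending=[False, True], kind="mergesort")
    order = pd.Series(tmp["score"].to_numpy(), index=tmp["sample"].to_numpy())
    ranked = list(order.index)
    is_hit = np.asarray([s in set(sample_set) for s in ranked])
    w = np.abs(order.to_numpy()) ** weight if weight else np.ones(n)
    es, peak = _running_es(is_hit, w)
    leading = [s for s, h in zip(ranked[: peak + 1], is_hit[: peak + 1]) if h] if es > 0 else []

    rng = np.random.default_rng(seed)
    k = len(sample_set)
    count = 0
    for _ in range(n_perm):
        perm_hit = np.zeros(n, dtype=bool)
        perm_hit[rng.choice(n, size=k, replace=False)] = True
        es_p, _ = _running_es(perm_hit, w)
        if abs(es_p) >= abs(es):
            count += 1
    p = (count + 1) / (n_perm + 1)
    return SseaResult(
        es=es, p_value=p, n_perm=n_perm, leading_edge=leading, ranked_samples=ranked
    )


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def run_ssea(
    expr: pd.DataFrame,
    labels: pd.Series,
    genesets: Dict[str, Sequence[str]],
    q_threshold: float = 0.05,
    weight: int = 1,
    n_perm: int = 1000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """SSEA over every (pathway, subtype) pair.

    Per pathway, genes are restricted to the set, split into pos/neg by
    correlation with the subtype, reduced to an integrated score, and the
    subtype's sample set is tested for enrichment at high ranks. Returns a
    tidy frame (pathway, subtype, ES, p, q).
    """
    labels = labels.reindex(expr.columns)
    ss = np.random.SeedSequence(seed)
    rows = []
    subtypes = sorted(labels.unique())
    pairs = [(p, s) for p in sorted(genesets) for s in subtypes]
    children = ss.spawn(len(pairs))
    for (pathway, subtype), child in zip(pairs, children):
        genes = [g for g in genesets[pathway] if g in expr.index]
        if len(genes) < 2:
            continue
        sub_expr = expr.loc[genes]
        try:
            pos, neg = subtype_correlated_genes(sub_expr, labels, subtype, q_threshold)
        except ValueError:
            continue
        score = integrated_score(sub_expr, pos, neg, pathway=pathway)
        members = list(labels.index[labels == subtype])
        res = ssea_enrichment(
            score.scores,
            members,
            weight=weight,
            n_perm=n_perm,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
        )
        rows.append(
            {"pathway": pathway, "subtype": subtype, "es": res.es, "p": res.p_value}
        )
    out = pd.DataFrame(rows, columns=["pathway", "subtype", "es", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
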
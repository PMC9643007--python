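"""Subtype classifiers.

Two classifier families are provided:

1. The centroid family used to propagate discovered subtypes to new cohorts:
   a one-vs-rest SAM screen (moderated t-like statistic with a fudge factor
   and permutation q-values), a nearest-shrunken-centroid (PAM) model with a
   cross-validated shrinkage path, a diagonal quadratic discriminant (DQDA)
   rule over the surviving gene panel, and a correlation-based cross-cohort
   assignment mode for heterogeneous platforms.

2. A compact "miniclassifier" chain for clinical assays: one-vs-rest
   differential expression, a bootstrap univariable-logistic robustness
   screen, multinomial LASSO panel selection under the one-standard-error
   rule, and a random forest over the final panel, evaluated with a
   stratified 70/30 split.

Function-level APIs take genes x samples expression frames (matching the
file formats); the sklearn-style estimators take samples x genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

from .containers import SamResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# SAM screen
# ---------------------------------------------------------------------------


def _sam_stats(x: np.ndarray, mask: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene SAM d and pooled s for a binary contrast (mask vs rest)."""
    x1, x2 = x[:, mask], x[:, ~mask]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return m1 - m2, s


def sam_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_perm: int = 200,
    fdr: float = 0.05,
    seed: Optional[int] = None,
) -> SamResult:
    """One-vs-rest significance analysis of microarrays across subtypes.

    For each subtype the statistic is ``d_i = (mean_in - mean_rest) /
    (s_i + s0)`` with ``s0`` the median of the per-gene pooled sd vector.
    Per-gene p-values come from a pooled label-permutation null (all genes,
    all permutations) and are BH-adjusted; genes with ``q <= fdr`` are
    selected for that subtype.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    labels = labels.reindex(expr.columns)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError("need >= 2 samples per class")
    x = expr.to_numpy(dtype=float)
    genes = expr.index
    rng = np.random.default_rng(seed)

    d_obs, s_obs, s0s = {}, {}, {}
    for c in classes:
        mask = (labels == c).to_numpy()
        num, s = _sam_stats(x, mask)
        s0 = float(np.median(s))
        s0s[c] = s0
        d_obs[c] = num / (s + s0)
        s_obs[c] = s

    null_abs = {c: [] for c in classes}
    lab_arr = labels.to_numpy()
    for _ in range(n_perm):
        perm = rng.permutation(lab_arr)
        for c in classes:
            mask = perm == c
            num, s = _sam_stats(x, mask)
            null_abs[c].append(np.abs(num / (s + s0s[c])))

    q_df = {}
    for c in classes:
        pool = np.sort(np.concatenate(null_abs[c]))
        obs = np.abs(d_obs[c])
        # exceedance count via right-tail searchsorted on the pooled null
        n_ge = pool.size - np.searchsorted(pool, obs, side="left")
        p = (1.0 + n_ge) / (1.0 + pool.size)
        q_df[c] = multipletests(p, method="fdr_bh")[1]

    d = pd.DataFrame(d_obs, index=genes)
    q = pd.DataFrame(q_df, index=genes)
    s = pd.DataFrame(s_obs, index=genes)
    selected = {c: list(genes[q[c] <= fdr]) for c in classes}
    return SamResult(d=d, q=q, s=s, s0=s0s, selected=selected, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Nearest shrunken centroid (PAM)
# ---------------------------------------------------------------------------


class ShrunkenCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest shrunken centroid classifier with a CV-chosen shrinkage.

    Class centroids are soft-thresholded toward the overall centroid:
    ``d'_ik = sign(d_ik) (|d_ik| - delta)_+`` where
    ``d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0))``,
    ``m_k = sqrt(1/n_k - 1/n)`` and ``s0 = median(s_i)``. Genes whose
    shrunken difference is zero for every class drop out of the model.
    ``shrinkage="cv"`` picks delta by stratified cross-validation minimising
    misclassification, breaking ties toward the larger delta (fewer genes).
    """

    def __init__(
        self,
        shrinkage: Union[str, float] = "cv",
        delta_grid: Optional[Sequence[float]] = None,
        cv: int = 10,
        random_state: Optional[int] = None,
    ):
        self.shrinkage = shrinkage
        self.delta_grid = delta_grid
        self.cv = cv
        self.random_state = random_state

    # -- internal statistics -------------------------------------------------

    @staticmethod
    def _stats(x: np.ndarray, y: np.ndarray, classes: np.ndarray):
        n, g = x.shape
        k = len(classes)
        overall = x.mean(axis=0)
        centroids = np.empty((g, k))
        nk = np.empty(k)
        ss = np.zeros(g)
        for j, c in enumerate(classes):
            sub = x[y == c]
            nk[j] = sub.shape[0]
            centroids[:, j] = sub.mean(axis=0)
            ss += ((sub - centroids[:, j]) ** 2).sum(axis=0)
        s = np.sqrt(ss / (n - k))
        s0 = float(np.median(s))
        m = np.sqrt(1.0 / nk - 1.0 / n)
        d = (centroids - overall[:, None]) / (m[None, :] * (s + s0)[:, None])
        priors = nk / n
        return overall, centroids, s, s0, m, d, priors

    @staticmethod
    def _shrink(d: np.ndarray, delta: float) -> np.ndarray:
        return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)

    @staticmethod
    def _discriminant(
        x: np.ndarray, overall, s, s0, m, dshr, priors
    ) -> np.ndarray:
        centroids = overall[:, None] + (m[None, :] * (s + s0)[:, None]) * dshr
        denom = (s + s0) ** 2
        # score_k(x) = sum_i (x_i - c_ik)^2 / (s_i+s0)^2 - 2 log pi_k ; lower wins
        diff = x[:, :, None] - centroids[None, :, :]
        score = (diff**2 / denom[None, :, None]).sum(axis=1) - 2.0 * np.log(priors)[None, :]
        return score

    # -- sklearn API ---------------------------------------------------------

    def fit(self, X, y) -> "ShrunkenCentroidClassifier":
        X, feature_names = _as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        overall, centroids, s, s0, m, d, priors = self._stats(X, y, classes)
        max_d = float(np.abs(d).max())
        if self.delta_grid is None:
            grid = np.linspace(0.0, max_d, 30)
        else:
            grid = np.asarray(list(self.delta_grid), dtype=float)
            if grid.size == 0:
                raise ValueError("delta_grid is empty")

        if self.shrinkage == "cv":
            delta, cv_errors = self._cv_choose(X, y, classes, grid)
            self.cv_errors_ = cv_errors
        else:
            delta = float(self.shrinkage)
            self.cv_errors_ = None

        dshr = self._shrink(d, delta)
        survivors = np.abs(dshr).sum(axis=1) > 0
        if not survivors.any():
            raise ValueError(f"no genes survive shrinkage delta={delta}")

        self.classes_ = classes
        self.feature_names_ = feature_names
        self.overall_centroid_ = overall
        self.centroids_ = centroids
        self.s_ = s
        self.s0_ = s0
        self.m_ = m
        self.d_ = d
        self.delta_ = delta
        self.shrunken_d_ = dshr
        self.shrunken_centroids_ = overall[:, None] + (m[None, :] * (s + s0)[:, None]) * dshr
        self.priors_ = priors
        self.survivors_ = [feature_names[i] for i in np.where(survivors)[0]]
        self.feature_medians_ = np.median(X, axis=0)
        return self

    def _cv_choose(self, X, y, classes, grid):
        min_class = int(pd.Series(y).value_counts().min())
        folds = min(self.cv, min_class)
        if folds < 2:
            raise ValueError("smallest class has <2 samples; cannot cross-validate")
        if folds < self.cv:
            logger.warning("reducing CV folds from %d to %d (small class)", self.cv, folds)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        errors = np.zeros(len(grid))
        for tr, va in skf.split(X, y):
            overall, _, s, s0, m, d, priors = self._stats(X[tr], y[tr], classes)
            for gi, delta in enumerate(grid):
                dshr = self._shrink(d, delta)
                score = self._discriminant(X[va], overall, s, s0, m, dshr, priors)
                pred = classes[np.argmin(score, axis=1)]
                errors[gi] += (pred != y[va]).sum()
        errors /= len(y)
        best_err = errors.min()
        # ties -> larger delta (sparser model)
        best_idx = np.where(errors == best_err)[0][-1]
        return float(grid[best_idx]), pd.Series(errors, index=grid, name="cv_error")

    def decision_function(self, X) -> np.ndarray:
        X, _ = _as_matrix(X, self.feature_names_)
        return -self._discriminant(
            X, self.overall_centroid_, self.s_, self.s0_, self.m_, self.shrunken_d_, self.priors_
        )

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "shrunken_centroid",
                "classes": [str(c) for c in self.classes_],
                "features": list(self.feature_names_),
                "overall_centroid": self.overall_centroid_.tolist(),
                "shrunken_centroids": self.shrunken_centroids_.tolist(),
                "s": self.s_.tolist(),
                "s0": self.s0_,
                "m": self.m_.tolist(),
                "shrunken_d": self.shrunken_d_.tolist(),
                "priors": self.priors_.tolist(),
                "delta": self.delta_,
                "feature_medians": self.feature_medians_.tolist(),
            }
        )


def train_shrunken_centroid(
    expr: pd.DataFrame,
    labels: pd.Series,
    delta_grid: Optional[Sequence[float]] = None,
    cv_folds: int = 10,
    seed: Optional[int] = None,
) -> ShrunkenCentroidClassifier:
    """Fit a CV-tuned shrunken-centroid model on genes x samples input."""
    labels = labels.reindex(expr.columns)
    model = ShrunkenCentroidClassifier(
        shrinkage="cv", delta_grid=delta_grid, cv=cv_folds, random_state=seed
    )
    return model.fit(expr.T, labels.to_numpy())


# ---------------------------------------------------------------------------
# DQDA
# ---------------------------------------------------------------------------


class DqdaClassifier(ClassifierMixin, BaseEstimator):
    """Diagonal quadratic discriminant analysis.

    Gaussian class-conditional model with class-specific per-gene variances
    and no covariances:

    ``delta_k(x) = -sum_i [ (x_i - mu_ik)^2 / (2 sigma2_ik)
    + 0.5 log sigma2_ik ] + log pi_k``

    Samples are assigned to the argmax class (ties deterministically to the
    lowest class index). Variances are floored at
    ``var_floor_frac * pooled variance`` per gene to keep the rule finite.
    """

    def __init__(self, var_floor_frac: float = 1e-6):
        self.var_floor_frac = var_floor_frac

    def fit(self, X, y) -> "DqdaClassifier":
        X, feature_names = _as_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        pooled = X.var(axis=0, ddof=1)
        floor = np.maximum(self.var_floor_frac * pooled, 1e-12)
        means, variances, priors = [], [], []
        for c in classes:
            sub = X[y == c]
            if sub.shape[0] < 2:
                raise ValueError(f"class {c!r} has <2 samples; variance undefined")
            means.append(sub.mean(axis=0))
            variances.append(np.maximum(sub.var(axis=0, ddof=1), floor))
            priors.append(sub.shape[0] / X.shape[0])
        self.classes_ = classes
        self.feature_names_ = feature_names
        self.means_ = np.vstack(means)  # classes x genes
        self.variances_ = np.vstack(variances)
        self.priors_ = np.asarray(priors)
        self.feature_medians_ = np.median(X, axis=0)
        return self

    def decision_function(self, X) -> np.ndarray:
        X, _ = _as_matrix(X, self.feature_names_)
        diff = X[:, None, :] - self.means_[None, :, :]
        quad = (diff**2 / (2.0 * self.variances_[None, :, :])).sum(axis=2)
        logdet = 0.5 * np.log(self.variances_).sum(axis=1)
        return -(quad + logdet[None, :]) + np.log(self.priors_)[None, :]

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.decision_function(X), axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": "dqda",
                "classes": [str(c) for c in self.classes_],
                "features": list(self.feature_names_),
                "means": self.means_.tolist(),
                "variances": self.variances_.tolist(),
                "priors": self.priors_.tolist(),
                "feature_medians": self.feature_medians_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "DqdaClassifier":
        obj = json.loads(payload)
        model = cls()
        model.classes_ = np.asarray(obj["classes"])
        model.feature_names_ = list(obj["features"])
        model.means_ = np.asarray(obj["means"], dtype=float)
        model.variances_ = np.asarray(obj["variances"], dtype=float)
        model.priors_ = np.asarray(obj["priors"], dtype=float)
        model.feature_medians_ = np.asarray(obj["feature_medians"], dtype=float)
        return model


def dqda_fit(expr: pd.DataFrame, labels: pd.Series, var_floor_frac: float = 1e-6) -> DqdaClassifier:
    """Fit DQDA on a panel-restricted genes x samples expression frame."""
    labels = labels.reindex(expr.columns)
    return DqdaClassifier(var_floor_frac=var_floor_frac).fit(expr.T, labels.to_numpy())


def dqda_predict(model: DqdaClassifier, expr: pd.DataFrame) -> Tuple[pd.Series, pd.DataFrame]:
    """Predict labels + per-class posteriors for genes x samples input."""
    missing = [g for g in model.feature_names_ if g not in expr.index]
    if missing:
        raise ValueError(f"panel genes missing from expression matrix: {missing[:10]}")
    X = expr.loc[model.feature_names_].T
    labels = pd.Series(model.predict(X), index=expr.columns, name="subtype")
    post = pd.DataFrame(model.predict_proba(X), index=expr.columns, columns=model.classes_)
    return labels, post


# ---------------------------------------------------------------------------
# Cross-cohort assignment
# ---------------------------------------------------------------------------


def assign_cohort(
    model: Union[DqdaClassifier, ShrunkenCentroidClassifier],
    expr_new: pd.DataFrame,
    mode: str = "centroid_correlation",
    margin: float = 0.05,
) -> pd.DataFrame:
    """Assign a new cohort (genes x samples) to the fitted subtypes.

    Expression rows are median-centred within the new cohort before
    assignment, which absorbs per-gene platform/batch offsets. At least 50%
    of the model panel must be measured. ``centroid_correlation`` assigns by
    the highest Pearson correlation to the (median-centred) class centroids,
    flagging low-confidence calls whose top-two correlations differ by less
    than ``margin``; ``dqda`` applies the discriminant rule in the centred
    space.
    """
    if mode not in {"dqda", "centroid_correlation"}:
        raise ValueError(f"unknown assignment mode {mode!r}")
    panel = list(model.feature_names_)
    measured = [g for g in panel if g in expr_new.index]
    coverage = len(measured) / len(panel)
    if coverage < 0.5:
        raise ValueError(
            f"only {coverage:.0%} of the panel is measured in the new cohort (need >=50%)"
        )
    if coverage < 1.0:
        logger.warning("panel coverage %.0f%%; restricting model", 100 * coverage)
    keep = np.asarray([g in expr_new.index for g in panel])
    sub = expr_new.loc[measured]
    centred = sub.sub(sub.median(axis=1), axis=0)

    if mode == "dqda":
        if isinstance(model, ShrunkenCentroidClassifier):
            raise ValueError("dqda mode requires a DqdaClassifier")
        restricted = DqdaClassifier(var_floor_frac=model.var_floor_frac)
        restricted.classes_ = model.classes_
        restricted.feature_names_ = measured
        restricted.means_ = (model.means_ - model.feature_medians_[None, :])[:, keep]
        restricted.variances_ = model.variances_[:, keep]
        restricted.priors_ = model.priors_
        restricted.feature_medians_ = np.zeros(len(measured))
        X = centred.T
        pred = restricted.predict(X)
        proba = restricted.predict_proba(X)
        top = np.sort(proba, axis=1)
        conf = top[:, -1]
        low = (top[:, -1] - top[:, -2]) < margin
    else:
        if isinstance(model, DqdaClassifier):
            centroids = model.means_.T  # genes x classes
        else:
            centroids = model.shrunken_centroids_
        centroids = centroids[keep, :]
        centroids = centroids - np.median(centroids, axis=1, keepdims=True)
        x = centred.to_numpy().T  # samples x genes
        c = centroids.T  # classes x genes
        xz = x - x.mean(axis=1, keepdims=True)
        cz = c - c.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(xz, axis=1)[:, None] * np.linalg.norm(cz, axis=1)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            cors = (xz @ cz.T) / denom
        cors = np.nan_to_num(cors, nan=-1.0)
        order = np.argsort(-cors, axis=1)
        best = order[:, 0]
        pred = model.classes_[best]
        conf = cors[np.arange(len(best)), best]
        second = cors[np.arange(len(best)), order[:, 1]]
        low = (conf - second) < margin

    return pd.DataFrame(
        {"subtype": pred, "confidence": conf, "low_confidence": low},
        index=expr_new.columns,
    )


# ---------------------------------------------------------------------------
# Miniclassifier chain
# ---------------------------------------------------------------------------


def paired_de_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    p_threshold: float = 0.01,
) -> Dict[str, pd.DataFrame]:
    """One-vs-rest two-sided Wilcoxon per gene per subtype.

    Returns, per subtype, the genes with ``p < p_threshold`` together with
    the direction of the subtype-specific shift (+1 up / -1 down).
    """
    labels = labels.reindex(expr.columns)
    counts = labels.value_counts()
    if (counts < 3).any():
        small = list(counts.index[counts < 3])
        raise ValueError(f"classes with <3 samples: {small}")
    x = expr.to_numpy(dtype=float)
    out = {}
    for c in sorted(labels.unique()):
        mask = (labels == c).to_numpy()
        res = stats.mannwhitneyu(x[:, mask], x[:, ~mask], axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
        direction = np.sign(
            np.median(x[:, mask], axis=1) - np.median(x[:, ~mask], axis=1)
        )
        keep = p < p_threshold
        out[c] = pd.DataFrame(
            {"p": p[keep], "direction": direction[keep]}, index=expr.index[keep]
        ).sort_values("p")
    return out


def _univariate_logistic_pvalues(
    x: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray]:
    """Wald p-values for the slope of per-column univariable logistic fits.

    ``x`` is (n_samples, n_genes), standardised columns recommended; ``y`` is
    binary. Newton-Raphson vectorised across genes; quasi-separated fits
    (|slope| blowing up, where the Wald test loses meaning) are flagged and
    assigned p = 0.
    """
    n, g = x.shape
    b0 = np.zeros(g)
    b1 = np.zeros(g)
    yv = y[:, None].astype(float)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + b1[None, :] * x, -30, 30)
        p = expit(eta)
        w = p * (1 - p)
        r = yv - p
        g0 = r.sum(axis=0)
        g1 = (r * x).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * x).sum(axis=0)
        h11 = (w * x * x).sum(axis=0)
        det = h00 * h11 - h01**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (-h01 * g0 + h00 * g1) / det
        step0 = np.clip(step0, -5, 5)
        step1 = np.clip(step1, -5, 5)
        b0 += step0
        b1 += step1
        if max(np.abs(step0).max(), np.abs(step1).max()) < tol:
            break
    separated = np.abs(b1) > 10
    eta = np.clip(b0[None, :] + b1[None, :] * x, -30, 30)
    p = expit(eta)
    w = p * (1 - p)
    h00 = w.sum(axis=0)
    h01 = (w * x).sum(axis=0)
    h11 = (w * x * x).sum(axis=0)
    det = np.maximum(h00 * h11 - h01**2, 1e-12)
    se1 = np.sqrt(np.maximum(h00 / det, 1e-12))
    z = b1 / se1
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    pvals = np.where(separated, 0.0, pvals)
    return pvals, separated


@dataclass
class BootstrapScreenResult:
    """Retention fractions of the bootstrap univariable-logistic screen."""

    fractions: pd.DataFrame  # genes x subtypes, fraction of significant fits
    selected: Dict[str, List[str]]
    n_boot: int
    p_threshold: float
    retention: float

    @property
    def union_genes(self) -> List[str]:
        out = set()
        for genes in self.selected.values():
            out.update(genes)
        return sorted(out)


def bootstrap_logistic_screen(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 1000,
    p_threshold: float = 0.05,
    retention: float = 0.95,
    seed: Optional[int] = None,
) -> BootstrapScreenResult:
    """Per-gene robustness screen via bootstrap univariable logistic fits.

    For each subtype (one-vs-rest) and each stratified bootstrap resample,
    every candidate gene is fit in a univariable logistic model; a gene is
    retained for a subtype when its slope is significant
    (``p < p_threshold``) in at least ``retention`` of the iterations.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    labels = labels.reindex(expr.columns)
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float).T  # samples x genes
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x - x.mean(axis=0)) / sd

    classes = sorted(labels.unique())
    fractions = {}
    n_separated = 0
    for c in classes:
        y = (labels == c).to_numpy().astype(int)
        idx_pos = np.where(y == 1)[0]
        idx_neg = np.where(y == 0)[0]
        sig_counts = np.zeros(x.shape[1])
        for _ in range(n_boot):
            bs = np.concatenate(
                [
                    rng.choice(idx_pos, size=idx_pos.size, replace=True),
                    rng.choice(idx_neg, size=idx_neg.size, replace=True),
                ]
            )
            pv, sep = _univariate_logistic_pvalues(x[bs], y[bs])
            n_separated += int(sep.sum())
            sig_counts += pv < p_threshold
        fractions[c] = sig_counts / n_boot
    if n_separated:
        logger.info("quasi-separation fallback applied in %d fits", n_separated)
    frac_df = pd.DataFrame(fractions, index=expr.index)
    selected = {c: list(frac_df.index[frac_df[c] >= retention]) for c in classes}
    return BootstrapScreenResult(
        fractions=frac_df,
        selected=selected,
        n_boot=n_boot,
        p_threshold=p_threshold,
        retention=retention,
    )


@dataclass
class PanelSelection:
    """LASSO panel-selection outcome."""

    panel: List[str]
    chosen_c: float
    rule: str
    cv_table: pd.DataFrame  # per C: mean deviance, se
    fallback_to_min: bool = False


def lasso_panel_select(
    expr: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    rule: str = "1se",
    cs: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    max_iter: int = 3000,
) -> PanelSelection:
    """Multinomial L1 path with CV deviance and the one-standard-error rule.

    The chosen penalty is the strongest (smallest C) whose mean CV deviance
    is within one standard error of the minimum; the panel is every gene
    with a nonzero coefficient in any class at that penalty. An empty panel
    at the 1-SE point falls back to the deviance-minimising penalty (logged).
    """
    if expr.shape[0] < 1:
        raise ValueError("no candidate genes")
    if rule not in {"1se", "min"}:
        raise ValueError(f"unknown rule {rule!r}")
    labels = labels.reindex(expr.columns)
    y = labels.to_numpy()
    x = expr.to_numpy(dtype=float).T
    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    x = (x - mu) / sd
    if cs is None:
        cs = np.logspace(-3, 1, 20)
    cs = np.sort(np.asarray(list(cs), dtype=float))

    folds_eff = min(folds, int(pd.Series(y).value_counts().min()))
    if folds_eff < 2:
        raise ValueError("smallest class has <2 samples; cannot cross-validate")
    if folds_eff < folds:
        logger.warning("reducing LASSO CV folds from %d to %d", folds, folds_eff)
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    classes = np.unique(y)
    dev = np.zeros((len(cs), folds_eff))
    for fi, (tr, va) in enumerate(skf.split(x, y)):
        for ci, c in enumerate(cs):
            clf = LogisticRegression(
                C=c, solver="saga", l1_ratio=1.0, max_iter=max_iter, tol=1e-3
            )
            clf.fit(x[tr], y[tr])
            proba = clf.predict_proba(x[va])
            dev[ci, fi] = log_loss(y[va], proba, labels=clf.classes_)
    mean = dev.mean(axis=1)
    se = dev.std(axis=1, ddof=1) / np.sqrt(folds_eff)
    i_min = int(np.argmin(mean))
    if rule == "1se":
        thr = mean[i_min] + se[i_min]
        candidates = np.where(mean <= thr)[0]
        i_chosen = int(candidates[0])  # smallest C = strongest penalty
    else:
        i_chosen = i_min

    def _panel_at(ci: int) -> List[str]:
        clf = LogisticRegression(
            C=cs[ci], solver="saga", l1_ratio=1.0, max_iter=max_iter, tol=1e-4
        )
        clf.fit(x, y)
        nz = np.abs(clf.coef_).max(axis=0) > 1e-8
        return list(expr.index[nz])

    panel = _panel_at(i_chosen)
    fallback = False
    if not panel and i_chosen != i_min:
        logger.warning("empty panel at the 1-SE penalty; falling back to lambda_min")
        panel = _panel_at(i_min)
        i_chosen = i_min
        fallback = True
    cv_table = pd.DataFrame({"C": cs, "mean_deviance": mean, "se": se}).set_index("C")
    return PanelSelection(
        panel=panel,
        chosen_c=float(cs[i_chosen]),
        rule=rule,
        cv_table=cv_table,
        fallback_to_min=fallback,
    )


# ---------------------------------------------------------------------------
# Random forest + evaluation
# ---------------------------------------------------------------------------


def metrics_from_confusion(cm: pd.DataFrame) -> Dict:
    """Accuracy plus one-vs-rest precision/recall/F1/specificity per class.

    ``cm`` rows are true classes, columns predicted classes (same order).
    """
    m = cm.to_numpy(dtype=float)
    total = m.sum()
    tp = np.diag(m)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def safe(num, den):
        return np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den > 0)

    precision = safe(tp, tp + fp)
    recall = safe(tp, tp + fn)
    f1 = safe(2 * precision * recall, precision + recall)
    specificity = safe(tn, tn + fp)
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "specificity": specificity,
        },
        index=cm.index,
    )
    return {"accuracy": float(tp.sum() / total), "per_class": per_class}


def confusion_frame(y_true, y_pred, classes) -> pd.DataFrame:
    classes = list(classes)
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    return cm


def evaluate_classifier(clf, expr: pd.DataFrame, labels: pd.Series) -> Dict:
    """Confusion matrix + metrics for a fitted classifier on genes x samples."""
    labels = labels.reindex(expr.columns)
    pred = clf.predict(expr.T)
    classes = sorted(set(labels) | set(pred))
    cm = confusion_frame(labels.to_numpy(), pred, classes)
    out = metrics_from_confusion(cm)
    out["confusion"] = cm
    return out


@dataclass
class MiniClassifier:
    """Artifacts of the reduced-panel classifier chain."""

    forest: RandomForestClassifier
    panel: List[str]
    robust_genes: List[str]
    de_genes: Dict[str, List[str]]
    metrics_train: Dict
    metrics_test: Dict
    train_samples: List[str]
    test_samples: List[str]
    seed: Optional[int]

    @property
    def misclassification_train(self) -> float:
        return 1.0 - self.metrics_train["accuracy"]

    @property
    def misclassification_test(self) -> float:
        return 1.0 - self.metrics_test["accuracy"]

    def predict(self, expr: pd.DataFrame) -> pd.Series:
        missing = [g for g in self.panel if g not in expr.index]
        if missing:
            raise ValueError(f"panel genes missing: {missing[:10]}")
        pred = self.forest.predict(expr.loc[self.panel].T)
        return pd.Series(pred, index=expr.columns, name="subtype")


def train_forest(
    expr: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    seed: Optional[int] = None,
    test_size: float = 0.3,
) -> Tuple[RandomForestClassifier, Dict, Dict, List[str], List[str]]:
    """Seeded random forest over the panel with a stratified 70/30 split."""
    if expr.shape[0] < 1:
        raise ValueError("panel is empty")
    labels = labels.reindex(expr.columns)
    samples = np.asarray(expr.columns)
    tr, te = train_test_split(
        samples, test_size=test_size, stratify=labels.to_numpy(), random_state=seed
    )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(expr[tr].T, labels.loc[tr].to_numpy())
    metrics_train = evaluate_classifier(forest, expr[tr], labels.loc[tr])
    metrics_test = evaluate_classifier(forest, expr[te], labels.loc[te])
    return forest, metrics_train, metrics_test, list(tr), list(te)


def build_miniclassifier(
    expr: pd.DataFrame,
    labels: pd.Series,
    de_p: float = 0.01,
    n_boot: int = 1000,
    boot_p: float = 0.05,
    retention: float = 0.95,
    lasso_folds: int = 10,
    n_trees: int = 500,
    seed: Optional[int] = None,
) -> MiniClassifier:
    """Full chain: paired DE -> bootstrap logistic -> LASSO 1-SE -> forest."""
    ss = np.random.SeedSequence(seed)
    s_boot, s_lasso, s_forest = (
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3)
    )
    de = paired_de_screen(expr, labels, p_threshold=de_p)
    de_union = sorted(set().union(*(set(df.index) for df in de.values())))
    if not de_union:
        raise ValueError("differential-expression screen selected no genes")
    boot = bootstrap_logistic_screen(
        expr.loc[de_union], labels, n_boot=n_boot, p_threshold=boot_p,
        retention=retention, seed=s_boot,
    )
    robust = boot.union_genes
    if len(robust) < 2:
        raise ValueError("bootstrap screen retained <2 robust genes")
    sel = lasso_panel_select(
        expr.loc[robust], labels, folds=lasso_folds, rule="1se", seed=s_lasso
    )
    forest, m_tr, m_te, tr, te = train_forest(
        expr.loc[sel.panel], labels, n_trees=n_trees, seed=s_forest
    )
    return MiniClassifier(
        forest=forest,
        panel=sel.panel,
        robust_genes=robust,
        de_genes={c: list(df.index) for c, df in de.items()},
        metrics_train=m_tr,
        metrics_test=m_te,
        train_samples=tr,
        test_samples=te,
        seed=seed,
    )


class MiniClassifierPipeline(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper around the miniclassifier chain.

    ``fit(X, y)`` takes samples x genes; fitted attributes expose the chain
    stages (``de_genes_``, ``robust_genes_``, ``panel_``, ``forest_``).
    """

    def __init__(
        self,
        de_p: float = 0.01,
        n_boot: int = 1000,
        boot_p: float = 0.05,
        retention: float = 0.95,
        lasso_folds: int = 10,
        n_trees: int = 500,
        random_state: Optional[int] = None,
    ):
        self.de_p = de_p
        self.n_boot = n_boot
        self.boot_p = boot_p
        self.retention = retention
        self.lasso_folds = lasso_folds
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "MiniClassifierPipeline":
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expected a samples x genes DataFrame")
        labels = pd.Series(np.asarray(y, dtype=object), index=X.index)
        mini = build_miniclassifier(
            X.T,
            labels,
            de_p=self.de_p,
            n_boot=self.n_boot,
            boot_p=self.boot_p,
            retention=self.retention,
            lasso_folds=self.lasso_folds,
            n_trees=self.n_trees,
            seed=self.random_state,
        )
        self.mini_ = mini
        self.de_genes_ = mini.de_genes
        self.robust_genes_ = mini.robust_genes
        self.panel_ = mini.panel
        self.forest_ = mini.forest
        self.classes_ = mini.forest.classes_
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict(X[self.panel_])


# ---------------------------------------------------------------------------


def _as_matrix(X, feature_names: Optional[Sequence[str]] = None):
    """Coerce samples x features input to ndarray (+ feature names)."""
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in X.columns]
            if missing:
                raise ValueError(f"missing features: {missing[:10]}")
            X = X[list(feature_names)]
            names = list(feature_names)
        else:
            names = list(X.columns)
        return X.to_numpy(dtype=float), names
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D samples x features array")
    if feature_names is not None:
        if arr.shape[1] != len(feature_names):
            raise ValueError("feature count mismatch")
        return arr, list(feature_names)
    return arr, [f"f{i}" for i in range(arr.shape[1])]
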
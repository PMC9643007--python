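import numpy as np
import pandas as pd
import pytest

from netpert import (
    DqdaClassifier,
    ShrunkenCentroidClassifier,
    assign_cohort,
    bootstrap_logistic_screen,
    dqda_fit,
    dqda_predict,
    evaluate_classifier,
    lasso_panel_select,
    metrics_from_confusion,
    paired_de_screen,
    sam_screen,
    train_forest,
    train_shrunken_centroid,
)
from netpert.classifiers import _univariate_logistic_pvalues
from netpert.simdata import SimConfig, add_batch_effects, resample_cohort, simulate_cohort


def _gaussian_two_class(n_per=30, n_genes=50, n_inf=5, shift=3.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=(n_genes, 2 * n_per))
    x[:n_inf, n_per:] += shift
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{i}" for i in range(2 * n_per)]
    expr = pd.DataFrame(x, index=genes, columns=cols)
    labels = pd.Series(["A"] * n_per + ["B"] * n_per, index=cols)
    return expr, labels, genes[:n_inf]


class TestSamScreen:
    def test_null_gene_not_selected_and_shifted_gene_is(self):
        expr, labels, inf = _gaussian_two_class(seed=1)
        res = sam_screen(expr, labels, n_perm=100, seed=1)
        for g in inf:
            assert res.q.loc[g, "A"] < 0.05
        null_q = res.q.drop(index=inf)
        assert (null_q > 0.2).to_numpy().mean() > 0.8
        assert set(inf) <= set(res.selected["A"])

    def test_s0_is_median_pooled_sd(self):
        expr, labels, _ = _gaussian_two_class(seed=2)
        res = sam_screen(expr, labels, n_perm=20, seed=0)
        assert res.s0["A"] == pytest.approx(float(res.s["A"].median()))

    def test_min_permutations_enforced(self):
        expr, labels, _ = _gaussian_two_class()
        with pytest.raises(ValueError, match="n_perm"):
            sam_screen(expr, labels, n_perm=5)


class TestShrunkenCentroid:
    def test_zero_shrinkage_is_nearest_centroid(self):
        expr, labels, _ = _gaussian_two_class(seed=3)
        model = ShrunkenCentroidClassifier(shrinkage=0.0).fit(expr.T, labels)
        assert set(model.survivors_) == set(expr.index)
        # with delta=0 the shrunken centroids are the class means
        assert np.allclose(model.shrunken_centroids_, model.centroids_)

    def test_over_shrinkage_errors(self):
        expr, labels, _ = _gaussian_two_class(seed=3)
        with pytest.raises(ValueError, match="no genes survive"):
            ShrunkenCentroidClassifier(shrinkage=1e9).fit(expr.T, labels)

    def test_survivor_count_non_increasing_in_delta(self):
        expr, labels, _ = _gaussian_two_class(seed=4)
        fit0 = ShrunkenCentroidClassifier(shrinkage=0.0).fit(expr.T, labels)
        counts = []
        for delta in np.linspace(0, np.abs(fit0.d_).max() * 0.99, 10):
            m = ShrunkenCentroidClassifier(shrinkage=float(delta)).fit(expr.T, labels)
            counts.append(len(m.survivors_))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_cv_recovers_informative_panel(self):
        expr, labels, inf = _gaussian_two_class(
            n_per=30, n_genes=1000, n_inf=20, shift=2.0, seed=1
        )
        model = train_shrunken_centroid(expr, labels, cv_folds=5, seed=1)
        assert len(set(model.survivors_) & set(inf)) >= 16
        assert model.cv_errors_.min() <= 0.05

    def test_matches_sklearn_shrunken_survivors(self):
        from sklearn.neighbors import NearestCentroid

        expr, labels, _ = _gaussian_two_class(n_per=20, n_genes=40, seed=5)
        delta = 1.0
        mine = ShrunkenCentroidClassifier(shrinkage=delta).fit(expr.T, labels)
        sk = NearestCentroid(shrink_threshold=delta).fit(
            expr.T.to_numpy(), labels.to_numpy()
        )
        sk_survivors = {
            expr.index[i]
            for i in range(expr.shape[0])
            if not np.allclose(sk.centroids_[:, i], sk.centroids_[0, i])
        }
        assert set(mine.survivors_) == sk_survivors


class TestDqda:
    def test_equal_variance_prefers_nearer_centroid(self):
        m = DqdaClassifier().fit(
            pd.DataFrame({"g": [-0.5, 0.5, 3.5, 4.5]}), ["A", "A", "B", "B"]
        )
        m.means_ = np.array([[0.0], [4.0]])
        m.variances_ = np.array([[1.0], [1.0]])
        m.priors_ = np.array([0.5, 0.5])
        assert m.predict(pd.DataFrame({"g": [1.0]}))[0] == "A"

    def test_hand_discriminant_variance_rich_class_wins(self):
        m = DqdaClassifier().fit(
            pd.DataFrame({"g": [-0.5, 0.5, 3.5, 4.5]}), ["A", "A", "B", "B"]
        )
        m.means_ = np.array([[0.0], [0.0]])
        m.variances_ = np.array([[1.0], [4.0]])
        m.priors_ = np.array([0.5, 0.5])
        d = m.decision_function(pd.DataFrame({"g": [3.0]}))[0]
        assert d[0] == pytest.approx(-4.5 + np.log(0.5))
        assert d[1] == pytest.approx(-9 / 8 - 0.5 * np.log(4) + np.log(0.5))
        assert m.predict(pd.DataFrame({"g": [3.0]}))[0] == "B"

    def test_sample_at_centroid_assigned_there(self):
        expr, labels, _ = _gaussian_two_class(seed=6)
        model = dqda_fit(expr, labels)
        centroid_b = pd.DataFrame(
            {"x": model.means_[list(model.classes_).index("B")]},
            index=model.feature_names_,
        )
        pred, post = dqda_predict(model, centroid_b)
        assert pred.iloc[0] == "B"
        assert post.loc["x", "B"] > 0.5

    def test_missing_panel_gene_errors(self):
        expr, labels, _ = _gaussian_two_class(seed=6)
        model = dqda_fit(expr, labels)
        with pytest.raises(ValueError, match="missing"):
            dqda_predict(model, expr.iloc[1:])

    def test_matches_bruteforce_diagonal_gaussian_bayes(self):
        """DQDA must agree with an independently coded diagonal Gaussian
        Bayes rule on a dense simulated grid."""
        rng = np.random.default_rng(7)
        n_classes, n_genes = 5, 8
        means = rng.normal(0, 2, size=(n_classes, n_genes))
        variances = rng.uniform(0.5, 3.0, size=(n_classes, n_genes))
        priors = rng.dirichlet(np.ones(n_classes))
        model = DqdaClassifier().fit(
            pd.DataFrame(rng.normal(size=(n_classes * 2, n_genes))),
            np.repeat(np.arange(n_classes), 2),
        )
        model.means_, model.variances_, model.priors_ = means, variances, priors
        grid = rng.normal(0, 2.5, size=(10_000, n_genes))
        d_mine = model.decision_function(grid)
        # oracle: explicit per-class log density loop
        d_oracle = np.empty_like(d_mine)
        for k in range(n_classes):
            ll = -(
                (grid - means[k]) ** 2 / (2 * variances[k])
                + 0.5 * np.log(variances[k])
            ).sum(axis=1)
            d_oracle[:, k] = ll + np.log(priors[k])
        assert np.abs(d_mine - d_oracle).max() < 1e-9
        assert (model.classes_[np.argmax(d_oracle, axis=1)] == model.predict(grid)).all()


@pytest.fixture(scope="module")
def trained(mini_cohort):
    c = mini_cohort
    expr = c.expr[c.tumor_samples]
    labels = c.truth[c.tumor_samples]
    sam = sam_screen(expr, labels, n_perm=50, seed=1)
    nsc = train_shrunken_centroid(expr.loc[sam.union_genes], labels, cv_folds=5, seed=1)
    model = dqda_fit(expr.loc[nsc.survivors_], labels)
    return c, model


class TestAssignCohort:
    def test_self_assignment_reproduces_labels(self, trained):
        c, model = trained
        res = assign_cohort(model, c.expr[c.tumor_samples], mode="dqda")
        assert (res.subtype == c.truth[c.tumor_samples]).mean() == 1.0

    def test_constant_offset_invariance_of_correlation_mode(self, trained):
        c, model = trained
        expr = c.expr[c.tumor_samples]
        res1 = assign_cohort(model, expr, mode="centroid_correlation")
        res2 = assign_cohort(model, expr + 7.5, mode="centroid_correlation")
        assert (res1.subtype == res2.subtype).all()

    def test_batch_shifted_second_cohort_accuracy(self, trained):
        c, model = trained
        second = resample_cohort(c, n_normals=1, n_tumors=120, seed=22)
        shifted = add_batch_effects(second.expr[second.tumor_samples], 0.5, seed=2)
        res = assign_cohort(model, shifted, mode="centroid_correlation")
        acc = (res.subtype == second.truth[second.tumor_samples]).mean()
        assert acc >= 0.9

    def test_low_coverage_errors(self, trained):
        _, model = trained
        few = pd.DataFrame(
            np.zeros((2, 3)), index=model.feature_names_[:2], columns=list("abc")
        )
        with pytest.raises(ValueError, match="50%"):
            assign_cohort(model, few)


class TestPairedDeScreen:
    def test_shifted_gene_kept_null_not(self):
        expr, labels, inf = _gaussian_two_class(seed=8)
        de = paired_de_screen(expr, labels, p_threshold=0.01)
        assert set(inf) <= set(de["A"].index)
        from scipy.stats import mannwhitneyu

        g = inf[0]
        oracle = mannwhitneyu(
            expr.loc[g, labels == "A"], expr.loc[g, labels == "B"],
            alternative="two-sided",
        ).pvalue
        assert de["A"].loc[g, "p"] == pytest.approx(oracle)

    def test_threshold_one_keeps_everything(self):
        expr, labels, _ = _gaussian_two_class(seed=8)
        de = paired_de_screen(expr, labels, p_threshold=1.0)
        assert len(de["A"]) == expr.shape[0]

    def test_small_class_errors(self):
        expr, labels, _ = _gaussian_two_class(n_per=2)
        with pytest.raises(ValueError, match="<3"):
            paired_de_screen(expr, labels)


class TestBootstrapLogistic:
    def test_newton_solver_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        x = rng.normal(size=(80, 1))
        y = (rng.random(80) < 1 / (1 + np.exp(-(0.5 + 1.2 * x[:, 0])))).astype(int)
        p_mine, sep = _univariate_logistic_pvalues(x, y)
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=False)
        assert not sep[0]
        assert p_mine[0] == pytest.approx(fit.pvalues[1], abs=1e-5)

    def test_strong_gene_kept_null_dropped(self):
        expr, labels, inf = _gaussian_two_class(n_per=40, n_genes=20, shift=4.0, seed=9)
        res = bootstrap_logistic_screen(expr, labels, n_boot=100, seed=1)
        for g in inf:
            assert res.fractions.loc[g, "A"] >= 0.99
        null_frac = res.fractions.drop(index=inf)["A"]
        # a null gene is significant in roughly alpha of resamples
        assert null_frac.mean() < 0.25
        assert set(inf) <= set(res.union_genes)
        assert not (set(null_frac.index) & set(res.selected["A"]))

    def test_zero_bootstrap_errors(self):
        expr, labels, _ = _gaussian_two_class()
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_logistic_screen(expr, labels, n_boot=0)


class TestLassoPanel:
    def test_recovers_informative_genes(self):
        expr, labels, inf = _gaussian_two_class(
            n_per=60, n_genes=100, n_inf=5, shift=2.5, seed=1
        )
        sel = lasso_panel_select(expr, labels, folds=5, seed=1)
        assert len(set(sel.panel) & set(inf)) >= 4

    def test_single_candidate_with_signal(self):
        expr, labels, inf = _gaussian_two_class(n_genes=1, n_inf=1, seed=2)
        sel = lasso_panel_select(expr, labels, folds=5, seed=1)
        assert sel.panel == inf

    def test_null_data_falls_back_to_min(self, caplog):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(size=(10, 60)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(60)],
        )
        labels = pd.Series(["A", "B"] * 30, index=expr.columns)
        sel = lasso_panel_select(expr, labels, folds=5, seed=1)
        # on pure noise the 1-SE rule should pick a (near-)empty panel or
        # fall back; either way the panel stays small
        assert len(sel.panel) <= 5


class TestForestAndMetrics:
    def test_perfect_confusion_metrics(self):
        cm = pd.DataFrame([[10, 0], [0, 10]], index=["a", "b"], columns=["a", "b"])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == 1.0
        assert (m["per_class"].to_numpy() == 1.0).all()

    def test_hand_metric_formulas(self):
        cm = pd.DataFrame([[8, 2], [3, 7]], index=["c1", "c2"], columns=["c1", "c2"])
        m = metrics_from_confusion(cm)
        assert m["accuracy"] == pytest.approx(0.75)
        pc = m["per_class"]
        assert pc.loc["c1", "precision"] == pytest.approx(8 / 11)
        assert pc.loc["c1", "recall"] == pytest.approx(0.8)
        assert pc.loc["c1", "specificity"] == pytest.approx(0.7)
        assert pc.loc["c1", "f1"] == pytest.approx(2 * (8 / 11) * 0.8 / (8 / 11 + 0.8))

    def test_forest_split_and_evaluation(self):
        expr, labels, _ = _gaussian_two_class(n_per=40, shift=4.0, seed=10)
        forest, m_tr, m_te, tr, te = train_forest(expr, labels, n_trees=100, seed=1)
        assert len(tr) + len(te) == len(labels)
        assert m_te["accuracy"] >= 0.9
        out = evaluate_classifier(forest, expr[te], labels.loc[te])
        assert out["confusion"].to_numpy().sum() == len(te)
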
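import numpy as np
import pandas as pd
import pytest

from netpert import (
    InteractionNetwork,
    benchmark_vector,
    build_perturbation,
    delta_rank_matrix,
    dispersion_compare,
    perturbation_matrix,
    rank_transform,
    PerturbationTransformer,
)

GENES4 = ["g1", "g2", "g3", "g4"]


class TestRankTransform:
    def test_hand_ranked_column(self, toy_tumor, toy_net):
        ranks = rank_transform(toy_tumor, toy_net)
        assert ranks["T1"].tolist() == [4, 1, 3, 2]

    def test_full_tie_averages(self, toy_net):
        expr = pd.DataFrame({"s": [7.0, 7, 7, 7]}, index=GENES4)
        assert rank_transform(expr, toy_net)["s"].tolist() == [2.5] * 4

    def test_sorted_column_is_identity(self, toy_net):
        expr = pd.DataFrame({"s": [1.0, 2, 3, 4]}, index=GENES4)
        assert rank_transform(expr, toy_net)["s"].tolist() == [1, 2, 3, 4]

    def test_restricts_to_network_genes(self, toy_net):
        expr = pd.DataFrame({"s": [1.0, 2, 3, 4, 99]}, index=GENES4 + ["offnet"])
        ranks = rank_transform(expr, toy_net)
        assert "offnet" not in ranks.index
        assert rank_transform(expr, toy_net, restrict_to_network=False).shape[0] == 5

    def test_too_few_shared_genes(self, toy_net):
        expr = pd.DataFrame({"s": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="shared genes"):
            rank_transform(expr, toy_net)


class TestDeltaRank:
    def test_hand_subtraction(self, toy_tumor, toy_net):
        deltas = delta_rank_matrix(rank_transform(toy_tumor, toy_net), toy_net)
        assert deltas["T1"].tolist() == [3, -2, 1]
        assert list(deltas.index) == ["g1|g2", "g2|g3", "g3|g4"]

    def test_all_tied_gives_zero(self, toy_net):
        expr = pd.DataFrame({"s": [5.0] * 4}, index=GENES4)
        deltas = delta_rank_matrix(rank_transform(expr, toy_net), toy_net)
        assert (deltas["s"] == 0).all()

    def test_orientation_is_canonical(self, toy_tumor):
        swapped = InteractionNetwork.from_edges([("g2", "g1"), ("g3", "g2"), ("g4", "g3")])
        deltas = delta_rank_matrix(rank_transform(toy_tumor, swapped), swapped)
        assert deltas.loc["g1|g2", "T1"] == 3

    def test_unmeasured_endpoint_dropped(self, toy_net, caplog):
        expr = pd.DataFrame({"s": [1.0, 2, 3]}, index=["g1", "g2", "g3"])
        with caplog.at_level("WARNING"):
            deltas = delta_rank_matrix(rank_transform(expr, toy_net), toy_net)
        assert list(deltas.index) == ["g1|g2", "g2|g3"]
        assert "dropping 1 edges" in caplog.text


class TestBenchmark:
    def test_hand_computation(self, toy_normals, toy_net):
        bench = benchmark_vector(toy_normals, toy_net)
        assert bench.tolist() == [-2, 2, -2]

    def test_single_normal_equals_its_deltas(self, toy_net):
        one = pd.DataFrame({"N1": [4.0, 3, 2, 1]}, index=GENES4)
        bench = benchmark_vector(one, toy_net)
        deltas = delta_rank_matrix(rank_transform(one, toy_net), toy_net)
        assert bench.tolist() == deltas["N1"].tolist()

    def test_identical_normals_equal_each_column(self, toy_net):
        rep = pd.DataFrame({f"N{i}": [4.0, 1, 3, 2] for i in range(5)}, index=GENES4)
        bench = benchmark_vector(rep, toy_net)
        deltas = delta_rank_matrix(rank_transform(rep, toy_net), toy_net)
        for c in deltas:
            assert bench.tolist() == deltas[c].tolist()

    def test_requires_normals(self, toy_net):
        empty = pd.DataFrame(index=GENES4)
        with pytest.raises(ValueError, match="normal samples"):
            benchmark_vector(empty, toy_net)


class TestPerturbationMatrix:
    def test_worked_example(self, toy_tumor, toy_normals, toy_net):
        deltas = delta_rank_matrix(rank_transform(toy_tumor, toy_net), toy_net)
        bench = benchmark_vector(toy_normals, toy_net)
        pert = perturbation_matrix(deltas, bench)
        assert pert["T1"].tolist() == [5, -4, 3]

    def test_zero_benchmark_is_identity(self, toy_tumor, toy_net):
        deltas = delta_rank_matrix(rank_transform(toy_tumor, toy_net), toy_net)
        zero = pd.Series(0.0, index=deltas.index)
        assert perturbation_matrix(deltas, zero).equals(deltas)

    def test_edge_mismatch_errors(self, toy_tumor, toy_net):
        deltas = delta_rank_matrix(rank_transform(toy_tumor, toy_net), toy_net)
        bad = pd.Series(0.0, index=["g1|g2", "g2|g3", "gX|gY"])
        with pytest.raises(ValueError, match="edge mismatch"):
            perturbation_matrix(deltas, bad)

    def test_homogeneous_normals_give_zero_columns(self, toy_net):
        profile = [4.0, 1, 3, 2]
        expr = pd.DataFrame(
            {"N1": profile, "N2": profile, "T1": [1.0, 2, 3, 4]}, index=GENES4
        )
        phen = pd.Series(
            ["normal", "normal", "tumor"], index=["N1", "N2", "T1"]
        )
        net = InteractionNetwork.from_edges([("g1", "g2"), ("g2", "g3"), ("g3", "g4")])
        pert = build_perturbation(expr, phen, net)
        assert (pert.values[["N1", "N2"]] == 0).all().all()
        assert (pert.values["T1"] != 0).any()


def _random_increasing_transform(rng):
    c = rng.uniform(0.1, 2.0, size=3)
    shift = rng.uniform(-5, 5)

    def f(x):
        return c[0] * x + c[1] * x**3 + c[2] * np.exp(x / 10.0) + shift

    return f


class TestInvariants:
    def test_monotone_transform_invariance(self):
        """Delta ranks are always transform-invariant; the full perturbation
        matrix is bit-invariant under the rank-averaged benchmark (the
        mean-expression pseudo-sample's ranks need not be preserved)."""
        rng = np.random.default_rng(0)
        from netpert import SimConfig, simulate_cohort, rank_transform, delta_rank_matrix

        cohort = simulate_cohort(
            SimConfig(n_genes=120, n_normals=8, n_tumors=24, edges_per_subtype=3, seed=5)
        )
        ref_deltas = delta_rank_matrix(
            rank_transform(cohort.expr, cohort.net), cohort.net
        )
        ref = build_perturbation(
            cohort.expr, cohort.phenotype, cohort.net, benchmark_mode="mean_delta_rank"
        ).values
        for _ in range(20):
            transformed = cohort.expr.copy()
            for col in transformed.columns:
                f = _random_increasing_transform(rng)
                transformed[col] = f(transformed[col].to_numpy())
            deltas = delta_rank_matrix(
                rank_transform(transformed, cohort.net), cohort.net
            )
            assert deltas.equals(ref_deltas)
            out = build_perturbation(
                transformed, cohort.phenotype, cohort.net,
                benchmark_mode="mean_delta_rank",
            ).values
            assert out.equals(ref)

    def test_benchmark_modes_agree_on_homogeneous_normals(self, toy_net):
        rep = pd.DataFrame({f"N{i}": [4.0, 1, 3, 2] for i in range(4)}, index=GENES4)
        a = benchmark_vector(rep, toy_net, mode="mean_expression")
        b = benchmark_vector(rep, toy_net, mode="mean_delta_rank")
        assert a.tolist() == b.tolist()

    def test_bounds(self, default_pert, default_cohort):
        g = len(set(default_cohort.expr.index) & set(default_cohort.net.node_set))
        assert default_pert.values.abs().to_numpy().max() <= 2 * (g - 1)

    def test_sample_permutation_permutes_columns(self, toy_net, toy_normals):
        expr = pd.DataFrame(
            {"N1": [1.0, 2, 3, 4], "N2": [3.0, 4, 1, 2], "T1": [5.0, 1, 3, 2]},
            index=GENES4,
        )
        phen = pd.Series(["normal", "normal", "tumor"], index=["N1", "N2", "T1"])
        a = build_perturbation(expr, phen, toy_net).values
        b = build_perturbation(expr[["T1", "N2", "N1"]], phen, toy_net).values
        assert a[["T1", "N2", "N1"]].equals(b)

    def test_gene_order_irrelevant(self, toy_net):
        expr = pd.DataFrame(
            {"N1": [1.0, 2, 3, 4], "T1": [5.0, 1, 3, 2]}, index=GENES4
        )
        phen = pd.Series(["normal", "tumor"], index=["N1", "T1"])
        shuffled = expr.iloc[[2, 0, 3, 1]]
        a = build_perturbation(expr, phen, toy_net).values
        b = build_perturbation(shuffled, phen, toy_net).values
        assert a.equals(b)


class TestDispersion:
    def test_sd_method_detects_spread(self):
        pert = pd.DataFrame(
            {"N1": [0.0], "N2": [0.0], "N3": [0.0], "T1": [5.0], "T2": [-4.0], "T3": [3.0]},
            index=["e1"],
        )
        phen = pd.Series(
            ["normal"] * 3 + ["tumor"] * 3, index=pert.columns
        )
        rep = dispersion_compare(pert, phen, method="sd")
        assert rep.fraction_tumor_greater == 1.0

    def test_identical_groups_fraction_zero(self):
        pert = pd.DataFrame(
            {"N1": [1.0, 0], "N2": [2.0, 1], "T1": [1.0, 0], "T2": [2.0, 1]},
            index=["e1", "e2"],
        )
        phen = pd.Series(["normal", "normal", "tumor", "tumor"], index=pert.columns)
        rep = dispersion_compare(pert, phen, method="sd")
        assert rep.fraction_tumor_greater == 0.0

    def test_doubled_sd_recovered(self):
        rng = np.random.default_rng(3)
        nor = rng.normal(0, 1, size=(50, 50))
        tum = rng.normal(0, 2, size=(50, 50))
        pert = pd.DataFrame(
            np.hstack([nor, tum]),
            index=[f"e{i}" for i in range(50)],
            columns=[f"N{i}" for i in range(50)] + [f"T{i}" for i in range(50)],
        )
        phen = pd.Series(["normal"] * 50 + ["tumor"] * 50, index=pert.columns)
        rep = dispersion_compare(pert, phen, method="sd")
        # oracle: group-wise sd on the draws themselves
        direct = (tum.std(axis=1, ddof=1) > nor.std(axis=1, ddof=1)).mean()
        assert rep.fraction_tumor_greater == pytest.approx(direct)
        assert rep.fraction_tumor_greater >= 0.9
        assert rep.p_value < 1e-6

    def test_singleton_group_errors(self):
        pert = pd.DataFrame({"N1": [0.0], "T1": [1.0], "T2": [2.0]}, index=["e1"])
        phen = pd.Series(["normal", "tumor", "tumor"], index=pert.columns)
        with pytest.raises(ValueError, match=">=2"):
            dispersion_compare(pert, phen)


class TestTransformerEstimator:
    def test_fit_transform_matches_functions(self, default_cohort, default_pert):
        tr = PerturbationTransformer(default_cohort.net)
        normals = default_cohort.expr[default_cohort.normal_samples].T
        tr.fit(normals)
        out = tr.transform(default_cohort.expr.T)
        assert np.allclose(out.T.to_numpy(), default_pert.values.to_numpy())

    def test_sklearn_clone_and_params(self, default_cohort):
        from sklearn.base import clone

        tr = PerturbationTransformer(default_cohort.net, restrict_to_network=False)
        tr2 = clone(tr)
        assert tr2.get_params()["restrict_to_network"] is False
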
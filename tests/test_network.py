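import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epinet.network import (NetworkConfig, build_network, detect_modules,
                            identify_hubs, intramodular_connectivity,
                            module_eigengene, module_membership,
                            module_trait_association, pick_soft_threshold,
                            signed_adjacency, topological_overlap,
                            transform_expression)
from epinet.simulate import simulate_coexpression


def tom_oracle(A: np.ndarray) -> np.ndarray:
    """Triple-loop restatement of the topological-overlap definition."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            out[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


class TestTransform:
    def test_constant_matrix_rejected(self):
        norm = pd.DataFrame(np.full((5, 4), 7.0),
                            columns=[f"s{j}" for j in range(4)])
        with pytest.raises(ValueError, match="variable"):
            transform_expression(norm)

    def test_ranking_preserved(self, rng):
        norm = pd.DataFrame(rng.poisson(100, (10, 5)).astype(float) + 1,
                            columns=[f"s{j}" for j in range(5)])
        expr = transform_expression(norm)
        for g in expr.index:
            assert np.array_equal(np.argsort(norm.loc[g].values),
                                  np.argsort(expr.loc[g].values))

    def test_variance_stabilization_trend(self, rng):
        # transformed per-gene variance grows sublinearly with the mean
        means = np.array([10.0, 100.0, 1000.0, 10000.0])
        var_ratio = []
        for m in means:
            counts = rng.poisson(m, size=(200, 10)).astype(float)
            logvar = np.log2(counts + 1).var(axis=1, ddof=1).mean()
            var_ratio.append(logvar / counts.var(axis=1, ddof=1).mean())
        assert all(np.diff(var_ratio) < 0)


class TestAdjacency:
    def test_closed_forms(self):
        t = np.arange(6.0)
        expr = pd.DataFrame(
            [t, 2 * t + 1, -t], index=["a", "b", "c"],
            columns=[f"s{j}" for j in range(6)])
        adj = signed_adjacency(expr, beta=16)
        assert adj[0, 1] == pytest.approx(1.0)       # cor = 1
        assert adj[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor = -1
        assert np.all(np.diag(adj) == 0)

    def test_orthogonal_profiles_at_beta_16(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # exactly uncorrelated with x
        expr = pd.DataFrame([x, y], index=["a", "b"],
                            columns=[f"s{j}" for j in range(4)])
        adj = signed_adjacency(expr, beta=16)
        assert adj[0, 1] == pytest.approx(2.0**-16, rel=1e-9)

    def test_monotone_in_correlation(self, rng):
        expr, _ = simulate_coexpression(block_sizes=(20, 20), n_samples=20, seed=0)
        cor = np.corrcoef(expr.to_numpy())
        adj = signed_adjacency(expr, beta=6)
        iu = np.triu_indices_from(cor, k=1)
        order = np.argsort(cor[iu])
        assert np.all(np.diff(adj[iu][order]) >= -1e-12)
        assert adj.min() >= 0 and adj.max() <= 1


class TestTOM:
    def test_zero_adjacency(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert np.allclose(tom, np.eye(4))

    def test_hand_example_three_nodes(self):
        A = np.full((3, 3), 0.5)
        np.fill_diagonal(A, 0.0)
        tom = topological_overlap(A)
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5, rel=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 13))
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            assert np.allclose(topological_overlap(A), tom_oracle(A), atol=1e-12)

    def test_range_and_symmetry(self, rng):
        A = rng.uniform(0, 1, (15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = topological_overlap(A)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self):
        A = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            topological_overlap(A)


class TestModules:
    def test_two_perfect_blocks(self, rng):
        t = rng.standard_normal(12)
        u = rng.standard_normal(12)
        rows = [t * s for s in np.linspace(1, 2, 50)] + \
               [u * s for s in np.linspace(1, 2, 50)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{j}" for j in range(12)])
        config = NetworkConfig(min_module_size=10)
        tom = topological_overlap(signed_adjacency(expr, 16))
        labels = detect_modules(tom, expr.index, expr, config)
        assert (labels == "grey").sum() == 0
        assert labels.nunique() == 2

    def test_single_block_is_one_module(self, rng):
        expr, _ = simulate_coexpression(block_sizes=(60,), n_samples=20, seed=2)
        tom = topological_overlap(signed_adjacency(expr, 16))
        labels = detect_modules(tom, expr.index, expr,
                                NetworkConfig(min_module_size=10))
        assert set(labels) == {"turquoise"}

    def test_planted_blocks_recovered(self):
        aris = []
        for seed in range(5):
            expr, truth = simulate_coexpression(
                block_sizes=(60, 50, 40, 30, 20), loading=math.sqrt(0.8),
                n_samples=30, seed=seed)
            tom = topological_overlap(signed_adjacency(expr, 16))
            labels = detect_modules(tom, expr.index, expr,
                                    NetworkConfig(min_module_size=10))
            t = [truth.module_assignment[g] for g in expr.index]
            aris.append(adjusted_rand_score(t, list(labels)))
        assert min(aris) >= 0.9

    def test_largest_module_is_turquoise(self):
        expr, _ = simulate_coexpression(block_sizes=(50, 30), n_samples=25, seed=4)
        tom = topological_overlap(signed_adjacency(expr, 16))
        labels = detect_modules(tom, expr.index, expr,
                                NetworkConfig(min_module_size=10))
        sizes = labels.value_counts()
        assert sizes.idxmax() == "turquoise"

    def test_too_few_genes_all_grey(self):
        expr, _ = simulate_coexpression(block_sizes=(5,), n_samples=10,
                                        n_hubs_per_block=0, seed=0)
        tom = topological_overlap(signed_adjacency(expr, 6))
        with pytest.warns(UserWarning):
            labels = detect_modules(tom, expr.index, expr, NetworkConfig())
        assert set(labels) == {"grey"}


class TestEigengene:
    def test_identical_genes_give_common_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"],
                            columns=[f"s{j}" for j in range(5)])
        eig = module_eigengene(expr)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(np.abs(np.corrcoef(eig, z)[0, 1]), 1.0)
        assert np.corrcoef(eig, z)[0, 1] > 0  # oriented with members

    def test_orientation_invariance(self, rng):
        expr, _ = simulate_coexpression(block_sizes=(20,), n_samples=15, seed=3)
        e1 = module_eigengene(expr)
        e2 = module_eigengene(-expr)
        # flipping all members flips nothing observable after orientation
        assert np.allclose(np.abs(e1), np.abs(e2))

    def test_two_perfectly_correlated_genes(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        expr = pd.DataFrame([t, 2 * t + 5], index=["a", "b"],
                            columns=[f"s{j}" for j in range(4)])
        eig = module_eigengene(expr)
        assert np.corrcoef(eig, t)[0, 1] == pytest.approx(1.0)

    def test_eigengene_maximizes_explained_variance(self, rng):
        expr, _ = simulate_coexpression(block_sizes=(10,), n_samples=12, seed=5)
        X = expr.to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        eig = module_eigengene(expr)
        def explained(v):
            v = v / np.linalg.norm(v)
            return float(((Z @ v) ** 2).sum())
        best = explained(eig)
        for _ in range(200):
            assert explained(rng.standard_normal(len(eig))) <= best + 1e-9


class TestMembershipAndHubs:
    def test_gene_equal_to_eigengene(self, rng):
        expr, _ = simulate_coexpression(block_sizes=(15,), n_samples=20, seed=6)
        eig = module_eigengene(expr)
        expr2 = pd.concat([expr, pd.DataFrame([eig], index=["self"],
                                              columns=expr.columns)])
        kme, p = module_membership(expr2, pd.DataFrame([eig], index=["m"],
                                                       columns=expr.columns))
        assert kme.loc["self", "m"] == pytest.approx(1.0)
        assert p.loc["self", "m"] < 1e-12

    def test_closed_form_correlation_test(self):
        # kME = 0.9 at n = 29 -> t = 0.9 sqrt(27/0.19) = 10.73
        from epinet.network import _corr_pvalue
        from scipy import stats
        t = 0.9 * math.sqrt(27 / (1 - 0.81))
        assert t == pytest.approx(10.73, abs=0.01)
        assert _corr_pvalue(0.9, 29) == pytest.approx(2 * stats.t.sf(t, 27), rel=1e-9)

    def test_connectivity_matches_row_sums(self, rng):
        A = rng.uniform(0, 1, (8, 8))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        labels = pd.Series(["m1"] * 4 + ["m2"] * 4,
                           index=[f"g{i}" for i in range(8)])
        conn = intramodular_connectivity(A, labels)
        for i in range(8):
            assert conn["k_total"].iloc[i] == pytest.approx(A[i].sum())
            same = [j for j in range(8) if labels.iloc[j] == labels.iloc[i]]
            assert conn["k_within"].iloc[i] == pytest.approx(
                sum(A[i, j] for j in same if j != i))
        assert (conn["k_within"] <= conn["k_total"] + 1e-12).all()

    def test_hub_boundary_is_strict(self):
        genes = [f"g{i}" for i in range(12)]
        labels = pd.Series(["m"] * 12, index=genes)
        conn = pd.DataFrame({"k_within": np.arange(12.0),
                             "k_total": np.arange(12.0)}, index=genes)
        kme = pd.Series([0.95] * 11 + [0.9], index=genes)   # top-k gene at 0.9
        p = pd.Series(1e-5, index=genes)
        flags = identify_hubs(conn, kme, p, labels)
        assert not flags["g11"]           # kME exactly 0.9 -> excluded
        assert flags.sum() == 0 or flags[kme > 0.9].any()

    def test_small_module_top_gene_rule(self):
        genes = [f"g{i}" for i in range(5)]
        labels = pd.Series(["m"] * 5, index=genes)
        conn = pd.DataFrame({"k_within": [1.0, 2, 3, 4, 5],
                             "k_total": [1.0, 2, 3, 4, 5]}, index=genes)
        kme = pd.Series(0.95, index=genes)
        p = pd.Series(1e-5, index=genes)
        flags = identify_hubs(conn, kme, p, labels)
        assert flags.sum() == 1 and flags["g4"]

    def test_planted_hubs_recovered(self):
        expr, truth = simulate_coexpression(
            block_sizes=(60, 50, 40), loading=0.85, hub_loading=0.99,
            n_hubs_per_block=3, n_samples=30, seed=8)
        state = build_network(expr, NetworkConfig(min_module_size=10))
        recovered = set(state.hub_flags[state.hub_flags].index)
        recall = len(recovered & set(truth.hub_genes)) / len(truth.hub_genes)
        assert recall >= 0.8

    def test_grey_genes_never_hubs(self):
        expr, _ = simulate_coexpression(block_sizes=(40,), n_samples=20,
                                        n_background=15, seed=9)
        state = build_network(expr, NetworkConfig(min_module_size=20))
        grey = state.module_labels == "grey"
        assert grey.any()
        assert not state.hub_flags[grey].any()


class TestSoftThreshold:
    def test_tie_break_prefers_smaller_power(self, rng):
        expr, _ = simulate_coexpression(
            block_sizes=(80, 40, 25, 15, 10), loading=0.8, n_samples=30,
            n_background=60, seed=10)
        beta, table = pick_soft_threshold(expr, (6, 8, 10, 12, 16), target_r2=0.0)
        passing = table.dropna(subset=["signed_r2"])
        assert beta == passing.loc[passing["signed_r2"] >= 0.0, "beta"].min()

    def test_white_noise_falls_back(self, rng):
        expr = pd.DataFrame(rng.standard_normal((8, 30)),
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"s{j}" for j in range(30)])
        with pytest.warns(UserWarning):
            beta, _ = pick_soft_threshold(expr, (2, 4), default_beta=16)
        assert beta == 16

    def test_heterogeneous_blocks_reach_scale_free_fit(self):
        expr, _ = simulate_coexpression(
            block_sizes=(150, 70, 40, 25, 15, 10), loading=0.9,
            loading_spread=0.45, n_samples=30, n_background=150, seed=11)
        beta, table = pick_soft_threshold(expr)
        chosen = table.set_index("beta").loc[beta, "signed_r2"]
        assert chosen >= 0.8


class TestTraitAssociation:
    def test_trait_equal_to_eigengene(self):
        eig = pd.DataFrame([[1.0, -1.0, 0.5, -0.5, 0.2]], index=["m"],
                           columns=[f"s{j}" for j in range(5)])
        traits = pd.DataFrame({"w": eig.loc["m"].values},
                              index=eig.columns)
        out = module_trait_association(eig, traits)
        assert out["cor"].iloc[0] == pytest.approx(1.0)
        out2 = module_trait_association(-eig, traits)
        assert out2["cor"].iloc[0] == pytest.approx(-1.0)

    def test_constant_trait_flagged(self):
        eig = pd.DataFrame([[1.0, -1.0, 0.5]], index=["m"],
                           columns=["s0", "s1", "s2"])
        traits = pd.DataFrame({"w": [1.0, 1.0, 1.0]}, index=eig.columns)
        out = module_trait_association(eig, traits)
        assert not out["defined"].iloc[0]

    def test_null_calibration(self, rng):
        rejections = 0
        n_sim = 500
        eig = pd.DataFrame([rng.standard_normal(20)], index=["m"],
                           columns=[f"s{j}" for j in range(20)])
        for _ in range(n_sim):
            traits = pd.DataFrame({"w": rng.standard_normal(20)},
                                  index=eig.columns)
            out = module_trait_association(eig, traits)
            rejections += out["p"].iloc[0] < 0.05
        rate = rejections / n_sim
        half = 2.576 * math.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half
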
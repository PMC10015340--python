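"""Co-expression network tests: TOM, modules, eigengenes, hubs, lasso."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lysiomics.network import (build_network, correlation_p_value,
                               cross_species_module_correlation,
                               detect_modules, gene_statistics, hub_genes,
                               intermodular_lasso, module_eigengenes,
                               module_trait_association, tom_from_adjacency)


def naive_tom(a):
    """Triple-loop TOM oracle."""
    a = np.asarray(a, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    n = len(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (shared + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


def planted_blocks(sizes, seed=0, noise=0.08, factors=None, n_cond=12,
                   n_noise=0):
    """Genes driven by per-block latent 12-vectors, plus free noise genes."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    if factors is None:
        factors = [rng.normal(0, 1, n_cond) for _ in sizes]
    for b, size in enumerate(sizes):
        for g in range(size):
            rows.append(factors[b] + rng.normal(0, noise, n_cond))
            truth.append(b)
    for g in range(n_noise):
        rows.append(rng.normal(0, 1, n_cond))
        truth.append(-1)
    idx = [f"g{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), np.array(truth), factors


class TestTom:
    def test_hand_computed_three_gene_case(self):
        a = np.array([[1.0, 0.5, 0.5],
                      [0.5, 1.0, 0.25],
                      [0.5, 0.25, 1.0]])
        tom = tom_from_adjacency(a)
        # TOM_12 = (0.5*0.25 + 0.5) / (min(1.0, 0.75) + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_perfect_pair_has_unit_adjacency(self):
        x = np.linspace(0, 1, 12)
        data = pd.DataFrame([x, 2 * x + 1, np.cos(7 * x)],
                            index=["a", "b", "c"])
        net = build_network(data, beta=10)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_isolated_gene_has_near_zero_tom_row(self):
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, 12)
        rows = [f + rng.normal(0, 0.05, 12) for _ in range(5)]
        rows.append(rng.normal(0, 1, 12))
        net = build_network(pd.DataFrame(rows))
        assert np.max(net.tom[-1, :-1]) < 0.05

    @given(st.integers(0, 1000))
    def test_vectorized_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 9)
        c = rng.uniform(-1, 1, (n, n))
        a = np.abs((c + c.T) / 2) ** 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_from_adjacency(a), naive_tom(a),
                                   atol=1e-8)

    def test_bounds_and_diagonal(self):
        data, _, _ = planted_blocks([10, 10], n_noise=5)
        tom = build_network(data).tom
        assert np.all((tom >= 0) & (tom <= 1))
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_zero_variance_gene_excluded(self):
        data, _, _ = planted_blocks([5])
        data.loc["flat"] = 3.0
        with pytest.warns(UserWarning):
            net = build_network(data)
        assert "flat" not in net.genes


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        data, truth, _ = planted_blocks([40, 40], seed=1)
        mods = detect_modules(build_network(data), data)
        labs = mods.labels
        assert set(labs) == {1, 2}
        sizes = labs.value_counts()
        assert sizes[1] == 40 and sizes[2] == 40
        # block membership is pure
        assert len(set(labs[truth == 0])) == 1 and len(set(labs[truth == 1])) == 1

    def test_undersized_block_left_unassigned(self):
        data, _, _ = planted_blocks([20], seed=2, n_noise=15)
        mods = detect_modules(build_network(data), data)
        assert (mods.labels == 0).all()

    def test_highly_correlated_blocks_merged(self):
        rng = np.random.default_rng(3)
        f1 = rng.normal(0, 1, 12)
        f2 = f1 + rng.normal(0, 0.25, 12)   # eigengene correlation ~0.97
        data, _, _ = planted_blocks([35, 35], seed=3, factors=[f1, f2])
        mods = detect_modules(build_network(data), data)
        assert len(set(mods.labels) - {0}) == 1

    def test_gene_order_permutation_invariance(self):
        data, _, _ = planted_blocks([32, 32], seed=4, n_noise=10)
        mods = detect_modules(build_network(data), data)
        perm = list(np.random.default_rng(0).permutation(data.index))
        data_p = data.loc[perm]
        mods_p = detect_modules(build_network(data_p), data_p)
        joint = pd.crosstab(mods.labels.loc[perm], mods_p.labels)
        # identical partitions up to label names: one nonzero cell per row
        assert ((joint > 0).sum(axis=1) == 1).all()


class TestEigengenes:
    def test_rank_one_module(self):
        v = np.sin(np.linspace(0, 3, 12))
        data = pd.DataFrame([v, 2 * v + 5, -3 * v], index=list("abc"))
        labels = pd.Series([1, 1, 1], index=list("abc"))
        mes, ev = module_eigengenes(data, labels)
        assert ev["ME1"] == pytest.approx(1.0)
        z = (v - v.mean()) / v.std()
        got = mes["ME1"].to_numpy()
        assert abs(np.corrcoef(got, z)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(got) == pytest.approx(1.0)

    def test_anticorrelated_pair(self):
        v = np.linspace(0, 1, 12)
        data = pd.DataFrame([v, -v], index=list("ab"))
        labels = pd.Series([1, 1], index=list("ab"))
        mes, ev = module_eigengenes(data, labels)
        assert ev["ME1"] == pytest.approx(1.0)
        kme = np.corrcoef(data.loc["a"], mes["ME1"])[0, 1]
        assert abs(kme) == pytest.approx(1.0)

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(6)
        f = rng.normal(0, 1, 12)
        data, _, _ = planted_blocks([40], seed=6, factors=[f], noise=0.1)
        labels = pd.Series(1, index=data.index)
        mes, _ = module_eigengenes(data, labels)
        assert abs(np.corrcoef(mes["ME1"], f)[0, 1]) >= 0.95


class TestTraitAssociation:
    def test_perfectly_ranked_me(self):
        trait = np.arange(12, dtype=float)
        mes = pd.DataFrame({"ME1": np.exp(trait)})  # same ranking
        out = module_trait_association(mes, trait)
        assert out.spearman_rho.iloc[0] == pytest.approx(1.0)

    def test_permutation_null_p_uniform(self):
        """Spearman p over random trait permutations is ~uniform (KS)."""
        rng = np.random.default_rng(7)
        trait = rng.normal(0, 1, 12)
        me = rng.normal(0, 1, 12)
        ps = []
        for _ in range(1000):
            perm = rng.permutation(trait)
            ps.append(stats.spearmanr(me, perm).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_me_flagged(self):
        mes = pd.DataFrame({"ME1": np.ones(12)})
        out = module_trait_association(mes, np.arange(12, dtype=float))
        assert out.degenerate.iloc[0] and not out.significant.iloc[0]


class TestHubs:
    @staticmethod
    def _stats(rows):
        return pd.DataFrame(rows, columns=["gene", "module", "kME", "GS"]) \
            .set_index("gene")

    def test_absolute_gs_rule(self):
        assoc = pd.DataFrame({"module": ["ME1"], "significant": [True]})
        t = self._stats([("a", 1, 0.9, -0.9), ("b", 1, 0.9, 0.5),
                         ("c", 1, 0.5, 0.9)])
        hubs = hub_genes(t, assoc)
        assert list(hubs) == ["a"]

    def test_only_trait_associated_modules_yield_hubs(self):
        assoc = pd.DataFrame({"module": ["ME1", "ME2"],
                              "significant": [False, True]})
        t = self._stats([("a", 1, 0.95, 0.95), ("b", 2, 0.95, 0.95)])
        assert list(hub_genes(t, assoc)) == ["b"]

    def test_planted_top_loading_genes_pass(self):
        rng = np.random.default_rng(8)
        trait = rng.normal(0, 1, 12)
        data, _, _ = planted_blocks([40], seed=8, factors=[trait], noise=0.05)
        # add weakly loading genes that should fail the thresholds
        for i in range(5):
            data.loc[f"weak{i}"] = 0.3 * trait + rng.normal(0, 1.0, 12)
        labels = pd.Series(1, index=data.index)
        mes, _ = module_eigengenes(data, labels)
        gs = gene_statistics(data, labels, mes, trait)
        assoc = module_trait_association(mes, trait, alpha=0.05)
        hubs = set(hub_genes(gs.table, assoc))
        strong = {g for g in data.index if not g.startswith("weak")}
        assert hubs and hubs.issubset(strong)
        assert not hubs & {f"weak{i}" for i in range(5)}


class TestCrossSpecies:
    def test_printed_correlation_p_values(self):
        assert round(correlation_p_value(0.721, 12), 3) == 0.008
        assert correlation_p_value(-0.902, 12) == pytest.approx(5.89e-5, rel=0.03)

    def test_zero_correlation_p_is_one(self):
        assert correlation_p_value(0.0, 12) == pytest.approx(1.0)

    def test_table_matches_scipy_pearson(self):
        rng = np.random.default_rng(9)
        a = pd.DataFrame(rng.normal(0, 1, (12, 2)), columns=["ME1", "ME2"])
        b = pd.DataFrame(rng.normal(0, 1, (12, 2)), columns=["ME1", "ME2"])
        out = cross_species_module_correlation(a, b)
        for _, row in out.iterrows():
            r, p = stats.pearsonr(a[row.module_a], b[row.module_b])
            assert row.pearson_r == pytest.approx(r)
            assert row.p_value == pytest.approx(p)


def naive_lasso(X, y, lam, n_iter=2000):
    """Cyclic coordinate descent for (1/2n)||y-Xb||^2 + lam ||b||_1."""
    n, p = X.shape
    b = np.zeros(p)
    for _ in range(n_iter):
        for j in range(p):
            r = y - X @ b + X[:, j] * b[j]
            rho = X[:, j] @ r / n
            z = (X[:, j] ** 2).sum() / n
            b[j] = np.sign(rho) * max(abs(rho) - lam, 0.0) / z
    return b


class TestIntermodularLasso:
    def test_orthonormal_design_soft_threshold(self):
        """On orthonormal predictors the lasso is soft-thresholded OLS."""
        rng = np.random.default_rng(10)
        n = 12
        M = rng.normal(0, 1, (n, 3))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))
        X = Q * np.sqrt(n)          # columns: mean 0, (1/n) X'X = I
        y = X @ np.array([1.0, 0.4, 0.0]) + rng.normal(0, 0.1, n)
        lam = 0.2
        from sklearn.linear_model import lasso_path
        _, coefs, _ = lasso_path(X, y, alphas=[lam])
        ols = X.T @ y / n
        soft = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
        np.testing.assert_allclose(coefs[:, 0], soft, atol=1e-6)
        np.testing.assert_allclose(naive_lasso(X, y, lam), soft, atol=1e-8)

    def test_path_matches_naive_coordinate_descent(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (12, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([1.0, -0.5, 0.0, 0.2]) + rng.normal(0, 0.2, 12)
        from sklearn.linear_model import lasso_path
        for lam in (0.05, 0.2, 0.5):
            _, coefs, _ = lasso_path(X, y, alphas=[lam], tol=1e-12)
            np.testing.assert_allclose(coefs[:, 0], naive_lasso(X, y, lam),
                                       atol=1e-6)

    def test_uncorrelated_predictor_dropped(self):
        rng = np.random.default_rng(12)
        mes = pd.DataFrame({
            "ME1": rng.normal(0, 1, 12),
            "ME2": rng.normal(0, 1, 12),
            "ME3": rng.normal(0, 1, 12),
        })
        mes["ME1"] = 0.95 * mes["ME2"] + 0.05 * rng.normal(0, 1, 12)
        net = intermodular_lasso(mes)
        into_me1 = net.edges[net.edges.target == "ME1"]
        assert set(into_me1.source) == {"ME2"}
        assert not ((net.edges.source == "ME3") & (net.edges.target == "ME1")).any()

    def test_no_self_edges_and_signs(self):
        rng = np.random.default_rng(13)
        mes = pd.DataFrame(rng.normal(0, 1, (12, 4)),
                           columns=[f"ME{i+1}" for i in range(4)])
        mes["ME4"] = -0.9 * mes["ME1"] + 0.1 * rng.normal(0, 1, 12)
        net = intermodular_lasso(mes)
        assert not (net.edges.source == net.edges.target).any()
        neg = net.edges[(net.edges.source == "ME1") & (net.edges.target == "ME4")]
        if len(neg):
            assert (neg.sign == -1).all()

    def test_too_few_modules_rejected(self):
        mes = pd.DataFrame(np.random.default_rng(1).normal(0, 1, (12, 2)),
                           columns=["ME1", "ME2"])
        with pytest.raises(ValueError):
            intermodular_lasso(mes)


class TestRecoveryPipeline:
    def test_trait_linked_module_found_across_seeds(self):
        """3 planted modules, one trait-linked: detected with p<0.01 usually."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            trait = rng.normal(0, 1, 12)
            f2, f3 = rng.normal(0, 1, (2, 12))
            data, truth, _ = planted_blocks(
                [35, 35, 35], seed=100 + seed, factors=[trait, f2, f3],
                noise=0.3, n_noise=30)
            mods = detect_modules(build_network(data), data)
            if not len(mods.eigengenes.columns):
                continue
            assoc = module_trait_association(mods.eigengenes, trait)
            sig = assoc[assoc.significant]
            # the significant module must be the trait-linked block
            ok = False
            for m in sig.module:
                members = mods.labels[mods.labels == int(m[2:])].index
                planted = data.index[truth == 0]
                if len(set(members) & set(planted)) >= 20:
                    ok = True
            hits += ok
        assert hits / n_seeds >= 0.9
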
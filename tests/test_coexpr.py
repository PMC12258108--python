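import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import prognet as pg
from prognet.coexpr import GREY, pearson_with_p, scale_free_fit
from prognet.datatypes import ValidationError

from conftest import random_expr


def scale_free_expr(n_genes=500, n_samples=400, seed=42):
    """Latent single-factor model with power-law-ish connectivity.

    cor(i, j) = a_i a_j with uniform loadings, so k ~ a^beta follows an
    exact power-law density and the log-log fit is near-perfect.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.3, 0.95, n_genes)
    f = rng.standard_normal(n_samples)
    X = np.outer(a, f) + np.sqrt(1 - a ** 2)[:, None] * rng.standard_normal(
        (n_genes, n_samples))
    return pg.ExpressionMatrix(pd.DataFrame(
        X, index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"S{i:04d}" for i in range(n_samples)]))


class TestSoftThreshold:
    def test_scale_free_generator_reaches_cut(self):
        scan = pg.scan_soft_threshold(scale_free_expr(), r2_cut=0.85)
        assert scan.chosen_beta <= max(scan.betas)
        assert scan.fit_r2[scan.betas.index(scan.chosen_beta)] >= 0.85

    def test_uncorrelated_noise_has_poor_fit(self):
        expr = random_expr(500, 200, seed=77)
        C = np.corrcoef(expr.values)
        np.fill_diagonal(C, 0.0)
        k = np.abs(C).sum(axis=1)
        assert scale_free_fit(k) < 0.3

    def test_scale_invariance(self):
        expr = scale_free_expr(n_genes=100, n_samples=100, seed=3)
        doubled = pg.ExpressionMatrix(expr.data * 2.0)
        with pytest.warns(UserWarning):
            s1 = pg.scan_soft_threshold(expr, betas=(1, 2, 3), r2_cut=0.99)
            s2 = pg.scan_soft_threshold(doubled, betas=(1, 2, 3), r2_cut=0.99)
        assert s1.fit_r2 == s2.fit_r2
        assert s1.chosen_beta == s2.chosen_beta

    def test_constant_gene_errors(self):
        expr = random_expr(30, 10, seed=1)
        expr.data.iloc[0] = 5.0
        with pytest.raises(ValidationError, match="constant"):
            pg.scan_soft_threshold(expr)

    def test_too_few_genes_errors(self):
        with pytest.raises(ValidationError):
            pg.scan_soft_threshold(random_expr(10, 10, seed=1))

    def test_fallback_to_argmax_with_warning(self):
        expr = random_expr(50, 30, seed=5)
        with pytest.warns(UserWarning, match="argmax"):
            scan = pg.scan_soft_threshold(expr, betas=(1, 2), r2_cut=0.999)
        assert scan.chosen_beta in (1, 2)


def brute_force_tom(A):
    """Triple-loop oracle for the unsigned TOM formula."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTom:
    def test_clique_of_identical_genes(self):
        vals = np.tile(np.array([1.0, 2.0, 4.0, 3.0]), (3, 1))
        vals += np.array([[0.0], [1.0], [2.0]])  # same shape, shifted: cor = 1
        expr = pg.ExpressionMatrix(pd.DataFrame(
            vals, index=["A", "B", "C"], columns=list("wxyz")))
        _, T = pg.tom_matrix(expr, beta=1)
        np.testing.assert_allclose(T, 1.0, atol=1e-12)

    def test_uncorrelated_pair_is_zero(self):
        vals = np.array([[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]])
        expr = pg.ExpressionMatrix(pd.DataFrame(
            vals, index=["A", "B"], columns=list("wxyz")))
        _, T = pg.tom_matrix(expr, beta=2)
        assert T[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        expr = random_expr(6, 12, seed=8)
        genes, T = pg.tom_matrix(expr, beta=3)
        A = np.abs(np.corrcoef(expr.values)) ** 3
        np.fill_diagonal(A, 0.0)
        np.testing.assert_allclose(T, brute_force_tom(A), atol=1e-12)

    def test_matrix_invariants(self):
        _, T = pg.tom_matrix(random_expr(20, 15, seed=9), beta=6)
        np.testing.assert_allclose(T, T.T, atol=1e-12)
        assert T.min() >= 0.0 and T.max() <= 1.0
        np.testing.assert_array_equal(np.diag(T), 1.0)

    def test_network_wrapper(self):
        expr = random_expr(5, 10, seed=10)
        net = pg.tom(expr, beta=2)
        genes, T = pg.tom_matrix(expr, beta=2)
        for u, v, w in net.edge_weights():
            i, j = genes.index(u), genes.index(v)
            assert w == pytest.approx(T[i, j])


def block_tom_net(sizes, within=1.0, between=0.0):
    g = nx.Graph()
    names, offset = [], 0
    for b, size in enumerate(sizes):
        names.append([f"B{b}g{i:02d}" for i in range(size)])
    flat = [n for blk in names for n in blk]
    g.add_nodes_from(flat)
    for bi, blk_i in enumerate(names):
        for bj, blk_j in enumerate(names):
            for u in blk_i:
                for v in blk_j:
                    if u < v:
                        w = within if bi == bj else between
                        if w > 0:
                            g.add_edge(u, v, weight=w)
    return pg.GeneNetwork(g), names


class TestDetectModules:
    def test_two_perfect_blocks(self):
        net, names = block_tom_net([4, 3])
        expr = random_expr(7, 10, seed=11)
        expr.data.index = [n for blk in names for n in blk]
        mods = pg.detect_modules(net, expr, cut_height=0.5, min_size=3)
        assert set(mods.modules) == {"turquoise", "blue"}
        assert set(mods.genes_in("turquoise")) == set(names[0])  # larger block
        assert set(mods.genes_in("blue")) == set(names[1])

    def test_no_structure_all_grey(self):
        net, names = block_tom_net([3, 3], within=0.0)
        expr = random_expr(6, 8, seed=12)
        expr.data.index = [n for blk in names for n in blk]
        mods = pg.detect_modules(net, expr, cut_height=0.8, min_size=3)
        assert (mods.assignment == GREY).all()
        assert mods.modules == []

    def test_three_block_generator_recovery(self):
        aris = []
        for seed in range(21, 26):
            cfg = pg.SimConfig(n_genes=150, n_samples=200, module_blocks=3,
                               rho=0.8, signature_size=15, effect_size=0.6,
                               decoy_frac=0.0, seed=seed)
            d = pg.simulate_dataset(cfg)
            mods = pg.detect_modules(pg.tom(d.expr, 6), d.expr,
                                     cut_height=0.8, min_size=10)
            blocks = d.truth["block_assignment"]
            genes = list(mods.assignment.index)
            aris.append(adjusted_rand_score([blocks[g] for g in genes],
                                            list(mods.assignment)))
        assert np.mean(aris) >= 0.9

    def test_gene_order_invariance(self):
        cfg = pg.SimConfig(n_genes=60, n_samples=80, module_blocks=2, rho=0.8,
                           signature_size=10, decoy_frac=0.0, seed=30)
        d = pg.simulate_dataset(cfg)
        net = pg.tom(d.expr, 4)
        mods1 = pg.detect_modules(net, d.expr, cut_height=0.8, min_size=5)
        rng = np.random.default_rng(0)
        shuffled = pg.ExpressionMatrix(
            d.expr.data.iloc[rng.permutation(d.expr.n_genes)])
        net2 = pg.tom(shuffled, 4)
        mods2 = pg.detect_modules(net2, shuffled, cut_height=0.8, min_size=5)
        assert mods1.assignment.sort_index().equals(mods2.assignment.sort_index())

    def test_eigengene_of_perfectly_correlated_module(self):
        rng = np.random.default_rng(14)
        profile = rng.standard_normal(12)
        vals = np.vstack([2 * profile + 1, -0.5 * profile, profile])
        vals[1] = 0.5 * profile + 3  # keep all members positively correlated
        expr = pg.ExpressionMatrix(pd.DataFrame(
            vals, index=["A", "B", "C"], columns=[f"S{i}" for i in range(12)]))
        e = pg.module_eigengene(expr, ["A", "B", "C"])
        std = (profile - profile.mean()) / profile.std(ddof=1)
        std /= np.linalg.norm(std)
        np.testing.assert_allclose(np.abs(e.to_numpy()), np.abs(std), atol=1e-9)
        assert np.corrcoef(e, profile)[0, 1] == pytest.approx(1.0)

    def test_eigengenes_unit_norm_and_oriented(self):
        cfg = pg.SimConfig(n_genes=60, n_samples=50, module_blocks=2, rho=0.7,
                           signature_size=10, decoy_frac=0.0, seed=31)
        d = pg.simulate_dataset(cfg)
        mods = pg.detect_modules(pg.tom(d.expr, 4), d.expr, min_size=5)
        for m in mods.modules:
            e = mods.eigengenes[m].to_numpy()
            assert np.linalg.norm(e) == pytest.approx(1.0)
            cors = [np.corrcoef(e, d.expr.data.loc[g])[0, 1]
                    for g in mods.genes_in(m)]
            assert np.mean(cors) >= 0


def brute_force_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / (sxx * syy) ** 0.5
    from scipy.stats import t as t_dist
    stat = r * ((n - 2) / (1 - r ** 2)) ** 0.5
    return r, 2 * t_dist.sf(abs(stat), n - 2)


class TestModuleTrait:
    def _modules_with_eigengene(self, e, samples):
        assignment = pd.Series(["turquoise"], index=pd.Index(["A"], name="gene"))
        eig = pd.DataFrame({"turquoise": e}, index=pd.Index(samples, name="sample"))
        return pg.ModuleSet(assignment, eig)

    def test_eigengene_equal_to_trait(self):
        samples = [f"S{i}" for i in range(10)]
        e = np.linspace(-1, 1, 10)
        mods = self._modules_with_eigengene(e, samples)
        pheno = pg.PhenotypeTable(pd.DataFrame(
            {"trait": e}, index=pd.Index(samples, name="sample")))
        out = pg.module_trait(mods, pheno, ["trait"])
        assert out.trait_cor.loc["turquoise", "trait"] == pytest.approx(1.0)
        assert out.trait_p.loc["turquoise", "trait"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait(self):
        samples = [f"S{i}" for i in range(4)]
        mods = self._modules_with_eigengene(np.array([1.0, -1.0, 1.0, -1.0]), samples)
        pheno = pg.PhenotypeTable(pd.DataFrame(
            {"trait": [1.0, 1.0, -1.0, -1.0]}, index=pd.Index(samples, name="sample")))
        out = pg.module_trait(mods, pheno, ["trait"])
        assert out.trait_cor.loc["turquoise", "trait"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        r, p = pearson_with_p(x, y)
        rb, pb = brute_force_pearson(list(x), list(y))
        assert r == pytest.approx(rb, abs=1e-12)
        assert p == pytest.approx(pb, abs=1e-12)

    def test_constant_trait_warns_and_is_missing(self):
        samples = [f"S{i}" for i in range(5)]
        mods = self._modules_with_eigengene(np.arange(5.0), samples)
        pheno = pg.PhenotypeTable(pd.DataFrame(
            {"trait": [2.0] * 5}, index=pd.Index(samples, name="sample")))
        with pytest.warns(UserWarning, match="constant"):
            out = pg.module_trait(mods, pheno, ["trait"])
        assert np.isnan(out.trait_cor.loc["turquoise", "trait"])
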
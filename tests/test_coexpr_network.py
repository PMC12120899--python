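import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from polytraitx.coexpr_network import (
    NetworkConfig,
    build_network,
    cluster_modules,
    go_enrichment,
    gene_stats,
    merge_modules,
    module_eigengene,
    module_trait_stats,
    signed_adjacency,
    signed_tom,
)


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """O(n^3) triple-loop signed TOM."""
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


def random_adjacency(rng, n=10):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    a = ((1 + r) / 2) ** 6
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlations_map_to_bounds(self):
        t = np.linspace(0, 1, 8)
        expr = pd.DataFrame(
            [t, 2 * t + 1, -t, np.sin(20 * t)], index=["a", "b", "c", "d"]
        )
        a = signed_adjacency(expr, power=12)
        assert a.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "c"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_correlation_gives_half_to_the_beta(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])  # exactly orthogonal after centering
        a = signed_adjacency(pd.DataFrame([x, y], index=["a", "b"]), power=12)
        assert a.loc["a", "b"] == pytest.approx(0.5**12)


class TestSignedTom:
    def test_two_gene_network_equals_adjacency(self):
        a = pd.DataFrame([[1.0, 0.3], [0.3, 1.0]], index=list("ab"), columns=list("ab"))
        tom = signed_tom(a)
        assert tom.loc["a", "b"] == pytest.approx(0.3)

    def test_identical_rows_with_unit_link_give_unit_tom(self):
        a = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        df = pd.DataFrame(a, index=list("abc"), columns=list("abc"))
        assert signed_tom(df).loc["a", "b"] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self):
        for seed in range(5):
            a = random_adjacency(np.random.default_rng(seed))
            df = pd.DataFrame(a)
            got = signed_tom(df).to_numpy()
            assert np.abs(got - tom_oracle(a)).max() < 1e-12

    def test_requires_symmetry(self):
        a = pd.DataFrame([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            signed_tom(a)

    def test_bounds_fuzz(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            a = random_adjacency(rng, n=8)
            tom = signed_tom(pd.DataFrame(a)).to_numpy()
            assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()
            assert np.allclose(tom, tom.T)
            assert np.allclose(np.diag(tom), 1.0)


def planted_blocks(rng, sizes=(40, 40), n_acc=20, noise=0.1):
    factors = rng.standard_normal((len(sizes), n_acc))
    rows, names = [], []
    for b, size in enumerate(sizes):
        for g in range(size):
            rows.append(factors[b] + noise * rng.standard_normal(n_acc))
            names.append(f"b{b}_g{g:03d}")
    return pd.DataFrame(rows, index=names)


class TestClusterModules:
    def test_two_planted_blocks_recovered_without_grey(self):
        expr = planted_blocks(np.random.default_rng(0))
        tom = signed_tom(signed_adjacency(expr, 6))
        labels = cluster_modules(1 - tom, min_module_size=30)
        assert (labels != "grey").all()
        assert labels.nunique() == 2
        for b in (0, 1):
            block = labels[labels.index.str.startswith(f"b{b}_")]
            assert block.nunique() == 1

    def test_too_few_genes_all_grey(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.standard_normal((20, 10)))
        tom = signed_tom(signed_adjacency(expr, 6))
        labels = cluster_modules(1 - tom, min_module_size=30)
        assert (labels == "grey").all()


class TestEigengene:
    def test_identical_profiles_return_standardized_profile(self):
        rng = np.random.default_rng(2)
        prof = rng.uniform(0, 5, size=12)
        expr = pd.DataFrame([prof] * 5, index=[f"g{i}" for i in range(5)])
        eg = module_eigengene(expr, list(expr.index))
        z = (prof - prof.mean()) / prof.std()
        expected = z / np.linalg.norm(z)
        assert np.allclose(eg, expected)

    def test_sign_oriented_positively(self):
        rng = np.random.default_rng(3)
        expr = planted_blocks(rng, sizes=(10,), noise=0.05)
        eg = module_eigengene(expr, list(expr.index))
        z = (expr - expr.mean(axis=1).to_numpy()[:, None])
        z = z / z.std(axis=1, ddof=0).to_numpy()[:, None]
        assert (z @ eg).sum() > 0
        # flipping every gene leaves the oriented eigengene unchanged up to sign flip
        eg2 = module_eigengene(-expr, list(expr.index))
        assert np.allclose(np.abs(eg2), np.abs(eg))

    def test_matches_covariance_eigenvector_oracle(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.standard_normal((10, 8)),
                            index=[f"g{i}" for i in range(10)])
        eg = module_eigengene(expr, list(expr.index))
        x = expr.to_numpy()
        z = (x - x.mean(axis=1)[:, None]) / x.std(axis=1, ddof=0)[:, None]
        vals, vecs = np.linalg.eigh(z.T @ z)  # accession-space covariance
        v = vecs[:, np.argmax(vals)]
        v /= np.linalg.norm(v)
        assert np.allclose(np.abs(eg), np.abs(v), atol=1e-8)

    def test_explains_at_least_average_gene_variance(self):
        rng = np.random.default_rng(5)
        expr = planted_blocks(rng, sizes=(15,), noise=0.5)
        eg = module_eigengene(expr, list(expr.index)).to_numpy()
        z = expr.to_numpy()
        z = (z - z.mean(axis=1)[:, None]) / z.std(axis=1, ddof=0)[:, None]
        explained = ((z @ eg) ** 2).sum()
        per_gene = (z**2).sum(axis=1)
        assert explained >= per_gene.mean() - 1e-9


class TestMerge:
    def _expr_with_cor(self, rho, rng):
        """Two 5-gene modules whose latent factors correlate at ~rho."""
        n = 200
        f1 = rng.standard_normal(n)
        f2 = rho * f1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        rows, names = [], []
        for b, f in enumerate((f1, f2)):
            for g in range(5):
                rows.append(f + 0.01 * rng.standard_normal(n))
                names.append(f"m{b}_g{g}")
        expr = pd.DataFrame(rows, index=names)
        labels = pd.Series(["blue"] * 5 + ["red"] * 5, index=names)
        return expr, labels

    def test_highly_correlated_modules_merge(self):
        expr, labels = self._expr_with_cor(0.9, np.random.default_rng(0))
        merged = merge_modules(expr, labels, 0.25)
        assert merged.nunique() == 1

    def test_weakly_correlated_modules_stay(self):
        expr, labels = self._expr_with_cor(0.5, np.random.default_rng(0))
        merged = merge_modules(expr, labels, 0.25)
        assert merged.nunique() == 2


class TestTraitStats:
    def test_trait_equal_to_eigengene_gives_unit_correlation(self):
        rng = np.random.default_rng(6)
        eg = pd.DataFrame({"blue": rng.standard_normal(20)})
        trait = pd.Series(eg["blue"].to_numpy(), index=eg.index)
        stats_df = module_trait_stats(eg, trait)
        assert stats_df.loc["blue", "r"] == pytest.approx(1.0)
        assert stats_df.loc["blue", "p"] < 1e-12

    def test_gene_stats_ranges(self):
        rng = np.random.default_rng(7)
        expr = planted_blocks(rng, sizes=(10,), noise=0.3)
        labels = pd.Series("blue", index=expr.index)
        eg = pd.DataFrame({"blue": module_eigengene(expr, list(expr.index))})
        trait = pd.Series(rng.standard_normal(expr.shape[1]), index=expr.columns)
        gs = gene_stats(expr, trait, labels, eg)
        assert ((gs["GS"] >= 0) & (gs["GS"] <= 1)).all()
        assert ((gs["MM"] >= -1) & (gs["MM"] <= 1)).all()


class TestGoEnrichment:
    def test_exact_hypergeometric_value(self):
        universe = {f"g{i}" for i in range(20)}
        term_genes = {f"g{i}" for i in range(5)}
        go_map = pd.DataFrame({"gene_id": sorted(term_genes), "go_id": "GO:X"})
        res = go_enrichment(term_genes, universe, go_map)
        expected = 1 / comb(20, 5)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_proportional_overlap_is_not_significant(self):
        universe = {f"g{i}" for i in range(100)}
        members = {f"g{i}" for i in range(50)}  # term covers half the universe
        gene_set = {f"g{i}" for i in range(0, 100, 2)}  # half of it by parity
        go_map = pd.DataFrame({"gene_id": sorted(members), "go_id": "GO:X"})
        res = go_enrichment(gene_set, universe, go_map)
        assert not res["significant"].any()

    def test_bh_adjustment_of_enrichment_table(self):
        """Adjusted p equals the step-up minimum of m*p/rank over the table."""
        rng = np.random.default_rng(10)
        universe = {f"g{i}" for i in range(60)}
        rows = []
        for t in range(4):
            members = rng.choice(sorted(universe), size=12, replace=False)
            rows += [(g, f"GO:{t}") for g in members]
        go_map = pd.DataFrame(rows, columns=["gene_id", "go_id"])
        gene_set = {f"g{i}" for i in range(20)}
        res = go_enrichment(gene_set, universe, go_map)
        p = res["p"].to_numpy()
        m = len(p)
        ranked = m * p / (np.arange(m) + 1)
        expected = np.minimum.accumulate(ranked[::-1])[::-1]
        assert np.allclose(res["p_adj"], np.minimum(expected, 1.0))

    def test_gene_set_must_be_subset(self):
        with pytest.raises(ValueError):
            go_enrichment({"x"}, {"y"}, pd.DataFrame({"gene_id": [], "go_id": []}))


class TestPipelineDeterminism:
    def test_identical_input_gives_identical_modules(self):
        expr = planted_blocks(np.random.default_rng(8), sizes=(35, 35), noise=0.3)
        trait = pd.Series(np.arange(expr.shape[1], dtype=float), index=expr.columns)
        cfg = NetworkConfig(power=6, min_module_size=30)
        r1 = build_network(expr, trait, cfg)
        r2 = build_network(expr, trait, cfg)
        assert r1.labels.equals(r2.labels)
        assert np.allclose(r1.eigengenes, r2.eigengenes)
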
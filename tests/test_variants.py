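import math

import numpy as np
import pandas as pd
import pytest
import skbio

from polytraitx.variants import (
    GenotypeMatrix,
    annotate_snps,
    filter_snps,
    hwe_exact_test,
    ibs_distance,
    nj_tree,
    read_gff3,
    read_vcf,
    write_vcf,
)


def make_gm(dosages, accessions=None, chrom="Chr1"):
    dosages = np.asarray(dosages, dtype=float)
    n_snps, n_acc = dosages.shape
    accessions = accessions or [f"A{i + 1:02d}" for i in range(n_acc)]
    ids = [f"snp_{chrom}_{100 * (i + 1)}" for i in range(n_snps)]
    snp_map = pd.DataFrame(
        {"chrom": chrom, "pos": [100 * (i + 1) for i in range(n_snps)],
         "ref": "A", "alt": "G"},
        index=ids,
    )
    return GenotypeMatrix(pd.DataFrame(dosages, index=ids, columns=accessions), snp_map)


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-integer enumeration of the conditional HWE distribution."""
    n = n_AA + n_Aa + n_aa
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        homr = (rare - het) // 2
        homc = n - homr - het
        w = (math.factorial(n) // (math.factorial(homr) * math.factorial(het) * math.factorial(homc))) * (2**het)
        weights[het] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    return sum(w for w in weights.values() if w <= obs) / total


class TestVcfRoundTrip:
    def test_write_then_read_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(12, 6)).astype(float)
        dos[rng.random(dos.shape) < 0.1] = np.nan
        gm = make_gm(dos)
        path = tmp_path / "x.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        pd.testing.assert_frame_equal(gm.dosage, back.dosage)
        pd.testing.assert_frame_equal(gm.snp_map, back.snp_map)

    def test_gt_parsing_and_multiallelic_skip(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=Chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA01\tA02\tA03\n"
            "Chr1\t100\ts1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t./.\n"
            "Chr1\t200\ts2\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        )
        path = tmp_path / "toy.vcf"
        path.write_text(text)
        with pytest.warns(UserWarning, match="multiallelic"):
            gm = read_vcf(path)
        assert gm.n_snps == 1
        row = gm.dosage.loc["s1"]
        assert row["A01"] == 1 and row["A02"] == 2 and np.isnan(row["A03"])


class TestHweExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_extreme_heterozygote_excess_is_small(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @pytest.mark.parametrize("counts", [(25, 50, 25), (21, 57, 22), (3, 4, 5), (40, 2, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-12)

    def test_random_counts_against_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = tuple(int(x) for x in rng.integers(0, 40, size=3))
            if sum(c) == 0:
                continue
            assert hwe_exact_test(*c) == pytest.approx(hwe_oracle(*c), abs=1e-12)


class TestFilterSnps:
    def test_call_rate_boundary(self):
        dos = np.ones((1, 48))
        dos[0, :3] = np.nan  # 45/48 = 0.9375 < 0.95
        dos[0, 3] = 0.0  # keep polymorphic
        gm = make_gm(dos)
        out, drops = filter_snps(gm)
        assert out.n_snps == 0 and drops["call_rate"] == 1

    def test_maf_boundary_inclusive(self):
        # 40 accessions, 4 het -> freq 4/80 = 0.05 exactly
        dos = np.zeros((1, 40))
        dos[0, :4] = 1.0
        out, _ = filter_snps(make_gm(dos))
        assert out.n_snps == 1

    def test_hand_enumerated_toy_panel(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(12, 48)).astype(float)
        dos[0, :] = 0.0  # monomorphic -> maf 0
        dos[1, :5] = np.nan  # call rate 43/48
        dos[2, :] = 1.0  # all het -> HWE failure
        gm = make_gm(dos)
        out, drops = filter_snps(gm)
        survivors = []
        for i in range(12):
            row = dos[i]
            called = ~np.isnan(row)
            if called.mean() < 0.95:
                continue
            f = row[called].sum() / (2 * called.sum())
            if min(f, 1 - f) < 0.05:
                continue
            n_AA = int((row[called] == 0).sum())
            n_Aa = int((row[called] == 1).sum())
            n_aa = int((row[called] == 2).sum())
            if hwe_oracle(n_AA, n_Aa, n_aa) < 1e-6:
                continue
            survivors.append(gm.dosage.index[i])
        assert list(out.dosage.index) == survivors
        assert sum(drops.values()) == 12 - len(survivors)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        dos = rng.integers(0, 3, size=(30, 48)).astype(float)
        dos[rng.random(dos.shape) < 0.03] = np.nan
        once, _ = filter_snps(make_gm(dos))
        twice, drops = filter_snps(once)
        pd.testing.assert_frame_equal(once.dosage, twice.dosage)
        assert sum(drops.values()) == 0


class TestAnnotation:
    @pytest.fixture()
    def features(self):
        rows = [
            ("Chr1", 100, 1000, "gene", "gX", "+"),
            ("Chr1", 100, 180, "five_prime_UTR", "gX", "+"),
            ("Chr1", 100, 400, "exon", "gX", "+"),
            ("Chr1", 181, 400, "CDS", "gX", "+"),
            ("Chr1", 600, 1000, "exon", "gX", "+"),
            ("Chr1", 600, 900, "CDS", "gX", "+"),
            ("Chr1", 901, 1000, "three_prime_UTR", "gX", "+"),
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id", "strand"])

    @pytest.mark.parametrize(
        "pos,expected",
        [(200, "exon"), (150, "UTR5"), (950, "UTR3"), (500, "intron"), (5000, "intergenic")],
    )
    def test_region_precedence(self, features, pos, expected):
        dos = np.zeros((1, 3))
        dos[0, 0] = 1.0
        gm = make_gm(dos)
        gm.snp_map.loc[:, "pos"] = pos
        anno = annotate_snps(gm, features)
        assert anno.iloc[0]["region"] == expected

    def test_unknown_chromosome_is_intergenic_with_warning(self, features):
        gm = make_gm(np.ones((1, 3)) * 0, chrom="ChrZ")
        gm.dosage.iloc[0, 0] = 1.0
        with pytest.warns(UserWarning, match="unknown chromosome"):
            anno = annotate_snps(gm, features)
        assert anno.iloc[0]["region"] == "intergenic"

    def test_generated_gff_round_trips_and_annotates(self, tmp_path, small_dataset):
        from polytraitx.synthetic_data import write_gff3

        ds = small_dataset
        path = tmp_path / "models.gff3"
        write_gff3(ds.gene_models, path)
        feats = read_gff3(path)
        gene_rows = feats[feats["feature"] == "gene"]
        assert len(gene_rows) == ds.config.n_genes
        anno = annotate_snps(ds.genotypes, feats)
        # generator places every SNP inside a gene model
        assert (anno["region"] != "intergenic").all()
        counts = anno["region"].value_counts(normalize=True)
        assert counts["exon"] > 0.7  # exon-heavy mix by construction


class TestDistanceAndTree:
    def test_identical_accessions_distance_zero(self):
        dos = np.array([[0, 0, 2], [1, 1, 0], [2, 2, 1]], dtype=float)
        d = ibs_distance(make_gm(dos))
        assert d.iloc[0, 1] == 0.0

    def test_three_taxon_closed_form(self):
        dos = np.array([[0, 2, 2], [0, 0, 2], [2, 2, 0]], dtype=float)
        gm = make_gm(dos)
        d = ibs_distance(gm)
        tree = skbio.TreeNode.read([nj_tree(d)])
        # star tree branch lengths: (d_ab + d_ac - d_bc)/2 etc.
        names = list(d.index)
        for a in names:
            b, c = [x for x in names if x != a]
            expected = (d.loc[a, b] + d.loc[a, c] - d.loc[b, c]) / 2
            assert tree.find(a).length == pytest.approx(expected)

    def test_additive_four_taxon_metric_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        dist = pd.DataFrame(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ],
            index=list("ABCD"), columns=list("ABCD"),
        )
        tree = skbio.TreeNode.read([nj_tree(dist)])
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(dist.loc[a, b])

    def test_leaf_set_matches_accessions(self, small_dataset):
        gm_f, _ = filter_snps(small_dataset.genotypes)
        newick = nj_tree(ibs_distance(gm_f))
        tree = skbio.TreeNode.read([newick])
        assert {t.name for t in tree.tips()} == set(gm_f.accessions)

    def test_population_clusters_form_clades(self, small_dataset):
        """NJ on IBS distances separates the four planted clusters."""
        ds = small_dataset
        gm_f, _ = filter_snps(ds.genotypes)
        tree = skbio.TreeNode.read([nj_tree(ibs_distance(gm_f))])
        clusters = ds.truth["clusters"]
        for c in sorted(set(clusters.values())):
            members = {a for a, v in clusters.items() if v == c}
            outgroup = next(a for a, v in clusters.items() if v != c)
            rooted = tree.root_at(tree.find(outgroup).parent)
            lca = rooted.lca([rooted.find(m) for m in members])
            assert {t.name for t in lca.tips()} == members
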
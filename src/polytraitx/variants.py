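"""SNP genotype handling: VCF I/O, quality filters, annotation, phylogeny.

Genotypes are biallelic dosages in {0, 1, 2} with NaN for missing calls.
Sites are filtered on call rate, minor allele frequency and an exact
Hardy-Weinberg test; surviving SNPs are annotated against gene models and
summarized into an identity-by-state distance matrix from which a
neighbor-joining tree of the accessions is built.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy.special import gammaln
from skbio import DistanceMatrix
from skbio.tree import nj

__all__ = [
    "GenotypeMatrix",
    "read_vcf",
    "write_vcf",
    "read_gff3",
    "hwe_exact_test",
    "filter_snps",
    "annotate_snps",
    "ibs_distance",
    "nj_tree",
]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (SNPs x accessions) with a physical map.

    ``dosage`` holds alt-allele counts {0, 1, 2} as floats with NaN = missing;
    ``snp_map`` has one row per SNP (same order) with columns
    ``chrom``, ``pos`` (1-based), ``ref``, ``alt``.
    """

    dosage: pd.DataFrame = field(repr=False)
    snp_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.dosage.index.equals(self.snp_map.index):
            raise ValueError("dosage and snp_map must share the SNP index")
        vals = self.dosage.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be increasing within chromosome")

    @property
    def accessions(self) -> list[str]:
        return [str(c) for c in self.dosage.columns]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[0]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF (v4.2, GT field) into a dosage matrix.

    Multiallelic records are skipped with a warning; ``./.`` becomes NaN.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, rows, map_rows = [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = var.gt_types.astype(float)  # 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt[gt == 3] = np.nan
        vid = var.ID or f"snp_{var.CHROM}_{var.POS}"
        ids.append(vid)
        rows.append(gt)
        map_rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic records")
    dosage = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    snp_map = pd.DataFrame(map_rows, index=ids, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2 (round-trips through :func:`read_vcf`)."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.accessions) + "\n")
        dos = gm.dosage.to_numpy(dtype=float)
        for i, snp in enumerate(gm.dosage.index):
            m = gm.snp_map.iloc[i]
            calls = "\t".join(
                "./." if np.isnan(d) else gt_of[d] for d in dos[i]
            )
            fh.write(
                f"{m['chrom']}\t{int(m['pos'])}\t{snp}\t{m['ref']}\t{m['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Parse a GFF3 into the flat feature table used by :func:`annotate_snps`.

    Keeps gene / exon / CDS / UTR features; ``gene_id`` is the feature's own
    ID for genes and the top-level ancestor gene otherwise.  Intervals stay
    1-based inclusive.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    wanted = {"gene", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in wanted:
            continue
        if feat.featuretype == "gene":
            gene_id = feat.id
        else:
            parents = [p.id for p in db.parents(feat, featuretype="gene")]
            gene_id = parents[0] if parents else ""
        rows.append(
            (feat.seqid, int(feat.start), int(feat.end), feat.featuretype, gene_id, feat.strand)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "feature", "gene_id", "strand"]
    )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts whose probability under HWE does not exceed that of
    the observed count (the standard exact HWE test).  Monomorphic sites
    return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0 or n_AA + n_Aa + n_aa < 1:
        raise ValueError("genotype counts must be non-negative and sum to >= 1")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-agnostic: use rarer allele
    n_A = 2 * n_AA + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0
    # possible heterozygote counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2       # rare-allele homozygotes
    homc = n - homr - hets          # common-allele homozygotes
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs = probs / probs.sum()
    obs = probs[hets == n_Aa]
    if obs.size == 0:  # inconsistent het count (wrong parity) cannot occur from real data
        raise ValueError("heterozygote count inconsistent with allele totals")
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_snps(
    gm: GenotypeMatrix,
    max_missing: float = 0.95,
    maf: float = 0.05,
    hwe_p: float = 1e-6,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Site filters: call rate >= max_missing, MAF >= maf, HWE p >= hwe_p.

    Thresholds are inclusive (vcftools convention); filters apply in that
    order and per-filter drop counts are returned.
    """
    dos = gm.dosage.to_numpy(dtype=float)
    n_acc = dos.shape[1]
    called = (~np.isnan(dos)).sum(axis=1)
    keep_call = called / n_acc >= max_missing

    with np.errstate(invalid="ignore"):
        freq = np.nansum(dos, axis=1) / (2 * called)
    minor = np.minimum(freq, 1 - freq)
    keep_maf = keep_call & (minor >= maf)

    keep_hwe = keep_maf.copy()
    for i in np.flatnonzero(keep_maf):
        row = dos[i]
        n_aa = int(np.nansum(row == 2))
        n_het = int(np.nansum(row == 1))
        n_AA = int(np.nansum(row == 0))
        if hwe_exact_test(n_AA, n_het, n_aa) < hwe_p:
            keep_hwe[i] = False

    drops = {
        "call_rate": int((~keep_call).sum()),
        "maf": int((keep_call & ~keep_maf).sum()),
        "hwe": int((keep_maf & ~keep_hwe).sum()),
    }
    out = GenotypeMatrix(
        dosage=gm.dosage.loc[keep_hwe], snp_map=gm.snp_map.loc[keep_hwe]
    )
    return out, drops


def annotate_snps(gm: GenotypeMatrix, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Region annotation (exon / UTR5 / UTR3 / intron / intergenic) per SNP.

    ``gene_models`` is a feature table with columns ``chrom``, ``start``,
    ``end`` (1-based inclusive), ``feature`` in {gene, exon, CDS,
    five_prime_UTR, three_prime_UTR}, ``gene_id``, ``strand``.  Precedence
    when features overlap: CDS/exon > UTR > intron; a SNP inside a gene span
    with no exon/UTR overlap is intronic.
    """
    result = []
    by_chrom = {c: g for c, g in gene_models.groupby("chrom", sort=False)}
    known = set(by_chrom)
    for snp, m in zip(gm.snp_map.index, gm.snp_map.itertuples(index=False)):
        if m.chrom not in known:
            warnings.warn(f"{snp}: unknown chromosome {m.chrom}")
            result.append((snp, m.chrom, m.pos, "intergenic", ""))
            continue
        feats = by_chrom[m.chrom]
        hit = feats[(feats["start"] <= m.pos) & (m.pos <= feats["end"])]
        genes = hit[hit["feature"] == "gene"]
        if genes.empty:
            result.append((snp, m.chrom, m.pos, "intergenic", ""))
            continue
        gene_id = str(genes.iloc[0]["gene_id"])
        ghit = hit[hit["gene_id"] == gene_id]
        kinds = set(ghit["feature"])
        # GFF3 exon features span the UTRs, so coding status (CDS) outranks
        # the UTR label, which outranks a bare exon hit; intron otherwise.
        if "CDS" in kinds:
            region = "exon"
        elif "five_prime_UTR" in kinds:
            region = "UTR5"
        elif "three_prime_UTR" in kinds:
            region = "UTR3"
        elif "exon" in kinds:
            region = "exon"
        else:
            region = "intron"
        result.append((snp, m.chrom, m.pos, region, gene_id))
    return pd.DataFrame(
        result, columns=["snp_id", "chrom", "pos", "region", "gene_id"]
    ).set_index("snp_id")


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state distance: mean |dosage_a - dosage_b| / 2 over co-called sites."""
    if len(gm.accessions) < 3:
        raise ValueError("need at least 3 accessions")
    dos = gm.dosage.to_numpy(dtype=float)
    n = dos.shape[1]
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            mask = ~np.isnan(dos[:, a]) & ~np.isnan(dos[:, b])
            if not mask.any():
                raise ValueError(
                    f"no co-called sites for {gm.accessions[a]} / {gm.accessions[b]}"
                )
            d[a, b] = d[b, a] = float(np.abs(dos[mask, a] - dos[mask, b]).mean() / 2.0)
    return pd.DataFrame(d, index=gm.accessions, columns=gm.accessions)


def nj_tree(dist: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick) from a distance matrix.

    Taxa are sorted by ID for a deterministic agglomeration order; negative
    branch lengths are clamped to zero.
    """
    ids = sorted(str(i) for i in dist.index)
    dm = DistanceMatrix(dist.loc[ids, ids].to_numpy(dtype=float), ids)
    tree = nj(dm)
    for node in tree.traverse(include_self=True):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
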
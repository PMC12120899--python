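"""Seed-reproducible synthetic hexaploid study generator.

Emulates, at desk scale, the statistical structure of a leaf-transcriptome
diversity panel in an allohexaploid crop: negative-binomial counts over
syntenic homeolog triads with planted sub-genome bias (conserved-balanced,
conserved-dominant, divergent), a core/variable pan-transcriptome split with
a handful of line-restricted genes, planted co-expression modules (one tied
to the trait's genetic values), SNP genotypes with Balding-Nichols
population structure and missingness, gene models placing every SNP in an
exon/UTR/intron, and a two-season replicated flowering-time trait with
additive QTL effects plus a polygenic background.

Each output artifact draws from its own RNG stream spawned from the master
seed, so regenerating one artifact does not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .variants import GenotypeMatrix, write_vcf

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_gene_models",
    "generate_counts",
    "generate_genotypes",
    "generate_trait",
    "generate_go_map",
    "generate_dataset",
    "write_dataset",
]

TRIAD_CATEGORY_OF_SUBGENOME = {0: "A dominant", 1: "B dominant", 2: "C dominant"}
FLOWERING_GO = "GO:0009908"


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Counts of genes/triads/SNPs are scaled down from the real survey (which
    needs the deposited reads); structural settings (48 accessions, 3
    replicates, 2 seasons, 4 population clusters, triad category mix, SNP
    region mix) follow the study design.
    """

    n_accessions: int = 48
    n_replicates: int = 3
    n_genes: int = 3000
    n_triads: int = 400
    dominance_mix: dict[str, float] = field(
        default_factory=lambda: {
            "conserved_balanced": 0.17,
            "conserved_dominant": 0.20,
            "divergent": 0.63,
        }
    )
    nb_dispersion: float = 0.05
    n_snps: int = 2000
    n_clusters: int = 4
    fst: float = 0.1
    missing_rate: float = 0.02
    n_qtl: int = 1
    qtl_effects: tuple[float, ...] = (4.0,)  # days per alt allele
    heritability: float = 0.8
    replicate_sd: float | None = None  # overrides heritability calibration
    n_years: int = 2
    n_chromosomes: int = 6  # two per sub-genome
    n_variable_genes: int = 30  # line-restricted (<=10 accessions) genes
    variable_fraction: float = 0.15  # genes absent from a random accession subset
    n_modules: int = 5
    module_size: int = 40
    polygenic_sd: float = 1.5  # days
    dominant_fold: float = 8.0
    accession_noise_sd: float = 0.25  # lognormal sd of accession-level bias
    zero_noise: bool = False  # counts equal their means exactly (truth recovery)
    trait_mean: float = 50.0  # days to 50% flowering
    year_offsets: tuple[float, ...] = (0.0, 2.5)
    region_mix: tuple[float, float, float] = (0.868, 0.105, 0.027)  # exon, UTR, intron
    seed: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.dominance_mix.values()) - 1.0) > 1e-9:
            raise ValueError("dominance_mix proportions must sum to 1")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("negative-binomial dispersion must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        if self.n_qtl != len(self.qtl_effects):
            raise ValueError("qtl_effects must have one entry per QTL")
        if self.heritability == 1.0 and self.replicate_sd:
            raise ValueError("heritability 1 is incompatible with replicate noise")
        for name in ("n_accessions", "n_replicates", "n_genes", "n_triads",
                     "n_snps", "n_clusters", "n_years", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if 3 * self.n_triads + self.n_variable_genes + self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_genes too small for the requested triads/modules/variable genes")

    @property
    def accessions(self) -> list[str]:
        return [f"ACC{i + 1:02d}" for i in range(self.n_accessions)]

    def rng_streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(5)
        names = ("gene_models", "genotypes", "traits", "counts", "go")
        return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


@dataclass
class SyntheticDataset:
    config: SimConfig
    counts: ExpressionMatrix
    triads: pd.DataFrame  # triad_id, gene_a, gene_b, gene_c, true_category
    genotypes: GenotypeMatrix
    gene_models: pd.DataFrame  # chrom, start, end, feature, gene_id, strand
    traits: pd.DataFrame  # accession, year, replicate, value
    go_map: pd.DataFrame  # gene_id, go_id
    truth: dict


def generate_gene_models(cfg: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out gene models and the triad table.

    Sub-genomes A/B/C each own a third of the chromosomes; triad member X is
    placed on a sub-genome-X chromosome.  Every gene has the same five-part
    structure (UTR5, CDS, intron, CDS, UTR3) at a random start position.

    Returns (feature table, triad table).
    """
    per_sub = cfg.n_chromosomes // 3
    if per_sub == 0:
        raise ValueError("need at least 3 chromosomes (one per sub-genome)")
    chroms = [f"Chr{i + 1}" for i in range(cfg.n_chromosomes)]
    sub_chroms = {s: chroms[s * per_sub:(s + 1) * per_sub] for s in range(3)}

    gene_sub: list[int] = []
    for t in range(cfg.n_triads):
        gene_sub.extend([0, 1, 2])
    for g in range(cfg.n_genes - 3 * cfg.n_triads):
        gene_sub.append(int(rng.integers(0, 3)))

    # assign genes to chromosomes round-robin within sub-genome, spaced 3 kb
    cursor = {c: 1000 for c in chroms}
    counter = {s: 0 for s in range(3)}
    rows = []
    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]
    spans = {}
    for gid, s in zip(gene_ids, gene_sub):
        cs = sub_chroms[s]
        chrom = cs[counter[s] % len(cs)]
        counter[s] += 1
        start = cursor[chrom] + int(rng.integers(0, 500))
        utr5 = (start, start + 149)
        cds1 = (start + 150, start + 449)
        intr = (start + 450, start + 649)
        cds2 = (start + 650, start + 1099)
        utr3 = (start + 1100, start + 1249)
        end = utr3[1]
        cursor[chrom] = end + 3000
        strand = "+" if rng.random() < 0.5 else "-"
        spans[gid] = (chrom, start, end, strand)
        rows.append((chrom, start, end, "gene", gid, strand))
        rows.append((chrom, start, end, "mRNA", gid, strand))
        rows.append((chrom, utr5[0], utr5[1], "five_prime_UTR", gid, strand))
        rows.append((chrom, utr5[0], cds1[1], "exon", gid, strand))
        rows.append((chrom, cds1[0], cds1[1], "CDS", gid, strand))
        rows.append((chrom, cds2[0], utr3[1], "exon", gid, strand))
        rows.append((chrom, cds2[0], cds2[1], "CDS", gid, strand))
        rows.append((chrom, utr3[0], utr3[1], "three_prime_UTR", gid, strand))
    features = pd.DataFrame(rows, columns=["chrom", "start", "end", "feature", "gene_id", "strand"])
    triads = pd.DataFrame(
        {
            "triad_id": [f"triad{t + 1:04d}" for t in range(cfg.n_triads)],
            "gene_a": gene_ids[0:3 * cfg.n_triads:3],
            "gene_b": gene_ids[1:3 * cfg.n_triads:3],
            "gene_c": gene_ids[2:3 * cfg.n_triads:3],
        }
    )
    return features, triads


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 (alpha=0 -> Poisson)."""
    mean = np.maximum(mean, 0.0)
    if alpha == 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    p = np.clip(p, 1e-12, 1.0)
    return rng.negative_binomial(size, p)


def generate_counts(
    cfg: SimConfig,
    triads: pd.DataFrame,
    gene_ids: list[str],
    rng: np.random.Generator,
    trait_factor: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Raw counts with planted triad bias, modules and variable genes.

    Parameters
    ----------
    trait_factor
        Optional per-accession latent factor driving the first planted
        module (the dataset generator passes standardized trait genetic
        values here so the module is trait-correlated); random N(0,1) when
        omitted.

    Returns the raw ExpressionMatrix, the triad table with true categories
    appended, and a truth dict (module gene sets, variable genes).
    """
    n_acc, n_rep = cfg.n_accessions, cfg.n_replicates
    accs = cfg.accessions
    n_genes = len(gene_ids)
    if trait_factor is None:
        trait_factor = rng.standard_normal(n_acc)
    tf = np.asarray(trait_factor, dtype=float)
    tf = (tf - tf.mean()) / (tf.std() if tf.std() > 0 else 1.0)

    # base per-gene expression level (lognormal across genes)
    base = np.exp(rng.normal(np.log(40.0), 1.0, size=n_genes))
    mean = np.tile(base[:, None], (1, n_acc)).astype(float)

    # --- triad categories ---
    cats = list(cfg.dominance_mix)
    probs = np.array([cfg.dominance_mix[c] for c in cats])
    triad_cat = rng.choice(len(cats), size=cfg.n_triads, p=probs)
    triad_true = []
    gi = {g: i for i, g in enumerate(gene_ids)}
    for t in range(cfg.n_triads):
        idx = [gi[triads.iloc[t]["gene_a"]], gi[triads.iloc[t]["gene_b"]], gi[triads.iloc[t]["gene_c"]]]
        kind = cats[triad_cat[t]]
        mu_t = max(base[idx[0]], 15.0)  # keep triads comfortably above eligibility
        if kind == "conserved_balanced":
            for j in idx:
                mean[j, :] = mu_t
            triad_true.append("Balanced")
        elif kind == "conserved_dominant":
            # third sub-genome dominates most often, as in the reference genome
            dom = int(rng.choice(3, p=[0.25, 0.25, 0.5]))
            for k, j in enumerate(idx):
                mean[j, :] = mu_t * (cfg.dominant_fold if k == dom else 1.0)
            triad_true.append(TRIAD_CATEGORY_OF_SUBGENOME[dom])
        else:  # divergent: dominant homeolog rotates across three accession blocks
            shift = int(rng.integers(0, 3))
            for a in range(n_acc):
                dom = (a * 3 // n_acc + shift) % 3
                for k, j in enumerate(idx):
                    mean[j, a] = mu_t * (cfg.dominant_fold if k == dom else 1.0)
            triad_true.append("divergent")

    # --- planted co-expression modules among non-triad genes ---
    pool = list(range(3 * cfg.n_triads, n_genes))
    chosen = rng.choice(pool, size=cfg.n_modules * cfg.module_size + cfg.n_variable_genes, replace=False)
    module_sets: dict[str, list[str]] = {}
    pos = 0
    for m in range(cfg.n_modules):
        members = chosen[pos:pos + cfg.module_size]
        pos += cfg.module_size
        factor = tf if m == 0 else rng.standard_normal(n_acc)
        loadings = 0.6 + 0.4 * rng.random(cfg.module_size)
        mean[members, :] *= np.exp(loadings[:, None] * factor[None, :] * 0.5)
        module_sets[f"module_{m + 1}"] = [gene_ids[j] for j in members]

    # --- line-restricted (pan-transcriptome variable) genes ---
    var_idx = chosen[pos:pos + cfg.n_variable_genes]
    variable_truth: dict[str, list[str]] = {}
    for j in var_idx:
        k = int(rng.integers(1, 11))
        carriers = rng.choice(n_acc, size=k, replace=False)
        row = np.zeros(n_acc)
        row[carriers] = 200.0 * np.exp(rng.normal(0, 0.2, size=k))
        mean[j, :] = row
        variable_truth[gene_ids[j]] = [accs[a] for a in sorted(carriers)]

    # --- broader core/variable split on remaining singleton genes ---
    rest = np.array(sorted(set(pool) - set(chosen.tolist())))
    n_var = int(cfg.variable_fraction * len(rest))
    if n_var:
        for j in rng.choice(rest, size=n_var, replace=False):
            absent = rng.choice(n_acc, size=int(rng.integers(1, n_acc - 10)), replace=False)
            mean[j, absent] = 0.0

    # accession-level biological noise
    if not cfg.zero_noise and cfg.accession_noise_sd > 0:
        mean *= np.exp(rng.normal(0.0, cfg.accession_noise_sd, size=(n_genes, n_acc)))

    # --- replicate counts with per-sample depth factors ---
    samples = [f"{a}_{r + 1}" for a in accs for r in range(n_rep)]
    if cfg.zero_noise:
        depth = np.ones(n_acc * n_rep)
        counts = np.repeat(mean, n_rep, axis=1)
    else:
        depth = np.exp(rng.normal(0.0, 0.15, size=n_acc * n_rep))
        sample_mean = np.repeat(mean, n_rep, axis=1) * depth[None, :]
        counts = _nb_sample(rng, sample_mean, cfg.nb_dispersion)
    values = pd.DataFrame(counts, index=gene_ids, columns=samples, dtype=float)
    meta = pd.DataFrame(
        {"accession": [s.rsplit("_", 1)[0] for s in samples],
         "replicate": [int(s.rsplit("_", 1)[1]) for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    em = ExpressionMatrix(values=values, sample_meta=meta, state="raw")
    triads_out = triads.copy()
    triads_out["true_category"] = triad_true
    truth = {"module_genes": module_sets, "variable_genes": variable_truth}
    return em, triads_out, truth


def generate_genotypes(
    cfg: SimConfig,
    gene_models: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols genotypes placed inside gene models.

    Per SNP a global allele frequency is drawn, cluster frequencies are drawn
    Beta around it with divergence ``fst``, and diploid genotypes are sampled
    in Hardy-Weinberg proportions within each cluster.  SNP positions land in
    exons, UTRs or introns according to ``region_mix``.

    Returns the genotype matrix plus the per-accession true cluster labels.
    """
    if cfg.n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    n_acc = cfg.n_accessions
    clusters = np.arange(n_acc) * cfg.n_clusters // n_acc

    genes = gene_models[gene_models["feature"] == "gene"]
    cds = gene_models[gene_models["feature"] == "CDS"]
    utr = gene_models[gene_models["feature"].isin(["five_prime_UTR", "three_prime_UTR"])]
    intron_rows = []
    # introns = gene span minus exons; with the fixed layout this is the gap
    for gid, grp in gene_models[gene_models["feature"] == "exon"].groupby("gene_id", sort=False):
        g = grp.sort_values("start")
        if len(g) == 2:
            intron_rows.append((g.iloc[0]["chrom"], g.iloc[0]["end"] + 1, g.iloc[1]["start"] - 1))
    introns = pd.DataFrame(intron_rows, columns=["chrom", "start", "end"])

    p_exon, p_utr, p_intron = cfg.region_mix
    seen: set[tuple[str, int]] = set()
    positions: list[tuple[str, int, str, str]] = []
    guard = 0
    while len(positions) < cfg.n_snps and guard < 50 * cfg.n_snps:
        guard += 1
        u = rng.random()
        if u < p_exon:
            pool = cds
        elif u < p_exon + p_utr:
            pool = utr
        else:
            pool = introns
        row = pool.iloc[int(rng.integers(0, len(pool)))]
        pos = int(rng.integers(int(row["start"]), int(row["end"]) + 1))
        key = (str(row["chrom"]), pos)
        if key in seen:
            continue
        seen.add(key)
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        positions.append((key[0], pos, str(ref), str(alt)))
    positions.sort(key=lambda r: (r[0], r[1]))

    freqs_global = rng.uniform(0.1, 0.9, size=len(positions))
    dos = np.empty((len(positions), n_acc))
    for i, f in enumerate(freqs_global):
        if cfg.fst > 0:
            a, b = f * (1 - cfg.fst) / cfg.fst, (1 - f) * (1 - cfg.fst) / cfg.fst
            fc = rng.beta(a, b, size=cfg.n_clusters)
        else:
            fc = np.full(cfg.n_clusters, f)
        dos[i] = rng.binomial(2, fc[clusters])
    if cfg.missing_rate > 0:
        miss = rng.random(dos.shape) < cfg.missing_rate
        dos[miss] = np.nan

    ids = [f"snp_{c}_{p}" for c, p, _, _ in positions]
    dosage = pd.DataFrame(dos, index=ids, columns=cfg.accessions)
    snp_map = pd.DataFrame(
        [(c, p, r, a) for c, p, r, a in positions],
        index=ids, columns=["chrom", "pos", "ref", "alt"],
    )
    return GenotypeMatrix(dosage=dosage, snp_map=snp_map), clusters


def generate_trait(
    cfg: SimConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Two-season replicated trait with planted QTL effects.

    Accession genetic value = sum(dosage x effect) + polygenic draw from the
    realized kinship; replicate noise is scaled so the broad-sense
    heritability of a single plot measurement matches ``cfg.heritability``
    (unless ``replicate_sd`` overrides it).
    """
    from .association import kinship  # deferred: association imports variants

    n_acc = cfg.n_accessions
    accs = cfg.accessions
    dos = genotypes.dosage.to_numpy(dtype=float)
    freq = np.nanmean(dos, axis=1) / 2.0
    filled = np.where(np.isnan(dos), 2 * freq[:, None], dos)

    # Plant QTLs on common, fully genotyped SNPs that segregate *within* the
    # population clusters: a causal variant confounded with structure is
    # invisible to a structure-corrected association model by construction.
    maf = np.minimum(freq, 1 - freq)
    complete = ~np.isnan(dos).any(axis=1)
    clusters = np.arange(n_acc) * cfg.n_clusters // n_acc
    spread = np.zeros(dos.shape[0])
    for c in range(cfg.n_clusters):
        spread = np.maximum(spread, np.abs(np.nanmean(dos[:, clusters == c], axis=1) / 2 - freq))
    candidates = np.flatnonzero((maf >= 0.25) & complete & (spread <= 0.12))
    if len(candidates) < cfg.n_qtl:
        candidates = np.flatnonzero((maf >= 0.2) & complete)
    if len(candidates) < cfg.n_qtl:
        candidates = np.flatnonzero(maf >= 0.1)
    qtl_idx = rng.choice(candidates, size=cfg.n_qtl, replace=False)
    qtl_ids = [str(genotypes.dosage.index[i]) for i in qtl_idx]

    g = np.zeros(n_acc)
    for i, eff in zip(qtl_idx, cfg.qtl_effects):
        g += filled[i] * eff
    K = kinship(genotypes).to_numpy()
    L = np.linalg.cholesky(K + 1e-6 * np.eye(n_acc))
    u = L @ rng.standard_normal(n_acc)
    u = u / u.std() * cfg.polygenic_sd if u.std() > 0 else u
    g = g + u

    if cfg.heritability == 0.0:
        g = np.zeros(n_acc)
        sigma_e = cfg.replicate_sd if cfg.replicate_sd is not None else 2.0
    elif cfg.replicate_sd is not None:
        sigma_e = cfg.replicate_sd
    else:
        var_g = g.var()
        sigma_e = float(np.sqrt(var_g * (1 - cfg.heritability) / cfg.heritability))

    offsets = list(cfg.year_offsets)[:cfg.n_years]
    while len(offsets) < cfg.n_years:
        offsets.append(offsets[-1] + 2.0)
    rows = []
    for yi, year in enumerate(range(2012, 2012 + cfg.n_years)):
        for ai, acc in enumerate(accs):
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0
                rows.append((acc, year, rep, cfg.trait_mean + offsets[yi] + g[ai] + noise))
    traits = pd.DataFrame(rows, columns=["accession", "year", "replicate", "value"])
    truth = {
        "qtl_snps": qtl_ids,
        "qtl_effects": list(cfg.qtl_effects),
        "genetic_values": {a: float(v) for a, v in zip(accs, g)},
        "replicate_sd": float(sigma_e),
    }
    return traits, truth


def generate_go_map(
    cfg: SimConfig,
    gene_ids: list[str],
    module_sets: dict[str, list[str]],
    rng: np.random.Generator,
    n_terms: int = 40,
) -> pd.DataFrame:
    """Random gene->GO assignments with one term enriched in the trait module."""
    terms = [f"GO:{7000000 + i}" for i in range(n_terms)]
    rows = []
    for g in gene_ids:
        for _ in range(int(rng.integers(0, 3))):
            rows.append((g, terms[int(rng.integers(0, n_terms))]))
    trait_module = module_sets.get("module_1", [])
    for g in trait_module:
        if rng.random() < 0.8:
            rows.append((g, FLOWERING_GO))
    background = [g for g in gene_ids if g not in set(trait_module)]
    for g in background:
        if rng.random() < 0.02:
            rows.append((g, FLOWERING_GO))
    return pd.DataFrame(sorted(set(rows)), columns=["gene_id", "go_id"])


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full linked study (counts, triads, VCF-ready genotypes,
    gene models, traits, GO map, truth)."""
    streams = cfg.rng_streams()
    gene_models, triads = generate_gene_models(cfg, streams["gene_models"])
    gene_ids = list(gene_models.loc[gene_models["feature"] == "gene", "gene_id"])
    genotypes, clusters = generate_genotypes(cfg, gene_models, streams["genotypes"])
    traits, trait_truth = generate_trait(cfg, genotypes, streams["traits"])
    genetic = np.array([trait_truth["genetic_values"][a] for a in cfg.accessions])
    counts, triads, count_truth = generate_counts(
        cfg, triads, gene_ids, streams["counts"], trait_factor=-genetic
    )
    go_map = generate_go_map(cfg, gene_ids, count_truth["module_genes"], streams["go"])
    truth = {
        "clusters": {a: int(c) for a, c in zip(cfg.accessions, clusters)},
        "triad_categories": dict(zip(triads["triad_id"], triads["true_category"])),
        **count_truth,
        **trait_truth,
    }
    return SyntheticDataset(
        config=cfg, counts=counts, triads=triads, genotypes=genotypes,
        gene_models=gene_models, traits=traits, go_map=go_map, truth=truth,
    )


# ---------------------------------------------------------------------------
# writers (all plain text)

def write_gff3(gene_models: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        counters: dict[str, int] = {}
        for r in gene_models.itertuples(index=False):
            if r.feature == "gene":
                attrs = f"ID={r.gene_id}"
            elif r.feature == "mRNA":
                attrs = f"ID={r.gene_id}.1;Parent={r.gene_id}"
            else:
                counters[r.gene_id] = counters.get(r.gene_id, 0) + 1
                attrs = f"ID={r.gene_id}.1.{counters[r.gene_id]};Parent={r.gene_id}.1"
            fh.write(
                f"{r.chrom}\tsim\t{r.feature}\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as TSV/VCF/GFF3/JSON; returns the path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "triads": out / "triads.tsv",
        "vcf": out / "genotypes.vcf",
        "gff3": out / "gene_models.gff3",
        "traits": out / "traits.tsv",
        "go_map": out / "go_map.tsv",
        "truth": out / "truth.json",
    }
    ds.counts.values.rename_axis("gene_id").to_csv(paths["counts"], sep="\t", float_format="%.10g")
    ds.triads.to_csv(paths["triads"], sep="\t", index=False)
    write_vcf(ds.genotypes, paths["vcf"])
    write_gff3(ds.gene_models, paths["gff3"])
    ds.traits.to_csv(paths["traits"], sep="\t", index=False, float_format="%.10g")
    ds.go_map.to_csv(paths["go_map"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1, sort_keys=True)
    return paths
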
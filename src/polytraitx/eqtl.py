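"""All-pairs SNP x expression scan with Bonferroni control and cis/trans labels.

Each (SNP, gene) pair is tested with a simple linear regression of
accession-level expression on additive dosage (0/1/2); missing dosages are
dropped pairwise.  Family-wise control uses the Bonferroni threshold
alpha / (n_snps x n_genes), and significant pairs are labeled cis when the
SNP lies within a physical window of the gene span (strictly < 3 kb by
default), trans otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variants import GenotypeMatrix

__all__ = [
    "bonferroni_threshold",
    "eqtl_scan",
    "classify_cis_trans",
    "annotate_cis_trans",
    "module_eqtls",
]


def bonferroni_threshold(n_snps: int, n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise p-value threshold alpha / (n_snps * n_genes)."""
    if n_snps < 1 or n_genes < 1:
        raise ValueError("test counts must be >= 1")
    return alpha / (n_snps * n_genes)


def eqtl_scan(
    gm: GenotypeMatrix,
    expr: pd.DataFrame,
    alpha: float = 0.05,
    keep: str = "significant",
) -> tuple[pd.DataFrame, float]:
    """Regress every gene on every SNP dosage.

    Parameters
    ----------
    gm
        Genotypes; columns must cover ``expr``'s columns (accessions).
    expr
        genes x accessions accession-level expression.
    keep
        "significant" returns only pairs below the Bonferroni threshold;
        "all" returns every testable pair (use for small scans only).

    Returns the hit table (snp_id, gene_id, slope, t, p, significant) and the
    Bonferroni threshold used.  Pairs where the dosage has no variance after
    missing-drop are skipped and counted in ``scan.attrs['skipped']``.
    """
    acc = list(expr.columns)
    dos = gm.dosage[acc].to_numpy(dtype=float)
    y = expr.to_numpy(dtype=float)
    genes = list(expr.index)
    thr = bonferroni_threshold(gm.n_snps, len(genes), alpha)
    rows = []
    skipped = 0
    for i, snp in enumerate(gm.dosage.index):
        x = dos[i]
        mask = ~np.isnan(x)
        n = int(mask.sum())
        if n < 3:
            skipped += len(genes)
            continue
        xm = x[mask]
        xc = xm - xm.mean()
        sxx = float(xc @ xc)
        if sxx == 0:
            skipped += len(genes)
            continue
        ym = y[:, mask]
        yc = ym - ym.mean(axis=1, keepdims=True)
        slope = yc @ xc / sxx
        rss = (yc * yc).sum(axis=1) - slope**2 * sxx
        df = n - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / df / sxx)
            t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isfinite(t), p, 0.0)
        if keep == "all":
            sel = np.arange(len(genes))
        else:
            sel = np.flatnonzero(p < thr)
        for j in sel:
            rows.append((snp, genes[j], float(slope[j]), float(t[j]), float(p[j]), bool(p[j] < thr)))
    scan = pd.DataFrame(rows, columns=["snp_id", "gene_id", "slope", "t", "p", "significant"])
    scan.attrs["skipped"] = skipped
    return scan, thr


def classify_cis_trans(
    snp_chrom: str,
    snp_pos: int,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    window: int = 3000,
) -> tuple[str, float]:
    """cis/trans label and SNP-gene distance.

    Distance is 0 inside the gene span, else the bp gap to the nearest span
    edge; cis iff distance < window (strict).  Different chromosomes are
    trans at infinite distance.
    """
    if snp_chrom != gene_chrom:
        return "trans", float("inf")
    if gene_start <= snp_pos <= gene_end:
        dist = 0.0
    elif snp_pos < gene_start:
        dist = float(gene_start - snp_pos)
    else:
        dist = float(snp_pos - gene_end)
    return ("cis" if dist < window else "trans"), dist


def annotate_cis_trans(
    hits: pd.DataFrame,
    snp_map: pd.DataFrame,
    gene_spans: pd.DataFrame,
    window: int = 3000,
) -> pd.DataFrame:
    """Add cis_trans and distance columns to a hit table.

    ``gene_spans`` is indexed by gene_id with columns chrom, start, end.
    """
    labels, dists = [], []
    for rec in hits.itertuples(index=False):
        sm = snp_map.loc[rec.snp_id]
        gs = gene_spans.loc[rec.gene_id]
        lab, d = classify_cis_trans(
            str(sm["chrom"]), int(sm["pos"]), str(gs["chrom"]),
            int(gs["start"]), int(gs["end"]), window,
        )
        labels.append(lab)
        dists.append(d)
    out = hits.copy()
    out["cis_trans"] = labels
    out["distance"] = dists
    return out


def module_eqtls(
    hits: pd.DataFrame,
    module_genes: set[str],
    min_genes: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict hits to a module and find SNPs hitting several module genes.

    Returns the restricted hit table and, for SNPs significantly associated
    with at least ``min_genes`` distinct module genes, the per-SNP gene count.
    """
    if not module_genes:
        return hits.iloc[0:0], pd.Series(dtype=int)
    sub = hits[hits["gene_id"].isin(module_genes) & hits["significant"]]
    per_snp = sub.groupby("snp_id")["gene_id"].nunique().sort_values(ascending=False)
    return sub.reset_index(drop=True), per_snp[per_snp >= min_genes]
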
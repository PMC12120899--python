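"""Trait BLUPs, kinship, and mixed-linear-model association.

The replicated multi-year trait records are condensed to per-accession best
linear unbiased predictors (BLUPs) under the model

    value = mu + year (fixed) + accession (random) + error,

with variance components estimated by REML (profile likelihood over the
variance ratio).  Association then fits, per SNP,

    y = W alpha + x beta + u + e,    u ~ N(0, sigma_g^2 K),

where K is the centered genomic relationship matrix and W holds an
intercept plus genotype principal components.  K is eigendecomposed once;
for each SNP the restricted likelihood is maximized over the variance ratio
on the rotated data and beta is tested with a Wald t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variants import GenotypeMatrix

__all__ = [
    "TraitBlup",
    "HaplotypeGroup",
    "compute_blup",
    "kinship",
    "genotype_pcs",
    "lmm_association",
    "significant_snps",
    "haplotype_groups",
    "trait_correlations",
]

P_FLOOR = 1e-300  # underflow guard for reported p-values


@dataclass
class TraitBlup:
    blups: pd.Series  # accession -> BLUP (trait units)
    sigma2_g: float
    sigma2_e: float
    fixed_effects: pd.Series = field(repr=False)


@dataclass(frozen=True)
class HaplotypeGroup:
    group_id: int
    alleles: tuple[int, ...]  # dosages at the significant SNPs
    accessions: tuple[str, ...]
    trait_mean: float
    trait_median: float
    trait_q1: float
    trait_q3: float


def _reml_profile(y: np.ndarray, X: np.ndarray, eigvals: np.ndarray, U: np.ndarray):
    """Profile REML over the variance ratio lambda = sigma_random / sigma_error.

    ``eigvals``/``U`` eigendecompose the random-effect covariance structure
    (ZZ' or K).  Returns (lambda_hat, sigma2_e, beta, XtWiX_inv, resid_rotated).
    """
    n, p = X.shape
    ys = U.T @ y
    Xs = U.T @ X

    def neg2_reml(log_lam: float):
        lam = np.exp(log_lam)
        w = 1.0 + lam * eigvals
        Xw = Xs / w[:, None]
        XtX = Xs.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ ys)
        r = ys - Xs @ beta
        rss = float(r @ (r / w))
        sign, logdet = np.linalg.slogdet(XtX)
        return (n - p) * np.log(rss / (n - p)) + np.log(w).sum() + logdet

    res = optimize.minimize_scalar(neg2_reml, bounds=(-14.0, 14.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    w = 1.0 + lam * eigvals
    Xw = Xs / w[:, None]
    XtX = Xs.T @ Xw
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ ys)
    r = ys - Xs @ beta
    sigma2_e = float(r @ (r / w)) / (n - p)
    return lam, sigma2_e, beta, XtX_inv, r, w


def compute_blup(records: pd.DataFrame) -> TraitBlup:
    """REML BLUPs from replicated trait records.

    ``records`` has columns ``accession``, ``year``, ``replicate``, ``value``.
    With a single year the year term is dropped.  The reported BLUP is the
    overall mean (intercept plus average year effect) plus the shrunken
    accession effect.
    """
    accs = sorted(records["accession"].unique())
    if len(accs) < 2:
        raise ValueError("need at least 2 accessions")
    years = sorted(records["year"].unique())
    y = records["value"].to_numpy(dtype=float)
    n = len(y)
    acc_idx = records["accession"].map({a: i for i, a in enumerate(accs)}).to_numpy()
    Z = np.zeros((n, len(accs)))
    Z[np.arange(n), acc_idx] = 1.0
    X = [np.ones(n)]
    names = ["intercept"]
    for yr in years[1:]:
        X.append((records["year"] == yr).to_numpy(dtype=float))
        names.append(f"year_{yr}")
    X = np.column_stack(X)

    M = Z @ Z.T
    eigvals, U = np.linalg.eigh(M)
    lam, s2e, beta, _, r, w = _reml_profile(y, X, eigvals, U)
    s2g = lam * s2e
    # u_hat = lambda * Z' (I + lambda M)^(-1) (y - X beta), on rotated residuals
    vinv_r = U @ (r / w)
    u_hat = lam * (Z.T @ vinv_r)
    # overall mean: intercept + average year offset
    year_cols = [i for i, nm in enumerate(names) if nm.startswith("year_")]
    mu = float(beta[0] + sum(beta[i] for i in year_cols) / len(years))
    blups = pd.Series(mu + u_hat, index=accs, name="blup")
    fixed = pd.Series(beta, index=names)
    return TraitBlup(blups=blups, sigma2_g=float(s2g), sigma2_e=float(s2e), fixed_effects=fixed)


def kinship(gm: GenotypeMatrix) -> pd.DataFrame:
    """Centered genomic relationship matrix K = (1/p) sum_s (x_s - 2 f_s)(x_s - 2 f_s)'.

    Missing dosages are mean-imputed per SNP; monomorphic SNPs are skipped.
    """
    dos = gm.dosage.to_numpy(dtype=float)
    freq = np.nanmean(dos, axis=1) / 2.0
    centered = dos - 2.0 * freq[:, None]
    centered = np.where(np.isnan(centered), 0.0, centered)  # mean imputation
    poly = np.nanstd(dos, axis=1) > 0
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic SNPs")
    c = centered[poly]
    K = c.T @ c / poly.sum()
    return pd.DataFrame(K, index=gm.accessions, columns=gm.accessions)


def genotype_pcs(gm: GenotypeMatrix, k: int = 3) -> pd.DataFrame:
    """Top-k principal components of the kinship matrix, scaled by sqrt(eigenvalue).

    Component signs are fixed so each PC's largest-magnitude loading is
    positive (determinism).
    """
    K = kinship(gm)
    if k >= K.shape[0]:
        raise ValueError("k must be smaller than the number of accessions")
    vals, vecs = np.linalg.eigh(K.to_numpy())
    order = np.argsort(vals)[::-1][:k]
    cols = {}
    for j, idx in enumerate(order):
        v = vecs[:, idx] * np.sqrt(max(vals[idx], 0.0))
        if v[np.abs(v).argmax()] < 0:
            v = -v
        cols[f"PC{j + 1}"] = v
    return pd.DataFrame(cols, index=K.index)


def lmm_association(
    gm: GenotypeMatrix,
    phenotype: pd.Series,
    K: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-SNP mixed-model Wald tests.

    Missing dosages are mean-imputed per SNP (the kinship convention);
    zero-variance SNPs are skipped.  Returns a frame indexed by snp_id with
    beta, se, p.
    """
    acc = list(phenotype.index)
    y = phenotype.to_numpy(dtype=float)
    Km = K.loc[acc, acc].to_numpy(dtype=float)
    eigvals, U = np.linalg.eigh((Km + Km.T) / 2.0)
    if eigvals.min() < -1e-6 * max(1.0, abs(eigvals.max())):
        raise ValueError("kinship matrix is not positive semi-definite")
    eigvals = np.clip(eigvals, 0.0, None)
    W = [np.ones(len(acc))]
    if covariates is not None:
        W.extend(covariates.loc[acc].to_numpy(dtype=float).T)
    W = np.column_stack(W)

    dos = gm.dosage[acc].to_numpy(dtype=float)
    freq = np.nanmean(dos, axis=1)
    dos = np.where(np.isnan(dos), freq[:, None], dos)

    rows = []
    n = len(acc)
    for i, snp in enumerate(gm.dosage.index):
        x = dos[i]
        if np.std(x) == 0:
            continue
        X = np.column_stack([W, x])
        p_fix = X.shape[1]
        lam, s2e, beta, XtX_inv, _, _ = _reml_profile(y, X, eigvals, U)
        b = float(beta[-1])
        se = float(np.sqrt(s2e * XtX_inv[-1, -1]))
        tstat = b / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tstat), n - p_fix)
        rows.append((snp, b, se, max(float(p), P_FLOOR)))
    return pd.DataFrame(rows, columns=["snp_id", "beta", "se", "p"]).set_index("snp_id")


def significant_snps(results: pd.DataFrame, threshold: float = 5e-7) -> list[str]:
    """SNPs with p strictly below the genome-wide threshold."""
    return [str(s) for s in results.index[results["p"] < threshold]]


def haplotype_groups(
    gm: GenotypeMatrix,
    snps: list[str],
    trait: pd.Series,
) -> tuple[list[HaplotypeGroup], float, list[str]]:
    """Group accessions by their multilocus dosage string at significant SNPs.

    Returns the groups (with per-group trait summaries), a one-way ANOVA
    p-value across groups with >= 2 groups of >= 1 member (NaN when
    undefined), and the accessions excluded for missing calls.
    """
    if not snps:
        raise ValueError("need at least one significant SNP")
    sub = gm.dosage.loc[snps]
    complete, incomplete = [], []
    keys: dict[tuple[int, ...], list[str]] = {}
    for a in gm.accessions:
        col = sub[a].to_numpy(dtype=float)
        if np.isnan(col).any():
            incomplete.append(a)
            continue
        complete.append(a)
        keys.setdefault(tuple(int(v) for v in col), []).append(a)
    if not complete:
        raise ValueError("all accessions have missing calls at the significant SNPs")
    groups = []
    ordered = sorted(keys.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    for gid, (alleles, members) in enumerate(ordered, start=1):
        vals = trait.reindex(members).dropna()
        q1, med, q3 = np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
        groups.append(
            HaplotypeGroup(
                gid, alleles, tuple(members),
                float(vals.mean()) if len(vals) else float("nan"),
                float(med), float(q1), float(q3),
            )
        )
    samples = [trait.reindex(g.accessions).dropna().to_numpy() for g in groups]
    samples = [s for s in samples if len(s) > 0]
    if len(samples) >= 2 and sum(len(s) for s in samples) > len(samples):
        anova_p = float(stats.f_oneway(*samples).pvalue)
    else:
        anova_p = float("nan")
    return groups, anova_p, incomplete


def trait_correlations(blups: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p between trait BLUP vectors.

    ``blups`` is accessions x traits.  Constant traits yield NaN entries.
    """
    if blups.shape[0] < 3:
        raise ValueError("need at least 3 accessions")
    traits = list(blups.columns)
    r = pd.DataFrame(np.nan, index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    for i, ta in enumerate(traits):
        for tb in traits[i:]:
            a, b = blups[ta], blups[tb]
            if a.std() == 0 or b.std() == 0:
                continue
            rr, pp = stats.pearsonr(a, b)
            r.loc[ta, tb] = r.loc[tb, ta] = float(rr)
            p.loc[ta, tb] = p.loc[tb, ta] = float(pp)
    return r, p
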
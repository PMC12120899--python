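"""Signed weighted co-expression network with module detection.

Adjacency a_ij = ((1 + r_ij)/2)^beta over Pearson correlations keeps the
sign of co-expression (anti-correlated genes get near-zero weight); the
signed topological overlap matrix (TOM) measures shared-neighborhood
similarity; modules come from average-linkage clustering of 1 - TOM, are
represented by their eigengene (first principal component of the
standardized module submatrix), merged when eigengenes are highly
correlated, and finally related to a trait through module-trait Pearson
correlations, per-gene gene significance (GS) and module membership (MM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NetworkConfig",
    "ModuleResult",
    "MODULE_COLORS",
    "signed_adjacency",
    "signed_tom",
    "cluster_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_stats",
    "gene_stats",
    "go_enrichment",
    "build_network",
]

# Conventional module color sequence, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)

GREY = "grey"


@dataclass
class NetworkConfig:
    power: float = 12.0
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    n_top_genes: int = 15000
    cut_height_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValueError("soft-threshold power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0,1)")


@dataclass
class ModuleResult:
    labels: pd.Series  # gene -> module color ("grey" = unassigned)
    eigengenes: pd.DataFrame = field(repr=False)  # accessions x modules
    module_trait: pd.DataFrame | None = None  # module -> (r, p)
    gene_stats: pd.DataFrame | None = None  # gene -> (GS, MM, module)


def _safe_corr(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows get r = 0 by convention."""
    sd = x.std(axis=1, ddof=0)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance genes: correlations set to 0")
    xs = (x - x.mean(axis=1)[:, None]) / np.where(degenerate, 1.0, sd)[:, None]
    xs[degenerate] = 0.0
    r = xs @ xs.T / x.shape[1]
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def signed_adjacency(expr: pd.DataFrame, power: float = 12.0) -> pd.DataFrame:
    """Signed adjacency ((1 + cor)/2)^power with unit diagonal."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 accessions")
    x = expr.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    a = ((1.0 + _safe_corr(x)) / 2.0) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def signed_tom(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix from a symmetric adjacency in [0,1].

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    n = a.shape[0]
    k = a.sum(axis=1) - np.diag(a)
    # sum over all u of a_iu a_uj includes u=i (a_ii a_ij) and u=j (a_ij a_jj)
    shared = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    numer = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    np.clip(tom, 0.0, 1.0, out=tom)
    if n >= 2:
        tom = (tom + tom.T) / 2.0
        np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def cluster_modules(
    dissimilarity: pd.DataFrame,
    min_module_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    The dendrogram is cut at the ``cut_height_quantile`` quantile of its merge
    heights; clusters smaller than ``min_module_size`` are relabeled "grey".
    Surviving clusters get conventional colors by decreasing size (ties broken
    by smallest member gene ID).
    """
    genes = dissimilarity.index
    n = len(genes)
    if n < min_module_size:
        return pd.Series(GREY, index=genes, name="module")
    d = dissimilarity.to_numpy(dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    heights = link[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    raw = fcluster(link, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    big = [c for c in sizes.index if sizes[c] >= min_module_size]
    big.sort(key=lambda c: (-sizes[c], min(labels.index[labels == c])))
    mapping = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(big)}
    return labels.map(lambda c: mapping.get(c, GREY)).rename("module")


def module_eigengene(expr: pd.DataFrame, genes: list[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Unit-norm per-accession vector, sign-oriented so the mean correlation with
    member genes is positive.  A single-gene module returns its standardized
    (and normalized) profile.
    """
    if len(genes) == 0:
        raise ValueError("empty module")
    x = expr.loc[genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    z = (x - x.mean(axis=1)[:, None]) / np.where(sd == 0, 1.0, sd)[:, None]
    if len(genes) == 1:
        v = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        v = vt[0]
    nrm = np.linalg.norm(v)
    if nrm > 0:
        v = v / nrm
    # orient: average correlation with member gene profiles must be positive
    corr_sum = float((z @ v).sum())
    if corr_sum < 0:
        v = -v
    return pd.Series(v, index=expr.columns, name="eigengene")


def merge_modules(
    expr: pd.DataFrame,
    labels: pd.Series,
    merge_cut_height: float = 0.25,
) -> pd.Series:
    """Iteratively merge module pairs with eigengene dissimilarity < cut.

    Dissimilarity is 1 - cor(eigengene_a, eigengene_b); the closest pair is
    merged first and eigengenes are recomputed each round.  The merged module
    keeps the larger member's color (size ties: earlier color in the
    conventional sequence).
    """
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != GREY]
        if len(mods) < 2:
            return labels
        eg = {m: module_eigengene(expr, list(labels.index[labels == m])) for m in mods}
        best: tuple[float, str, str] | None = None
        for i, ma in enumerate(mods):
            for mb in mods[i + 1:]:
                r = float(np.corrcoef(eg[ma], eg[mb])[0, 1])
                diss = 1.0 - r
                if diss < merge_cut_height and (best is None or diss < best[0]):
                    best = (diss, ma, mb)
        if best is None:
            return labels
        _, ma, mb = best
        na, nb = (labels == ma).sum(), (labels == mb).sum()

        def rank(c: str) -> int:
            return MODULE_COLORS.index(c) if c in MODULE_COLORS else len(MODULE_COLORS)

        keep = ma if (na, -rank(ma)) >= (nb, -rank(mb)) else mb
        drop = mb if keep == ma else ma
        labels[labels == drop] = keep


def module_trait_stats(eigengenes: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson r and two-sided p (t with n-2 df) between each eigengene and a trait."""
    t = trait.reindex(eigengenes.index)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 accessions")
    rows = {}
    for m in eigengenes.columns:
        r, p = stats.pearsonr(eigengenes[m], t)
        rows[m] = (float(r), float(p))
    return pd.DataFrame(rows, index=["r", "p"]).T


def gene_stats(
    expr: pd.DataFrame,
    trait: pd.Series,
    labels: pd.Series,
    eigengenes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene GS = |cor(gene, trait)| and MM = cor(gene, own module eigengene)."""
    t = trait.reindex(expr.columns).to_numpy(dtype=float)
    rows = []
    for gene in expr.index:
        x = expr.loc[gene].to_numpy(dtype=float)
        gs = abs(_pearson_or_zero(x, t))
        mod = labels[gene]
        mm = np.nan
        if mod != GREY and mod in eigengenes.columns:
            mm = _pearson_or_zero(x, eigengenes[mod].to_numpy())
        rows.append((gene, gs, mm, mod))
    return pd.DataFrame(rows, columns=["gene_id", "GS", "MM", "module"]).set_index("gene_id")


def _pearson_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def go_enrichment(
    gene_set: set[str],
    universe: set[str],
    go_map: pd.DataFrame,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric (Fisher exact upper tail) GO-term enrichment.

    ``go_map`` has columns ``gene_id``, ``go_id``.  p-values are
    Benjamini-Hochberg adjusted; a term is significant when adjusted p < fdr.
    """
    if not gene_set or not universe:
        raise ValueError("empty gene set or universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    gm = go_map[go_map["gene_id"].isin(universe)]
    N, n = len(universe), len(gene_set)
    rows = []
    for term, grp in gm.groupby("go_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & gene_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return pd.DataFrame(columns=["go_id", "overlap", "term_size", "p", "p_adj", "significant"])
    df = pd.DataFrame(rows, columns=["go_id", "overlap", "term_size", "p"])
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["p_adj"] < fdr
    return df.sort_values(["p", "go_id"]).reset_index(drop=True)


def build_network(
    expr: pd.DataFrame,
    trait: pd.Series | None = None,
    config: NetworkConfig | None = None,
) -> ModuleResult:
    """Full network pass: adjacency -> TOM -> modules -> merge -> eigengenes (+ trait stats)."""
    cfg = config or NetworkConfig()
    adj = signed_adjacency(expr, cfg.power)
    tom = signed_tom(adj)
    labels = cluster_modules(1.0 - tom, cfg.min_module_size, cfg.cut_height_quantile)
    labels = merge_modules(expr, labels, cfg.merge_cut_height)
    mods = sorted(m for m in labels.unique() if m != GREY)
    eig = pd.DataFrame(
        {m: module_eigengene(expr, list(labels.index[labels == m])) for m in mods},
        index=expr.columns,
    )
    result = ModuleResult(labels=labels, eigengenes=eig)
    if trait is not None and mods:
        result.module_trait = module_trait_stats(eig, trait)
        result.gene_stats = gene_stats(expr, trait, labels, eig)
    return result
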
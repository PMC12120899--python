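"""Pan-transcriptome specificity: the tau index and line-restricted genes.

tau = sum_i (1 - x_i / x_max) / (n - 1) over per-accession mean expression;
0 for a uniformly expressed gene, 1 for single-accession expression.  Genes
with high tau whose expression is concentrated in few accessions flag the
variable fraction of the pan-transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

__all__ = ["TauResult", "tau", "variable_gene_filter", "dominant_genes", "zscore_order"]


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float
    dominance_set_size: int
    passes_filter: bool


def tau(profile: np.ndarray | pd.Series) -> float:
    """Specificity index of an expression profile over accessions.

    Returns NaN for an all-zero profile (undefined).
    """
    x = np.asarray(profile, dtype=float)
    if x.size < 2:
        raise ValueError("tau requires a profile of length >= 2")
    if (x < 0).any():
        raise ValueError("negative expression in tau profile")
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float((1.0 - x / xmax).sum() / (x.size - 1))


def variable_gene_filter(
    means: pd.DataFrame,
    mean_min: float = 10.0,
    max_min: float = 50.0,
    mode: str = "max",
) -> pd.Index:
    """Pre-filter against lowly expressed genes before computing tau.

    mode="mean" keeps genes with across-accession mean strictly above
    ``mean_min``; mode="max" keeps genes with maximum accession mean strictly
    above ``max_min``.
    """
    if mode == "mean":
        keep = means.mean(axis=1) > mean_min
    elif mode == "max":
        keep = means.max(axis=1) > max_min
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return means.index[keep]


def dominance_set_size(profile: np.ndarray, frac_of_max: float = 0.5) -> int:
    """Number of accessions expressing at >= ``frac_of_max`` of the profile max."""
    x = np.asarray(profile, dtype=float)
    if x.max() == 0:
        return 0
    return int((x >= frac_of_max * x.max()).sum())


def dominant_genes(
    means: pd.DataFrame,
    tau_min: float = 0.9,
    max_lines: int = 10,
    frac_of_max: float = 0.5,
) -> list[TauResult]:
    """Genes dominantly expressed in at most ``max_lines`` accessions.

    A gene qualifies when tau > ``tau_min`` (strict) and the number of
    accessions whose mean is at least ``frac_of_max`` of the gene's maximum
    (its dominance set) does not exceed ``max_lines``.  ``means`` should
    already be restricted by :func:`variable_gene_filter`.
    """
    out: list[TauResult] = []
    x = means.to_numpy(dtype=float)
    for i, gene in enumerate(means.index):
        t = tau(x[i])
        if np.isnan(t):
            continue
        dsize = dominance_set_size(x[i], frac_of_max)
        if t > tau_min and dsize <= max_lines:
            out.append(TauResult(str(gene), t, dsize, True))
    return out


def zscore_order(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Z-score genes and order both axes by average-linkage hierarchical clustering.

    Returns the Z-scored matrix plus the row (gene) and column leaf orders of
    Euclidean-distance average-linkage dendrograms.  Zero-variance genes get
    an all-zero Z row.  Rows are pre-sorted by ID so equal inputs yield a
    deterministic leaf order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    m = matrix.sort_index()
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=0)
    z = np.where(sd[:, None] > 0, (x - x.mean(axis=1)[:, None]) / np.where(sd == 0, 1, sd)[:, None], 0.0)
    zf = pd.DataFrame(z, index=m.index, columns=m.columns)
    row_order = [str(m.index[i]) for i in leaves_list(average(pdist(z)))]
    if matrix.shape[1] >= 2:
        col_order = [str(m.columns[j]) for j in leaves_list(average(pdist(z.T)))]
    else:
        col_order = [str(c) for c in m.columns]
    return zf, row_order, col_order
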
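"""Count normalization and expressed-gene calling.

The pipeline starts from a raw gene x sample count matrix (three biological
replicates per accession).  Counts are normalized with median-of-ratios size
factors followed by a variance-stabilizing transform (log2(x+1) by default,
asinh as an alternative); genes are then called "expressed" per accession
either when every replicate exceeds a threshold or when the replicate mean
does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_low_expressed",
    "size_factors",
    "normalize",
    "call_expressed",
    "accession_means",
    "top_variance_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with sample-level metadata.

    Parameters
    ----------
    values
        Non-negative genes x samples matrix (raw counts or normalized values).
    sample_meta
        One row per sample (same order as ``values`` columns) with columns
        ``accession`` and ``replicate``.
    state
        ``"raw"`` or ``"normalized"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(repr=False)
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("sample_meta index must match value columns")
        reps = self.sample_meta.groupby("accession").size()
        if reps.nunique() > 1:
            raise ValueError("replicate count must be constant across accessions")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def accessions(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["accession"]))

    @property
    def n_replicates(self) -> int:
        return int(self.sample_meta.groupby("accession").size().iloc[0])


def filter_low_expressed(counts: ExpressionMatrix, min_mean: float = 1.0) -> ExpressionMatrix:
    """Drop genes whose total raw count is below ``min_mean`` per sample.

    A gene is kept when its row sum is at least ``min_mean * n_samples``.
    """
    if counts.state != "raw":
        raise ValueError("low-expression filter operates on raw counts")
    keep = counts.values.sum(axis=1) >= min_mean * counts.values.shape[1]
    return replace(counts, values=counts.values.loc[keep])


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    The reference profile is the per-gene geometric mean over genes with
    strictly positive counts in every sample; each sample's factor is the
    median of its count/reference ratios over those genes.
    """
    if counts.state != "raw":
        raise ValueError("size factors are computed from raw counts")
    x = counts.values.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene has positive counts in all samples")
    logx = np.log(x[allpos])
    ref = logx.mean(axis=1)  # log geometric mean
    factors = np.exp(np.median(logx - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalize(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    mode: str = "log2p1",
) -> ExpressionMatrix:
    """Scale counts by size factors and apply a monotone variance-stabilizing transform."""
    if factors is None:
        factors = size_factors(counts)
    factors = factors.reindex(counts.values.columns)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("size factors must be positive for every sample")
    scaled = counts.values / factors
    if mode == "log2p1":
        values = np.log2(scaled + 1.0)
    elif mode == "asinh":
        values = np.arcsinh(scaled)
    elif mode == "counts":
        # size-factor-scaled counts, untransformed (the "normalized counts"
        # scale on which the count-level thresholds are stated)
        values = scaled
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ExpressionMatrix(values=values, sample_meta=counts.sample_meta, state="normalized")


def call_expressed(
    norm: ExpressionMatrix,
    min_value: float = 3.0,
    rule: str = "all_reps",
) -> tuple[pd.DataFrame, pd.Series]:
    """Call genes expressed per accession.

    rule="all_reps": expressed iff every replicate value is strictly greater
    than ``min_value``.  rule="mean": expressed iff the replicate mean is
    greater than or equal to ``min_value``.

    Returns
    -------
    expressed
        genes x accessions boolean frame.
    totals
        Per-accession expressed-gene counts, plus summary entries
        ``__all_accessions__`` (core genes expressed everywhere) and
        ``__any_accession__`` (genes expressed in at least one accession).
    """
    if norm.state != "normalized":
        raise ValueError("expressed-gene calling requires normalized values")
    if rule == "all_reps":
        per_acc = (norm.values > min_value).T.groupby(norm.sample_meta["accession"]).all().T
    elif rule == "mean":
        per_acc = accession_means(norm) >= min_value
    else:
        raise ValueError(f"unknown rule {rule!r}")
    per_acc = per_acc.loc[:, norm.accessions]
    totals = per_acc.sum(axis=0)
    totals.loc["__all_accessions__"] = int(per_acc.all(axis=1).sum())
    totals.loc["__any_accession__"] = int(per_acc.any(axis=1).sum())
    return per_acc, totals


def accession_means(norm: ExpressionMatrix) -> pd.DataFrame:
    """Arithmetic replicate mean per accession (genes x accessions).

    Missing replicate values (NaN) are excluded from the mean; an accession
    with no observed replicate for any gene is an error.
    """
    grouped = norm.values.T.groupby(norm.sample_meta["accession"]).mean().T
    if grouped.isna().any().any():
        raise ValueError("accession with zero observed replicates")
    return grouped.loc[:, norm.accessions]


def top_variance_genes(values: pd.DataFrame, k: int = 15000) -> list[str]:
    """IDs of the ``k`` genes with the largest across-sample variance.

    Sorted by descending variance; ties broken by gene ID (lexicographic).
    """
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds the {values.shape[0]} available genes")
    var = values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:k]
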
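"""Sub-genome expression bias for syntenic triads.

Each triad holds one homeolog per sub-genome (A, B, C).  Within an accession
the three accession-mean expression values are reduced to fractions on the
simplex and assigned one of seven bias categories; across accessions each
triad is summarized as conserved, intermediate or divergent depending on how
widely the per-accession categories agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "IDEAL_POINTS",
    "TriadCall",
    "TriadSummary",
    "triad_fractions",
    "triad_eligibility",
    "classify_triad",
    "classify_fractions",
    "summarize_triad",
    "call_triads",
    "summarize_all",
]

# Category order fixes the deterministic tie-break.
CATEGORIES = (
    "Balanced",
    "A dominant",
    "B dominant",
    "C dominant",
    "A suppressed",
    "B suppressed",
    "C suppressed",
)

IDEAL_POINTS = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],  # Balanced
        [1.0, 0.0, 0.0],        # A dominant
        [0.0, 1.0, 0.0],        # B dominant
        [0.0, 0.0, 1.0],        # C dominant
        [0.0, 0.5, 0.5],        # A suppressed
        [0.5, 0.0, 0.5],        # B suppressed
        [0.5, 0.5, 0.0],        # C suppressed
    ]
)


@dataclass(frozen=True)
class TriadCall:
    triad_id: str
    accession: str
    fractions: tuple[float, float, float]
    category: str | None
    eligible: bool


@dataclass(frozen=True)
class TriadSummary:
    triad_id: str
    modal_category: str
    modal_share: float
    conservation_class: str  # conserved | intermediate | divergent


def triad_eligibility(triad_means: np.ndarray, min_mean: float = 10.0) -> bool:
    """Eligible iff at least one homeolog's across-accession mean is >= ``min_mean``.

    ``triad_means`` is a 3 x n_accessions array of accession means (count
    scale) for the A, B, C homeologs.
    """
    m = np.asarray(triad_means, dtype=float)
    return bool(np.nanmean(m, axis=1).max() >= min_mean)


def triad_fractions(values: np.ndarray) -> np.ndarray | None:
    """Relative expression (fA, fB, fC) from the three homeolog values.

    Returns None when the homeologs sum to zero (no call possible).
    """
    v = np.asarray(values, dtype=float)
    s = v.sum()
    if s <= 0:
        return None
    return v / s


def classify_fractions(fracs: np.ndarray, rule: str = "nearest_ideal") -> np.ndarray:
    """Vectorized category assignment for an (n, 3) array of simplex points."""
    f = np.atleast_2d(np.asarray(fracs, dtype=float))
    if rule == "nearest_ideal":
        d2 = ((f[:, None, :] - IDEAL_POINTS[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)  # argmin takes the first minimum: listed-order tie-break
    elif rule == "threshold":
        idx = np.zeros(len(f), dtype=int)
        for i, (fa, fb, fc) in enumerate(f):
            v = np.array([fa, fb, fc])
            if v.max() >= 0.8:
                idx[i] = 1 + int(v.argmax())  # X dominant
            elif v.min() <= 0.2:
                idx[i] = 4 + int(v.argmin())  # X suppressed
            else:
                idx[i] = 0
    else:
        raise ValueError(f"unknown classification rule {rule!r}")
    return np.array([CATEGORIES[i] for i in idx])


def classify_triad(fracs: np.ndarray, rule: str = "nearest_ideal") -> str:
    """Bias category of one (fA, fB, fC) point."""
    return str(classify_fractions(np.asarray(fracs)[None, :], rule=rule)[0])


def summarize_triad(
    triad_id: str,
    categories: list[str],
    divergent_below: float = 0.5,
) -> TriadSummary | None:
    """Cross-accession conservation summary from eligible per-accession calls.

    conserved: all calls identical; divergent: modal share < ``divergent_below``;
    otherwise intermediate.  Returns None when there are no calls.
    """
    cats = [c for c in categories if c is not None]
    if not cats:
        return None
    counts = pd.Series(cats).value_counts()
    # value_counts sorts by count then insertion; break count ties by listed order
    top = counts.max()
    modal = min((c for c in counts.index[counts == top]), key=CATEGORIES.index)
    share = top / len(cats)
    if len(counts) == 1:
        klass = "conserved"
    elif share < divergent_below:
        klass = "divergent"
    else:
        klass = "intermediate"
    return TriadSummary(triad_id, modal, float(share), klass)


def call_triads(
    means: pd.DataFrame,
    triads: pd.DataFrame,
    min_mean: float = 10.0,
    rule: str = "nearest_ideal",
) -> pd.DataFrame:
    """Per-accession bias calls for every triad.

    Parameters
    ----------
    means
        genes x accessions accession-mean expression (count scale).
    triads
        One row per triad with columns ``triad_id``, ``gene_a``, ``gene_b``,
        ``gene_c``.

    Returns a tidy frame (triad_id, accession, fa, fb, fc, category, eligible).
    """
    rows = []
    acc = list(means.columns)
    for rec in triads.itertuples(index=False):
        trio = [rec.gene_a, rec.gene_b, rec.gene_c]
        sub = means.loc[trio].to_numpy(dtype=float)
        eligible = triad_eligibility(sub, min_mean)
        for j, a in enumerate(acc):
            fr = triad_fractions(sub[:, j]) if eligible else None
            if fr is None:
                rows.append((rec.triad_id, a, np.nan, np.nan, np.nan, None, False))
            else:
                cat = classify_triad(fr, rule=rule)
                rows.append((rec.triad_id, a, fr[0], fr[1], fr[2], cat, True))
    return pd.DataFrame(
        rows, columns=["triad_id", "accession", "fa", "fb", "fc", "category", "eligible"]
    )


def summarize_all(calls: pd.DataFrame, divergent_below: float = 0.5) -> pd.DataFrame:
    """Conservation summaries for every triad with at least one eligible call."""
    out = []
    for tid, grp in calls.groupby("triad_id", sort=True):
        s = summarize_triad(str(tid), list(grp.loc[grp["eligible"], "category"]), divergent_below)
        if s is not None:
            out.append((s.triad_id, s.modal_category, s.modal_share, s.conservation_class))
    return pd.DataFrame(
        out, columns=["triad_id", "modal_category", "modal_share", "conservation_class"]
    )
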
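"""Shared fixtures: small synthetic studies generated once per session."""

from __future__ import annotations

import pytest

from polytraitx import expression
from polytraitx.synthetic_data import SimConfig, generate_dataset

SMALL = dict(n_genes=900, n_triads=100, n_snps=600, seed=1)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-noise desk-scale study used across modules."""
    return generate_dataset(SimConfig(**SMALL))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Same study conditions with counts equal to their means (truth recovery)."""
    return generate_dataset(SimConfig(**SMALL, zero_noise=True))


def _means(ds, mode):
    counts_f = expression.filter_low_expressed(ds.counts)
    norm = expression.normalize(counts_f, mode=mode)
    return expression.accession_means(norm)


@pytest.fixture(scope="session")
def count_means(small_dataset):
    """Accession means on the normalized-count (linear) scale."""
    return _means(small_dataset, "counts")


@pytest.fixture(scope="session")
def log_means(small_dataset):
    """Accession means on the log2 variance-stabilized scale."""
    return _means(small_dataset, "log2p1")
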
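"""Shared fixtures.

The heavy fixtures (the 2,000-record strong-signal dataset and the nested-CV
ensemble trained on it) are session-scoped so the recovery, member-count and
importance checks all reuse one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import neoforest as nf


@pytest.fixture(scope="session")
def allele_set():
    return nf.make_alleles(6, seed=1)


@pytest.fixture(scope="session")
def predictor(allele_set):
    return allele_set.predictor()


@pytest.fixture(scope="session")
def small_dataset(allele_set):
    """500 default-signal records for light-weight end-to-end checks."""
    return nf.make_neoepitope_dataset(500, allele_set, nf.SignalSpec(seed=42))


@pytest.fixture(scope="session")
def strong_dataset(allele_set):
    """2,000 strong-signal records with a pure-noise foreignness column."""
    records = nf.make_neoepitope_dataset(
        2000, allele_set, nf.SignalSpec.strong(seed=7)
    )
    rng = np.random.default_rng(123)
    for rec in records:  # foreignness carries no label signal by construction
        rec.foreignness = float(rng.random())
    return records


@pytest.fixture(scope="session")
def strong_model(strong_dataset):
    """Nested 10-fold ensemble trained on the strong-signal dataset."""
    config = nf.RunConfig(seed=1, background_size=2000)
    config.flags["foreignness"] = True
    return nf.train_pipeline(strong_dataset, config)
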
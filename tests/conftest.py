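"""Shared fixtures: synthetic datasets and reusable empirical nulls."""

from __future__ import annotations

import numpy as np
import pytest

import moanet as m


@pytest.fixture(scope="session")
def noise_dataset():
    """Pure-noise corpus: 10,000 genes, 20 drugs x 2 samples, no signal."""
    cfg = m.SimulationConfig(
        n_genes=10_000, n_moas=1, drugs_per_moa=20, samples_per_drug=2,
        signature_size=1, effect_size=0.0, noise_sd=1.0, seed=101)
    return m.generate_dataset(cfg)


@pytest.fixture(scope="session")
def noise_null(noise_dataset):
    matrix, metadata, _ = noise_dataset
    return m.build_null(matrix, metadata, n_draws=200_000, seed=5)


@pytest.fixture(scope="session")
def small_null():
    """Null from a small noise corpus, for cheap selection tests."""
    cfg = m.SimulationConfig(
        n_genes=2_000, n_moas=1, drugs_per_moa=6, samples_per_drug=2,
        signature_size=1, effect_size=0.0, noise_sd=1.0, seed=77)
    matrix, metadata, _ = m.generate_dataset(cfg)
    return m.build_null(matrix, metadata, n_draws=100_000, seed=78)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_profile(name, gene_ids, values, sig_genes):
    """DrugProfile with a simple all-up signature over ``sig_genes``."""
    entries = [m.SignatureEntry(g, d, 1e-4, float(d)) for g, d in sig_genes]
    sig = m.DrugSignature(name, entries, 2)
    return m.DrugProfile(name, list(gene_ids), np.asarray(values, float), sig)
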
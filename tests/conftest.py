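"""Shared fixtures: small deterministic matrices and simulated replicates."""

from __future__ import annotations

import numpy as np
import pytest

from omegascan import Alphabet, SnpMatrix


def make_binary(codes, positions=None) -> SnpMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1.0, codes.shape[1] + 1.0)
    return SnpMatrix.from_codes(
        codes, positions, Alphabet.BINARY, require_polymorphic=False
    )


def make_dna(codes, positions=None) -> SnpMatrix:
    codes = np.asarray(codes, dtype=np.int8)
    if positions is None:
        positions = np.arange(1.0, codes.shape[1] + 1.0)
    return SnpMatrix.from_codes(
        codes, positions, Alphabet.DNA, require_polymorphic=False
    )


def random_binary_matrix(
    rng: np.random.Generator, n_samples: int, n_snps: int, spacing: float = 10.0
) -> SnpMatrix:
    """Random polymorphic binary matrix with evenly jittered positions."""
    codes = np.zeros((n_samples, n_snps), dtype=np.int8)
    for j in range(n_snps):
        k = int(rng.integers(1, n_samples))
        codes[rng.choice(n_samples, k, replace=False), j] = 1
    pos = np.sort(rng.random(n_snps)) * spacing * n_snps
    pos = np.maximum.accumulate(pos + np.arange(n_snps) * 1e-6)
    return make_binary(codes, pos)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def sim_replicate():
    """One medium simulated neutral replicate for engine-level tests."""
    from omegascan import SimParams, simulate_neutral

    p = SimParams(
        n_samples=20,
        pop_size=40,
        region_length=100_000.0,
        theta_total=60.0,
        rho_total=40.0,
    )
    return simulate_neutral(p, 1, seed=7)[0]
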
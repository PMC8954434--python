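"""Shared fixtures: small simulated datasets and toy tables.

Simulations are session-scoped (they are deterministic under fixed seeds)
so the suite pays for each one once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dispersalscreen import GenotypeMatrix, build_scenario, simulate_dataset

NUC_ONLY = dict(cp_sequence_length=0, samples_per_deme_cp=0)


@pytest.fixture(scope="session")
def iso3():
    """3-deme post-isolation dataset, nuclear only (24 samples)."""
    cfg = build_scenario("iso", n_demes=3, samples_per_deme_nuclear=8, **NUC_ONLY)
    return simulate_dataset(cfg, seed=31)


@pytest.fixture(scope="session")
def iso2():
    """2-deme post-isolation dataset, nuclear only."""
    cfg = build_scenario("iso", n_demes=2, samples_per_deme_nuclear=10, **NUC_ONLY)
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def iso6_cp():
    """Default 6-deme isolation dataset including the chloroplast alignment."""
    return simulate_dataset(build_scenario("iso"), seed=604)


@pytest.fixture(scope="session")
def hd3_cp():
    """Default 6-deme dataset under the ancient human-dispersal pulse."""
    return simulate_dataset(build_scenario("hd3"), seed=604)


@pytest.fixture(scope="session")
def panmictic():
    """Single-deme (panmictic) dataset with 20 samples."""
    from dispersalscreen.scenarios import DEEP_SPLIT, zero_migration

    cfg = build_scenario(
        "iso", n_demes=1, samples_per_deme_nuclear=20,
        epochs=[(0.0, DEEP_SPLIT, zero_migration(1))], **NUC_ONLY,
    )
    return simulate_dataset(cfg, seed=8)


@pytest.fixture
def qc_toy():
    """10-locus table: 3 fail reproducibility only, 2 fail call rate only,
    1 fails both, 4 pass (boundary values count as passing).  Call-rate
    metadata is consistent with the actual missingness pattern."""
    rng = np.random.default_rng(0)
    n_samples, n_loci = 20, 10
    calls = rng.integers(0, 3, size=(n_samples, n_loci)).astype(np.int16)
    repro = np.array([0.99, 0.95, 0.96, 0.90, 0.80, 1.00, 0.97, 0.98, 1.00, 0.50])
    call_rate = np.array([1.00, 1.00, 0.80, 0.90, 1.00, 0.75, 0.50, 0.85, 0.95, 0.70])
    for j, cr in enumerate(call_rate):
        n_missing = round((1 - cr) * n_samples)
        calls[rng.choice(n_samples, size=n_missing, replace=False), j] = -1
    # fails: repro only -> loci 1, 3, 4; call rate only -> loci 5, 6; both -> locus 9
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
        reproducibility=repro,
        call_rate=call_rate,
    )


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2", "c1", "c2"],
            "species_id": ["sp"] * 6,
            "site_code": ["A", "A", "B", "B", "C", "C"],
            "latitude": [-30.0, -30.0, -29.0, -29.0, -28.0, -28.0],
            "longitude": [152.0, 152.0, 152.5, 152.5, 153.0, 153.0],
            "region_label": ["S", "S", "S", "S", "N", "N"],
        }
    )
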
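"""Shared fixtures: one small synthetic genome and its pipeline results."""

from __future__ import annotations

import warnings

import pytest

from retroforge import expression, retroscan, simgenome

warnings.filterwarnings("ignore", category=DeprecationWarning)

SMALL_CONFIG = dict(
    genome_length=250_000,
    n_parent_genes=10,
    n_retro_intact=3,
    n_retro_pseudo=2,
    n_retro_chimeric=4,
    retro_divergence=0.05,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim() -> simgenome.SimResult:
    """A small synthetic genome with planted retrocopies of every kind."""
    return simgenome.generate_genome(simgenome.SimConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_calls(small_sim):
    """Pipeline output on the small genome (calls, report)."""
    return retroscan.run_pipeline(small_sim.genome, small_sim.genes)


@pytest.fixture(scope="session")
def truth_by_call(small_sim, small_calls):
    """Map call_id -> planted RetroTruth by majority interval overlap."""
    calls, _ = small_calls
    mapping = {}
    for call in calls:
        for retro in small_sim.truth.retros:
            overlap = min(call.end, retro.end) - max(call.start, retro.start)
            if overlap > 0.5 * (retro.end - retro.start):
                mapping[call.call_id] = retro
    return mapping


@pytest.fixture(scope="session")
def est_data(small_sim):
    """Sampled ESTs, their truth, and accepted placements on the genome."""
    ests, est_truth = simgenome.sample_ests(small_sim)
    raw = expression.map_reads(ests, small_sim.genome)
    accepted, rejected = expression.place_ests(raw)
    return ests, est_truth, accepted, rejected
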
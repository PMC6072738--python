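"""Shared fixtures: compiled patterns and small seeded simulations."""

from __future__ import annotations

import pytest

from tcrprof import simulate as sim
from tcrprof.motif import TRBJ_PATTERN, TRBV_PATTERN, compile_pattern


@pytest.fixture(scope="session")
def v_pattern():
    return compile_pattern(TRBV_PATTERN)


@pytest.fixture(scope="session")
def j_pattern():
    return compile_pattern(TRBJ_PATTERN)


@pytest.fixture(scope="session")
def germline():
    """Four V and three J planted germline alleles (seeded)."""
    return sim.simulate_germline(n_v=4, n_j=3, seed=42)


@pytest.fixture(scope="session")
def small_simulation(germline):
    """Error-free library over 60 clonotypes, full coverage, 4 replicates."""
    cfg = sim.SimulationConfig(
        n_clonotypes=60, per_base_error=0.0, molecules_per_replicate=150,
        reads_per_molecule=3, n_replicates=4, guarantee_coverage=True,
        seed=7,
    )
    truth = sim.recombine(germline, cfg)
    replicates, truth = sim.simulate_library(truth, germline, cfg)
    return cfg, truth, replicates


@pytest.fixture(scope="session")
def germline_refs(germline):
    """Reference tuples in discovery's trimmed-segment convention."""
    v_refs = [(f"V{i + 1:03d}", germline.v_segment(i))
              for i in range(len(germline.v_alleles))]
    j_refs = [(f"J{i + 1:03d}", germline.j_segment(i))
              for i in range(len(germline.j_alleles))]
    return v_refs, j_refs
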
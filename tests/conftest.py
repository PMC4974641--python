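"""Shared fixtures: one synthetic germline library and one default-noise
simulated heavy-chain sample run through the pipeline (reused by the
recovery tests so the expensive simulation happens once per session)."""

from __future__ import annotations

import pytest

from abpipe.benchmark import TruthedRun, run_on_simulation
from abpipe.pipeline import PipelineConfig
from abpipe.simulate import SimulationConfig, make_synthetic_library

DEFAULT_SIM_SEED = 11
DEFAULT_N_READS = 2000


@pytest.fixture(scope="session")
def library():
    return make_synthetic_library(seed=1)


@pytest.fixture(scope="session")
def default_run(library) -> TruthedRun:
    """2000 heavy-chain reads at default noise, full pipeline."""
    return run_on_simulation(
        SimulationConfig(library=library, n_reads=DEFAULT_N_READS, seed=DEFAULT_SIM_SEED)
    )


@pytest.fixture(scope="session")
def uncorrected_run(library) -> TruthedRun:
    """The same sample with the correction stage disabled."""
    return run_on_simulation(
        SimulationConfig(library=library, n_reads=DEFAULT_N_READS, seed=DEFAULT_SIM_SEED),
        PipelineConfig(correction_enabled=False),
    )


@pytest.fixture(scope="session")
def noise_free_run(library) -> TruthedRun:
    return run_on_simulation(
        SimulationConfig(
            library=library,
            n_reads=400,
            seed=13,
            shm_rate=0.0,
            seq_sub_rate=0.0,
            seq_indel_rate=0.0,
        )
    )


@pytest.fixture(scope="session")
def long_indel_run(library) -> TruthedRun:
    """Error model widened to indels of up to 4 nt so the uncorrectable
    regime (3 nt and over) is exercised."""
    return run_on_simulation(
        SimulationConfig(
            library=library, n_reads=400, seed=12, indel_max_len=4, seq_indel_rate=0.004
        )
    )
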
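import numpy as np
import pytest

from psft.design import build_probe_sf_sequence, build_run_design, build_session_schedule
from psft.fitting import concatenate_condition_blocks
from psft.model import hirf_kernel


@pytest.fixture(scope="session")
def kernel():
    return hirf_kernel()


@pytest.fixture(scope="session")
def default_design():
    return build_run_design(seed=11)


@pytest.fixture(scope="session")
def session_runs(default_design):
    """Three runs with probe sequences (desk-scale session)."""
    runs = build_session_schedule(3, default_design, seed=7)
    seqs = [build_probe_sf_sequence(r, seed=100 + i) for i, r in enumerate(runs)]
    return runs, seqs


@pytest.fixture(scope="session")
def spliced_baseline(session_runs):
    runs, seqs = session_runs
    return concatenate_condition_blocks(
        [(None, r, s) for r, s in zip(runs, seqs)], "AttendFixation"
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
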
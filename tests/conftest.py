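import numpy as np
import pytest

from rivalry.profiles import (
    paper_like_local,
    paper_like_nonlocal,
    paper_like_quartet,
    persistent_activity,
)
from rivalry.recipes import run_intermittent


@pytest.fixture(scope="session")
def local_profile():
    return paper_like_local()


@pytest.fixture(scope="session")
def nonlocal_profile():
    return paper_like_nonlocal()


@pytest.fixture(scope="session")
def quartet_profile():
    return paper_like_quartet()


@pytest.fixture(scope="session")
def persistent_profile():
    return persistent_activity()


@pytest.fixture(scope="session")
def local_run(local_profile):
    """One rested local-fatigue pulse-train run (T_frame = 260 ms),
    shared by readout / habituation / classification tests."""
    traj, trace, records = run_intermittent(
        local_profile.params, local_profile, 260.0, 120, record_every=5
    )
    return traj, trace, records


@pytest.fixture(scope="session")
def nonlocal_run(nonlocal_profile):
    traj, trace, records = run_intermittent(
        nonlocal_profile.params, nonlocal_profile, 260.0, 120, record_every=5
    )
    return traj, trace, records


@pytest.fixture(scope="session")
def quartet_run(quartet_profile):
    traj, trace, records = run_intermittent(
        quartet_profile.params, quartet_profile, 260.0, 100, record_every=5
    )
    return traj, trace, records
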
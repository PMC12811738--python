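import warnings

import numpy as np
import pytest

from fivs.protocol import Segment, ProtocolTimeline, build_protocol
from fivs.simulate import DEFAULT_NOISY, SubjectParams, simulate_participant


@pytest.fixture(scope="session")
def timeline():
    return build_protocol()


@pytest.fixture(scope="session")
def baseline_only_timeline():
    """A single quiet 300-s segment with no sigh cues."""
    return ProtocolTimeline(
        segments=(Segment("baseline", 0.0, 300.0),), sigh_cues=(), inter_task_gap=60.0
    )


@pytest.fixture(scope="session")
def noiseless_recording(timeline):
    """Default subject, full session, every stochastic term off."""
    return simulate_participant(SubjectParams(), timeline, seed=5)


@pytest.fixture(scope="session")
def noisy_recording(timeline):
    return simulate_participant(SubjectParams(**DEFAULT_NOISY), timeline, seed=5)


@pytest.fixture(scope="session")
def processed_noiseless(noiseless_recording):
    from fivs.pipeline import process_recording

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return process_recording(noiseless_recording)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*convergence.*")
        warnings.filterwarnings("ignore", message=".*boundary.*")
        yield
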
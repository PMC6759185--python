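import numpy as np
import pytest

from perisaccade.experiment import ProbeGrid, Trial, TrialSet


@pytest.fixture(scope="session")
def grid3() -> ProbeGrid:
    """Small probe grid with the saccade target two probes left of the FP."""
    return ProbeGrid(n_rows=3, n_cols=3, origin=(-9.9, -3.3), dx=3.3,
                     dy=3.3, fp=(0.0, 0.0), st=(-6.6, 0.0))


@pytest.fixture(scope="session")
def grid9() -> ProbeGrid:
    return ProbeGrid()


def make_trial(stimulus, spikes, t_start, trial_id=0):
    return Trial(stimulus=stimulus, spikes=spikes, t_start=t_start,
                 trial_id=trial_id)


@pytest.fixture
def empty_trial(grid3):
    stim = np.zeros((3, 3, 100), dtype=np.uint8)
    spk = np.zeros(100, dtype=np.uint8)
    return make_trial(stim, spk, -50)
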
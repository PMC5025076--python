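import numpy as np
import pytest

from icabci.infomax import IcaConfig
from icabci.preprocessing import bandpass_filter, epoch_trials
from icabci.simulate import SimConfig, generate_dataset

#: Reduced-iteration optimizer for pipeline-scale tests (75 single-trial
#: fits per run); quality at 128 iterations matches the 512 default on the
#: simulator's trial lengths.
FAST_ICA = IcaConfig(seed=0, max_iter=128)
SUBJECT_BAND = (10.0, 14.0)
ANALYSIS_WINDOW = (0.5, 5.0)


@pytest.fixture(scope="session")
def clean_run():
    """One clean simulated run (75 trials, 9 channels, seed 42)."""
    return generate_dataset(SimConfig(seed=42))


@pytest.fixture(scope="session")
def clean_trials(clean_run):
    """The clean run band-passed to 8-30 Hz and epoched to full trials."""
    rec, _ = clean_run
    return epoch_trials(bandpass_filter(rec, 8.0, 30.0), (0.0, 10.0))
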
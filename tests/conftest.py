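import numpy as np
import pytest

import palpaid as p


@pytest.fixture(scope="session")
def desk_profile():
    """Reduced-rate (50 Hz) high-SNR scanning profile used across tests."""
    return p.desk_profile(seed=11)


@pytest.fixture(scope="session")
def desk_extraction():
    return p.ExtractionConfig(sampling_rate=50.0)


@pytest.fixture(scope="session")
def participant_trials(desk_profile):
    """One simulated participant: 40 trials, 20 per class."""
    return p.generate_participant(desk_profile, np.random.default_rng(11))


@pytest.fixture(scope="session")
def tumor_trial(desk_profile):
    return p.generate_trial(desk_profile, True, np.random.default_rng(3))


@pytest.fixture(scope="session")
def fitted_detector(participant_trials):
    """Detector trained on the first 20 trials and calibrated on the next 10."""
    det = p.TumorDetector(segmenter=p.WindowSegmenterMLP(epochs=30,
                                                         random_state=1))
    det.fit(participant_trials[:20])
    det.calibrate(participant_trials[20:30])
    return det
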
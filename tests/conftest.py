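import numpy as np
import pytest

from eog_audiometry.pipeline import EogEpoch, ProcessingStage
from eog_audiometry.simulate import SimulatedListener


@pytest.fixture
def law70():
    from eog_audiometry.stimulus import PanningLaw

    return PanningLaw(target_dBA=70.0)


@pytest.fixture
def quiet_listener():
    """Deterministic listener: no noise, no drift, no phase jitter."""
    return SimulatedListener(
        true_thresholds={1000.0: 40.0, 2000.0: 40.0, 4000.0: 40.0},
        noise_sd=0.0,
        drift_amplitude=0.0,
        reflex_phase_jitter=0.0,
        common_mode_amplitude=0.0,
        dc_offset_sd=0.0,
    )


@pytest.fixture
def default_listener():
    return SimulatedListener()


def make_epoch(samples, sample_rate=512.0, stage=ProcessingStage.RAW_BIPOLAR, ref=None):
    return EogEpoch(np.asarray(samples, dtype=float), sample_rate, trial_ref=ref, stage=stage)


@pytest.fixture
def sine_epoch():
    """6-s raw-bipolar epoch holding a pure 1/3 Hz unit sinusoid at 512 Hz."""
    t = np.arange(round(6 * 512)) / 512.0
    return make_epoch(np.sin(2 * np.pi * t / 3))
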
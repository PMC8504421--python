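import numpy as np
import pytest

from neurovasc import ScenarioConfig


@pytest.fixture
def compact_config():
    """A 13-minute scenario with the full baseline/drop/recovery structure.

    Structurally identical to the hour-scale defaults (baseline, rapid drop,
    sub-trigger interval holding two SDs, sustained 80% recovery crossing
    after the 5-min ischemia window, late plateau) but sized so the rendered
    kymograph and 10 kHz-equivalent LFP stay desk-scale.
    """
    return ScenarioConfig(
        injection_time=120.0,
        baseline_duration=120.0,
        duration=780.0,
        recovery_onset_time=560.0,
        n_sds=2,
        seed=0,
    )


@pytest.fixture
def tone():
    """Factory for pure-tone sample arrays: tone(freq, duration, fs)."""

    def _tone(freq, duration=30.0, fs=1000.0, amplitude=1.0):
        t = np.arange(0.0, duration, 1.0 / fs)
        return amplitude * np.sin(2 * np.pi * freq * t)

    return _tone
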
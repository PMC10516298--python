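import numpy as np
import pytest

from oculomet.preprocess import GazeRecording
from oculomet.synth import PlantedOculomotorTruth


@pytest.fixture
def quiet_truth():
    """Noise-free truth: no scatter, intrusions, blinks or sensor noise."""
    return PlantedOculomotorTruth(
        noise_sd_deg=0.0, fix_sigma_x_deg=0.0, fix_sigma_y_deg=0.0,
        intrusion_rate_hz=0.0, blink_rate_hz=0.0, bias_deg=0.0,
        pro_latency_sd_s=0.0, anti_latency_sd_s=0.0,
        anti_time_to_correct_sd_s=0.0)


@pytest.fixture
def device_truth():
    """Device-like sensor noise, modest scatter, no intrusions/blinks."""
    return PlantedOculomotorTruth(
        noise_sd_deg=0.33, fix_sigma_x_deg=0.15, fix_sigma_y_deg=0.15,
        intrusion_rate_hz=0.0, blink_rate_hz=0.0)


def make_recording(x, y=None, rate=60.0, valid=None):
    x = np.asarray(x, float)
    t = np.arange(len(x)) / rate
    y = np.zeros_like(x) if y is None else np.asarray(y, float)
    valid = np.ones(len(x), bool) if valid is None else np.asarray(valid, bool)
    return GazeRecording(t=t, x=x, y=y, valid=valid, rate_hz=rate)
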
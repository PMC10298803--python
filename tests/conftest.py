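import numpy as np
import pytest

from tonotopy.types import SynthConfig


@pytest.fixture
def small_isc_config():
    """Scaled-down supporting-cell movie: 5-min, 120×120 px field, noiseless."""
    return SynthConfig(
        seed=1,
        duration_s=300.0,
        frame_rate_hz=2.0,
        image_shape=(120, 120),
        pixel_scale_um=0.83,
        event_rate_per_min=2.0,
        event_footprint_um=40.0,
        event_amplitude_dff=1.0,
        noise_sd_dff=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
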
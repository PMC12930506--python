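import warnings

import numpy as np
import pytest

from mimicomm.signal_model import GateParams, STAR_DEFAULTS, TRIGGER_DEFAULTS

warnings.filterwarnings("ignore", category=UserWarning, module="mimicomm")


@pytest.fixture(scope="session")
def gate():
    return GateParams()

@pytest.fixture(scope="session")
def star():
    return STAR_DEFAULTS

@pytest.fixture(scope="session")
def trigger():
    return TRIGGER_DEFAULTS


@pytest.fixture(scope="session")
def endpoint_benchmark():
    """The shipped 29-sample end point benchmark plus its controls (seed 42)."""
    from mimicomm.workbench import benchmark_samples

    return benchmark_samples("benchmark_endpoint")


@pytest.fixture(scope="session")
def small_rendered_sample():
    """A 50-mimic layout rendered at default SNR, with its ground truth."""
    from mimicomm.community import render_images, sample_random_layout

    layout = sample_random_layout(
        {"receiver": 25, "star_sender": 13, "trigger_sender": 12},
        droplet_radius=0.8,
        seed=5,
    )
    channels = render_images(layout, np.full(len(layout), 500.0), pixel_size=4.0, seed=5)
    return layout, channels
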
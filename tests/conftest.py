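import numpy as np
import pytest
from hypothesis import settings

import optopace as op

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def speckle_video():
    """A short contracting-cell movie shared by the tracking tests."""
    spec = op.SyntheticVideoSpec(
        width=96,
        height=96,
        n_frames=400,
        fps=50.0,
        cell_center=(48.0, 48.0),
        cell_axes=(30.0, 24.0),
        contraction_rate=0.5,
        area_reduction=0.10,
        texture_seed=11,
        noise_sd=2.0,
    )
    stack, truth = op.make_contraction_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def speckle_box():
    return op.BoundingBox(12, 18, 84, 78)


@pytest.fixture(scope="session")
def ap_train_10khz():
    """Noiseless 4-AP train sampled at 10 kHz with its ground truth."""
    spec = op.SyntheticTraceSpec(
        duration=10.0,
        dt=1e-4,
        event_times=(1.0, 3.0, 5.0, 7.0),
        MDP=-42.0,
        APA=70.0,
        APD90=300.0,
    )
    trace, truth = op.make_ap_train(spec)
    return spec, trace, truth


@pytest.fixture(scope="session")
def ca_train():
    """Noiseless calcium transients at 0.2 Hz (fully recovering baseline)."""
    spec = op.SyntheticTraceSpec(
        duration=25.0,
        dt=5e-3,
        event_times=tuple(1.0 + 5.0 * np.arange(4)),
        CaD=1.0,
        amplitude=0.5,
        t_peak=0.15,
        tau_decay=0.8,
    )
    trace, truth = op.make_ca_trace(spec)
    return spec, trace, truth
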
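import numpy as np
import pytest

import qmsi

# 200 µm pixels keep the default 20x20 mm block at 100x100 px (15x15-px wells,
# 225 px/well) so seeded Monte-Carlo tests stay fast.
PIXEL_SIZE_UM = 200.0


@pytest.fixture(scope="session")
def layout():
    return qmsi.default_mimetic_layout(pixel_size_um=PIXEL_SIZE_UM, seed=7)


@pytest.fixture()
def noisefree_params():
    return qmsi.SimParams(
        pixel_rsd=0.0, baseline_noise_sd=0.0, pixel_size_um=PIXEL_SIZE_UM, seed=0
    )


@pytest.fixture()
def noisy_params():
    return qmsi.SimParams(pixel_size_um=PIXEL_SIZE_UM, seed=0)


@pytest.fixture(scope="session")
def noisefree_array(layout):
    params = qmsi.SimParams(
        pixel_rsd=0.0, baseline_noise_sd=0.0, pixel_size_um=PIXEL_SIZE_UM, seed=0
    )
    grid, truth = qmsi.generate_mimetic_array(layout, params)
    return grid, truth, params


@pytest.fixture(scope="session")
def noisefree_curve(layout, noisefree_array):
    grid, _, _ = noisefree_array
    obs = qmsi.observe_array(grid, layout, "compound_A", "lipid_782")
    cal = [o for o in obs if o.role == "calibration"]
    blanks = [o for o in obs if o.role == "blank"]
    return qmsi.build_calibration(cal, blanks)


def make_tiny_grid(values_by_channel, pixel_size_um=100.0, kinds=None):
    """Build a small ChannelGrid from 2-D arrays (test helper)."""
    kinds = kinds or {}
    channels = [
        qmsi.ChannelDef(name, kinds.get(name, "analyte")) for name in values_by_channel
    ]
    intensities = {k: np.asarray(v, dtype=float) for k, v in values_by_channel.items()}
    return qmsi.ChannelGrid(
        pixel_size_um=pixel_size_um, channels=channels, intensities=intensities
    )
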
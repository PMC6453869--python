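import numpy as np
import pytest

from condensia import synthgen


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized filled disk, radius 50 px."""
    yy, xx = np.mgrid[-60:61, -60:61]
    return yy**2 + xx**2 <= 50**2


@pytest.fixture(scope="session")
def rect_mask():
    """Filled 120x60 px axis-aligned rectangle."""
    mask = np.zeros((80, 140), dtype=bool)
    mask[10:70, 10:130] = True
    return mask


@pytest.fixture(scope="session")
def ellipse_mask():
    """Rasterized 2:1 ellipse (a=70, b=35 px semi-axes)."""
    yy, xx = np.mgrid[-45:46, -85:86]
    return (yy / 35.0) ** 2 + (xx / 70.0) ** 2 <= 1.0


def make_scene_spec(**overrides):
    """Well-separated ellipse scene; defaults sized for fast tests."""
    params = dict(
        image_size=(400, 400),
        n_objects=8,
        area_range=(300.0, 900.0),
        axis_ratio_range=(1.0, 2.0),
        noise_sd=0.03,
        min_gap=8,
        seed=0,
    )
    params.update(overrides)
    return synthgen.MicromassSceneSpec(**params)


def make_groove_spec(**overrides):
    """Single-groove time series with two growing condensations."""
    params = dict(
        groove_width_um=100.0,
        groove_length_um=500.0,
        pixel_size_um=1.0,
        n_timepoints=12,
        frame_interval_h=0.5,
        condensations=[
            synthgen.CondensationParams(center_um=150.0),
            synthgen.CondensationParams(
                center_um=370.0, final_length_um=60.0, final_width_um=50.0
            ),
        ],
        noise_sd=0.01,
        seed=0,
    )
    params.update(overrides)
    return synthgen.GrooveSeriesSpec(**params)


@pytest.fixture
def scene_spec():
    return make_scene_spec()


@pytest.fixture
def groove_spec():
    return make_groove_spec()
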
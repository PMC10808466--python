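"""Shared fixtures: truth curves, chip configuration, small rendering setups.

All image fixtures are generated in-process by the synthetic chip simulator;
no binary data ships with the tests.
"""

import numpy as np
import pytest
import yaml

import barriersense as bs
from barriersense.io import default_config_text, parse_config


@pytest.fixture(scope="session")
def truth_curve():
    """An increasing 4PL response typical of the 8-bit sensor."""
    return bs.CalibrationCurve("cyan", a=5.0, b=1.2, c=0.5, d=220.0)


@pytest.fixture(scope="session")
def simple_curve():
    """The hand-computable curve used in the worked arithmetic examples."""
    return bs.CalibrationCurve("cyan", a=5.0, b=1.0, c=0.5, d=205.0)


@pytest.fixture(scope="session")
def chip_config():
    """Default configuration (synthetic geometry) parsed from the package."""
    return parse_config(yaml.safe_load(default_config_text()))


@pytest.fixture(scope="session")
def inulin(chip_config):
    return chip_config.tracer_for_channel("cyan")


@pytest.fixture
def small_rois():
    """Two non-overlapping ROIs inside a 120 x 160 test frame."""
    return bs.ROISet(
        capillary=bs.Rect(10, 110, 20, 60),
        filtrate=bs.Rect(10, 110, 100, 140),
    )


@pytest.fixture
def small_mask():
    """A smooth non-flat illumination field for 120 x 160 frames."""
    return bs.make_gradient_mask((120, 160), strength=0.3)


@pytest.fixture
def flat_mask():
    return bs.IlluminationMask(np.ones((120, 160)))


def make_frame(values, channel="cyan", t=0.0):
    """Build a Frame from a plain array without 8-bit range checking."""
    return bs.Frame(
        pixels=np.asarray(values, dtype=float),
        led_channel=channel,
        timestamp=t,
        validate_range=False,
    )
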
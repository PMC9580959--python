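"""Shared fixtures: small synthetic images, tables and calibrations."""

import numpy as np
import pytest

from prismtrack.detect import DetectionParams, make_default_astigmatism_calibration
from prismtrack.io import LocalizationRecord, LocalizationTable


def render_gaussian(shape, x, y, sigma_x, sigma_y, amplitude, background=0.0):
    """Noiseless sampled elliptical Gaussian (shared rendering oracle)."""
    yg, xg = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return (
        amplitude
        * np.exp(-((xg - x) ** 2) / (2 * sigma_x**2) - ((yg - y) ** 2) / (2 * sigma_y**2))
        + background
    )


@pytest.fixture
def detection_params():
    return DetectionParams()


@pytest.fixture
def astig_calib():
    return make_default_astigmatism_calibration()


@pytest.fixture
def small_table():
    records = [
        LocalizationRecord(frame=0, x=10.25, y=20.5, sigma_x=1.3, sigma_y=1.4,
                           photons=500.0, background=10.0, goodness=0.95),
        LocalizationRecord(frame=1, x=11.0, y=21.0, sigma_x=1.2, sigma_y=1.5,
                           photons=450.0, background=12.0, goodness=0.9,
                           z=150.0, wavelength=655.0, pair_distance=3.45, track_id=7,
                           species="qd655"),
        LocalizationRecord(frame=2, x=11.5, y=21.5, sigma_x=1.25, sigma_y=1.45,
                           photons=480.0, background=9.0, goodness=0.92),
    ]
    return LocalizationTable(records, channel_label="spatial", metadata={"seed": 1})
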
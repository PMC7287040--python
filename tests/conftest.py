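"""Shared fixtures: all test data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hfopipe.seeg_io import ContactTable, Recording, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_recording(rng) -> Recording:
    """2-channel, 10 s monopolar recording at 2048 Hz."""
    fs = 2048
    data = 50.0 * rng.standard_normal((2, 10 * fs))
    return Recording(data=data, fs=fs, channel_names=["A1", "A2"],
                     montage="monopolar")


@pytest.fixture
def contact_table() -> ContactTable:
    """One electrode shaft A with 4 contacts spaced 1.5 mm along x."""
    rows = [{"electrode": "A", "index": i + 1,
             "x_mm": 10.0 + 1.5 * i, "y_mm": 20.0, "z_mm": 30.0}
            for i in range(4)]
    return ContactTable(pd.DataFrame(rows))


@pytest.fixture
def shaft_recording(rng, contact_table) -> Recording:
    """Monopolar recording matching the 4-contact shaft fixture."""
    fs = 2048
    data = 30.0 * rng.standard_normal((4, 4 * fs))
    return Recording(data=data, fs=fs,
                     channel_names=["A1", "A2", "A3", "A4"],
                     montage="monopolar")


def make_mask(shape=(40, 40, 40), affine=None, fill=1.0,
              interpretation="brain_mask") -> VolumeImage:
    if affine is None:
        affine = np.eye(4)
    return VolumeImage(grid=np.full(shape, fill), affine=affine,
                      interpretation=interpretation)


@pytest.fixture
def brain_mask() -> VolumeImage:
    return make_mask(interpretation="brain_mask")


@pytest.fixture
def gray_mask() -> VolumeImage:
    return make_mask(interpretation="gray_mask")
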
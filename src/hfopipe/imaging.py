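"""Volumetric projection of channel HFO occurrence rates.

Per-channel event counts become rates (events/min), normalized to the
highest-rate channel, and each channel's normalized rate is painted into
9x9x9 mm cubes centered on its two member contacts (overlaps keep the
maximum).  The volume is then smoothed with a 4 mm-FWHM-per-axis Gaussian
and rescaled so the normalization survives, yielding the anatomical
heatmap used for surgical review.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .classifier import EventLabel, filter_qhfo
from .seeg_io import BipolarChannel, VolumeImage

__all__ = ["build_rate_table", "rates_to_volume", "smooth_volume"]

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

SUBSETS = ("chfo", "qhfo", "qhfo_with_spike", "qhfo_without_spike",
           "qhfo_with_fr", "qhfo_without_fr")


def _subset_count(labels: list[EventLabel], subset: str) -> int:
    if subset == "chfo":
        return len(labels)
    key = None if subset == "qhfo" else subset.removeprefix("qhfo_")
    return len(filter_qhfo(labels, key))


def build_rate_table(labels_by_channel: dict[str, list[EventLabel]],
                     duration_min: float | dict[str, float]) -> pd.DataFrame:
    """Per-channel occurrence rates, absolute and max-normalized.

    Returns a DataFrame indexed by channel with, for each event subset
    (cHFO, qHFO and the four qHFO sub-populations), a count, a rate in
    events/min and a rate normalized to the highest-rate channel.
    """
    channels = list(labels_by_channel)
    if isinstance(duration_min, (int, float)):
        duration_min = {ch: float(duration_min) for ch in channels}
    if any(duration_min[ch] <= 0 for ch in channels):
        raise ValueError("clip durations must be positive")
    rows = {}
    for ch in channels:
        row = {}
        for subset in SUBSETS:
            n = _subset_count(labels_by_channel[ch], subset)
            row[f"{subset}_count"] = n
            row[f"{subset}_rate"] = n / duration_min[ch]
        rows[ch] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "channel"
    for subset in SUBSETS:
        mx = df[f"{subset}_rate"].max()
        if mx == 0:
            if subset in ("chfo", "qhfo"):
                warnings.warn(f"all-zero counts for subset {subset}")
            df[f"{subset}_norm"] = 0.0
        else:
            df[f"{subset}_norm"] = df[f"{subset}_rate"] / mx
    return df


def rates_to_volume(table: pd.DataFrame, channels: list[BipolarChannel],
                    template: VolumeImage, column: str = "qhfo_norm",
                    cube_mm: float = 9.0, included_only: bool = True,
                    subject_to_template: np.ndarray | None = None
                    ) -> VolumeImage:
    """Paint normalized rates into contact-centered cubes on the template grid.

    For every channel in the table its normalized rate is written into all
    voxels of the ``cube_mm`` cube (default 9 mm) centered on each of the
    channel's two member contacts; overlapping cubes keep the maximum.
    Contacts outside the template are skipped with a log message.

    ``subject_to_template`` is an optional 4x4 mm-to-mm affine (e.g.
    subject space to MNI) applied to contact coordinates before painting;
    the transformation is an input, never computed here.
    """
    grid = np.zeros(template.grid.shape)
    half = cube_mm / 2.0
    vox = template.voxel_sizes()
    by_name = {ch.name: ch for ch in channels}
    for name, row in table.iterrows():
        ch = by_name.get(name)
        if ch is None:
            continue
        if included_only and not ch.included:
            continue
        value = float(row[column])
        for xyz in (ch.anode_xyz, ch.cathode_xyz):
            if subject_to_template is not None:
                xyz = (subject_to_template @ np.append(xyz, 1.0))[:3]
            center = template.mm_to_voxel(xyz)
            if not template.in_bounds(center):
                logger.info("contact of %s outside template; skipped", name)
                continue
            # voxels whose center lies within +-half mm of the cube center
            n_half = np.floor(half / vox).astype(int)
            lo = np.maximum(center - n_half, 0)
            hi = np.minimum(center + n_half + 1, np.array(grid.shape))
            block = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            np.maximum(block, value, out=block)
    return VolumeImage(grid=grid, affine=template.affine.copy(),
                       interpretation="heatmap")


def smooth_volume(vol: VolumeImage, fwhm_mm: float = 4.0) -> VolumeImage:
    """3-D Gaussian smoothing (FWHM per axis in mm), preserving the max scale.

    After blurring, the grid is rescaled so its maximum equals the input
    maximum (a max-normalized heatmap stays max-normalized).
    """
    vox = vol.voxel_sizes()
    sigma = (fwhm_mm / _FWHM_TO_SIGMA) / vox
    out = ndimage.gaussian_filter(vol.grid, sigma=sigma)
    in_max = vol.grid.max()
    out_max = out.max()
    if in_max > 0 and out_max > 0:
        out *= in_max / out_max
    return VolumeImage(grid=out, affine=vol.affine.copy(),
                       interpretation="heatmap")
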
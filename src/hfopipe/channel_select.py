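"""Screening of bipolar channels before event detection.

Four exclusion rules, applied to the notch-filtered bipolar montage:

* outside brain — either member contact maps outside the brain mask;
* out of gray matter — the 3x3x3-voxel cube around the bipolar midpoint
  holds fewer than 9 gray-matter voxels (white-matter channel);
* low amplitude — channel RMS below the 35th percentile of the RMS
  distribution over channels not already flagged outside the brain;
* extreme amplitude — |v| > 1000 µV sustained for more than 1 s
  (amplifier/connection artifact).

A channel is included iff none of the four flags is set.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .seeg_io import BipolarChannel, Recording, VolumeImage

__all__ = [
    "flag_outside_brain",
    "gray_matter_cube_test",
    "flag_low_amplitude",
    "flag_extreme_amplitude",
    "select_channels",
]

logger = logging.getLogger(__name__)


def _contact_outside(vol: VolumeImage, xyz_mm: np.ndarray) -> bool:
    ijk = vol.mm_to_voxel(xyz_mm)
    if not vol.in_bounds(ijk):
        logger.info("contact at %s maps outside the mask grid", xyz_mm)
        return True
    return vol.grid[tuple(ijk)] == 0


def flag_outside_brain(channels: list[BipolarChannel],
                       brain_mask: VolumeImage) -> None:
    """Set the outside_brain flag on each channel (in place).

    A bipolar channel is outside the brain if at least one of its two
    member contacts falls on a zero voxel of the brain mask, or beyond the
    grid entirely.
    """
    if brain_mask.interpretation != "brain_mask":
        raise ValueError("flag_outside_brain requires a brain_mask volume")
    for ch in channels:
        ch.flags["outside_brain"] = (
            _contact_outside(brain_mask, ch.anode_xyz)
            or _contact_outside(brain_mask, ch.cathode_xyz)
        )


def gray_matter_cube_test(channel: BipolarChannel, gm_mask: VolumeImage,
                          min_gray_voxels: int = 9) -> bool:
    """True iff the channel midpoint fails the gray-matter cube test.

    Counts gray voxels in the 3x3x3 cube centered on the voxel containing
    the bipolar midpoint; fewer than ``min_gray_voxels`` (default 9 of 27)
    marks the channel as lying in white matter. Cube voxels beyond the grid
    count as non-gray.
    """
    if gm_mask.interpretation != "gray_mask":
        raise ValueError("gray_matter_cube_test requires a gray_mask volume")
    center = gm_mask.mm_to_voxel(channel.midpoint)
    shape = np.array(gm_mask.grid.shape)
    count = 0
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                ijk = center + np.array([di, dj, dk])
                if np.all(ijk >= 0) and np.all(ijk < shape):
                    count += int(gm_mask.grid[tuple(ijk)] > 0)
    return count < min_gray_voxels


def channel_rms(rec: Recording) -> np.ndarray:
    """Root-mean-square per channel over the full trace."""
    return np.sqrt(np.mean(rec.data ** 2, axis=1))


def flag_low_amplitude(rec: Recording, channels: list[BipolarChannel],
                       percentile: float = 35.0) -> None:
    """Flag channels whose RMS is below the given percentile (in place).

    The percentile reference set excludes channels already flagged as
    outside the brain. With fewer than 3 eligible channels the rule is
    skipped (the percentile is meaningless on so few values).
    """
    name_to_row = {n: i for i, n in enumerate(rec.channel_names)}
    rms = channel_rms(rec)
    eligible = [ch for ch in channels if not ch.flags["outside_brain"]]
    if len(eligible) < 3:
        warnings.warn("fewer than 3 in-brain channels; low-amplitude rule skipped")
        return
    ref = np.array([rms[name_to_row[ch.name]] for ch in eligible])
    cut = np.percentile(ref, percentile)
    for ch in eligible:
        ch.flags["low_amplitude"] = bool(rms[name_to_row[ch.name]] < cut)


def flag_extreme_amplitude(rec: Recording, channels: list[BipolarChannel],
                           threshold_uv: float = 1000.0,
                           min_duration_s: float = 1.0) -> None:
    """Flag channels with |v| > threshold sustained for more than 1 s (in place).

    The run must be strictly longer than ``min_duration_s`` in consecutive
    samples; brief high-amplitude transients (e.g. spikes) do not qualify.
    """
    name_to_row = {n: i for i, n in enumerate(rec.channel_names)}
    min_run = int(min_duration_s * rec.fs)  # strictly more than 1 s
    for ch in channels:
        x = rec.data[name_to_row[ch.name]]
        above = np.abs(x) > threshold_uv
        ch.flags["extreme_amplitude"] = bool(_longest_run(above) > min_run)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def select_channels(rec: Recording, channels: list[BipolarChannel],
                    brain_mask: VolumeImage | None = None,
                    gm_mask: VolumeImage | None = None,
                    rms_percentile: float = 35.0) -> pd.DataFrame:
    """Apply all four exclusion rules and return the selection report.

    Masks may be omitted (e.g. for purely simulated data), in which case
    the corresponding rules are skipped. Returns a DataFrame with one row
    per bipolar channel: RMS, the four flags and the included verdict.
    """
    if brain_mask is not None:
        flag_outside_brain(channels, brain_mask)
    if gm_mask is not None:
        for ch in channels:
            if not ch.flags["outside_brain"]:
                ch.flags["out_of_gray"] = gray_matter_cube_test(ch, gm_mask)
    flag_low_amplitude(rec, channels, percentile=rms_percentile)
    flag_extreme_amplitude(rec, channels)

    rms = channel_rms(rec)
    name_to_row = {n: i for i, n in enumerate(rec.channel_names)}
    rows = []
    for ch in channels:
        rows.append({
            "channel": ch.name,
            "rms_uv": rms[name_to_row[ch.name]],
            **ch.flags,
            "included": ch.included,
        })
    return pd.DataFrame(rows)
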
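"""Initial candidate-HFO detector.

Band-limited envelope thresholding: the trace is band-passed with a
64-order zero-phase FIR filter, the envelope is a cubic spline through the
local maxima of the rectified signal, and the threshold is five times the
median of the per-100 ms-epoch standard deviations of the filtered signal.
A candidate is an envelope excursion above threshold lasting more than
6 ms; excursions whose envelope peaks lie closer than 20 ms are merged.
The procedure runs in the broad 80-500 Hz band and again in the 250-500 Hz
fast-ripple band (fast ripples ride on a 1/f background and can stay below
the broad-band threshold), and the two event sets are unioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "DetectorConfig",
    "EventCandidate",
    "bandpass_zero_phase",
    "compute_envelope",
    "compute_threshold",
    "detect_band_events",
    "detect_candidates",
    "candidates_to_frame",
]


@dataclass(frozen=True)
class DetectorConfig:
    broad_band: tuple[float, float] = (80.0, 500.0)
    fr_band: tuple[float, float] = (250.0, 500.0)
    fir_order: int = 64
    epoch_len: float = 0.100      # s, SD estimation epoch
    epoch_step: float = 0.100     # s, non-overlapping by default
    threshold_factor: float = 5.0  # x median of epoch SDs
    min_duration: float = 0.006   # s, strictly-greater-than rule
    merge_gap: float = 0.020      # s, peak-distance merge rule
    merge_before_duration_test: bool = False

    def __post_init__(self) -> None:
        if self.epoch_step > self.epoch_len:
            raise ValueError("epoch_step must not exceed epoch_len")
        for v in (self.fir_order, self.epoch_len, self.threshold_factor,
                  self.min_duration, self.merge_gap):
            if v <= 0:
                raise ValueError("detector parameters must be positive")


@dataclass
class EventCandidate:
    """One candidate event on one channel, times in seconds from clip start."""

    channel: str
    t_start: float
    t_end: float
    t_peak: float
    peak_amplitude: float  # envelope value at t_peak, µV
    detected_broad: bool = True
    detected_fr: bool = False
    label: object = field(default=None, repr=False)  # filled by the classifier

    def __post_init__(self) -> None:
        if not (self.t_start <= self.t_peak <= self.t_end):
            raise ValueError("event peak must lie inside its span")
        if not (self.detected_broad or self.detected_fr):
            raise ValueError("event must be detected in at least one band")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def bandpass_zero_phase(x: np.ndarray, band: tuple[float, float], fs: float,
                        order: int = 64) -> np.ndarray:
    """Zero-phase (forward-reverse) FIR band-pass, same length as input."""
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie inside (0, {fs / 2})")
    if len(x) <= 3 * order:
        raise ValueError("signal too short for the FIR filter order")
    taps = sps.firwin(order + 1, [lo, hi], pass_zero=False, fs=fs)
    return sps.filtfilt(taps, 1.0, x)


def compute_envelope(filtered: np.ndarray, fs: float) -> np.ndarray:
    """Cubic-spline envelope through the local maxima of the rectified signal.

    The envelope equals |filtered| exactly at the maxima; before the first
    and after the last maximum it is held at the nearest maximum's value.
    Signals with fewer than two local maxima fall back to |filtered|.
    """
    r = np.abs(filtered)
    peaks, _ = sps.find_peaks(r)
    if len(peaks) < 2:
        warnings.warn("fewer than 2 local maxima; envelope = rectified signal")
        return r
    env = np.empty_like(r)
    spline = CubicSpline(peaks, r[peaks])
    inner = slice(peaks[0], peaks[-1] + 1)
    env[inner] = spline(np.arange(peaks[0], peaks[-1] + 1))
    env[: peaks[0]] = r[peaks[0]]
    env[peaks[-1] + 1:] = r[peaks[-1]]
    return env


def compute_threshold(filtered: np.ndarray, fs: float,
                      cfg: DetectorConfig = DetectorConfig()) -> float:
    """Threshold = factor x median of per-epoch SDs of the filtered signal.

    Epochs are ``epoch_len`` long with step ``epoch_step``; a truncated
    epoch at the clip end is dropped from the median.
    """
    n_epoch = int(round(cfg.epoch_len * fs))
    n_step = int(round(cfg.epoch_step * fs))
    if len(filtered) < n_epoch:
        raise ValueError("signal shorter than one SD epoch")
    starts = np.arange(0, len(filtered) - n_epoch + 1, n_step)
    sds = np.array([filtered[s:s + n_epoch].std() for s in starts])
    thr = cfg.threshold_factor * float(np.median(sds))
    if thr == 0.0:
        warnings.warn("degenerate channel: all-constant signal, threshold 0")
    return thr


def _suprathreshold_runs(env: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal runs of env > thr as (start, stop) half-open sample indices."""
    above = env > thr
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_by_peak_distance(events: list[dict], gap_samples: float) -> list[dict]:
    """Single-linkage merge of events whose run peaks are < gap apart.

    Chains collapse: each event links to the previous member's original
    run peak, so a sequence of runs each < gap apart becomes one event.
    """
    if not events:
        return []
    events = sorted(events, key=lambda e: e["peak"])
    merged = [dict(events[0])]
    for ev in events[1:]:
        if ev["peak"] - merged[-1]["peak"] < gap_samples:
            merged[-1]["stop"] = max(merged[-1]["stop"], ev["stop"])
            merged[-1]["start"] = min(merged[-1]["start"], ev["start"])
            merged[-1]["peak"] = ev["peak"]  # chain onto the newest member
        else:
            merged.append(dict(ev))
    return merged


def detect_band_events(x: np.ndarray, band: tuple[float, float], fs: float,
                       cfg: DetectorConfig = DetectorConfig(),
                       channel: str = "ch") -> list[EventCandidate]:
    """Detect envelope-threshold events of one band on one channel.

    Boundaries are the threshold-crossing samples of the envelope; the
    duration rule is strict (an excursion of exactly the minimum duration
    is rejected); merging is single-linkage on peak distance.
    """
    filt = bandpass_zero_phase(x, band, fs, cfg.fir_order)
    env = compute_envelope(filt, fs)
    thr = compute_threshold(filt, fs, cfg)
    if thr == 0.0:
        return []
    runs = _suprathreshold_runs(env, thr)
    events = [
        {"start": a, "stop": b, "peak": a + int(np.argmax(env[a:b]))}
        for a, b in runs
    ]
    min_samples = cfg.min_duration * fs
    gap_samples = cfg.merge_gap * fs

    def long_enough(ev):
        return ev["stop"] - ev["start"] > min_samples

    if cfg.merge_before_duration_test:
        events = _merge_by_peak_distance(events, gap_samples)
        events = [ev for ev in events if long_enough(ev)]
    else:
        events = [ev for ev in events if long_enough(ev)]
        events = _merge_by_peak_distance(events, gap_samples)
    out = []
    for ev in events:
        peak = ev["start"] + int(np.argmax(env[ev["start"]:ev["stop"]]))
        out.append(EventCandidate(
            channel=channel,
            t_start=ev["start"] / fs,
            t_end=(ev["stop"] - 1) / fs,
            t_peak=peak / fs,
            peak_amplitude=float(env[peak]),
        ))
    return out


def detect_candidates(x: np.ndarray, fs: float,
                      cfg: DetectorConfig = DetectorConfig(),
                      channel: str = "ch") -> list[EventCandidate]:
    """Run the detector in the broad and fast-ripple bands and union events.

    A fast-ripple-band event that overlaps a broad-band event in span, or
    whose peak lies within the merge gap of one, marks that event as also
    fast-ripple-detected; otherwise it is appended as an extra candidate.
    """
    broad = detect_band_events(x, cfg.broad_band, fs, cfg, channel)
    fr = detect_band_events(x, cfg.fr_band, fs, cfg, channel)
    for ev in fr:
        ev.detected_broad = False
        ev.detected_fr = True
    out = list(broad)
    for fev in fr:
        matched = False
        for bev in out:
            if bev is fev:
                continue
            overlap = fev.t_start <= bev.t_end and bev.t_start <= fev.t_end
            close = abs(fev.t_peak - bev.t_peak) < cfg.merge_gap
            if overlap or close:
                bev.detected_fr = True
                matched = True
                break
        if not matched:
            out.append(fev)
    out.sort(key=lambda ev: ev.t_peak)
    return out


def candidates_to_frame(events: list[EventCandidate]) -> pd.DataFrame:
    """Serialize candidates to the report table layout."""
    return pd.DataFrame([{
        "channel": ev.channel,
        "t_start": ev.t_start,
        "t_end": ev.t_end,
        "t_peak": ev.t_peak,
        "peak_amp_uv": ev.peak_amplitude,
        "detected_broad": ev.detected_broad,
        "detected_fr": ev.detected_fr,
    } for ev in events])
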
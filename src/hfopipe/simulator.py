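"""Synthetic SEEG benchmark with ground-truth event logs.

Emulates the structure of the open simulated HFO benchmark: 2-minute
channels at 2048 Hz, each carrying 42 inserted events, 6 of each of the
7 types

    1 spike, 2 spike+R, 3 spike+FR, 4 spike+R+FR, 5 R, 6 FR, 7 R+FR

at a controlled signal-to-noise ratio.  The background is zero-mean pink
(1/f-power) noise normalized to 50 µV RMS, the standard surrogate for
interictal intracranial EEG.  Ripples are Gaussian-windowed sinusoids at
80-250 Hz lasting 30-100 ms, fast ripples at 250-500 Hz lasting 10-30 ms,
and spikes are biphasic transients of total width 30-70 ms with a sharp
exponential apex (the field-typical interictal spike morphology, which
gives the broadband time-frequency ridge classifiers rely on).

SNR definition: each oscillatory component is scaled so that the ratio of
its band-limited power to the band-limited background power over the event
span equals the requested dB value (the component's own band: 80-250 Hz
for R, 250-500 Hz for FR).  Spikes are not HFOs and are instead scaled to
a fixed visibility of 3x the background standard deviation.

Events are placed uniformly at random with >= 500 ms spacing so the 100 ms
scoring windows can never overlap.  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seeg_io import Recording

__all__ = [
    "SimConfig",
    "EVENT_TYPES",
    "event_type_flags",
    "make_background",
    "make_event_waveform",
    "insert_events",
    "simulate_channel",
    "simulate_benchmark",
    "generate_training_corpus",
    "balanced_flag_dataset",
]

logger = logging.getLogger(__name__)

EVENT_TYPES = {
    1: "spike",
    2: "spike+R",
    3: "spike+FR",
    4: "spike+R+FR",
    5: "R",
    6: "FR",
    7: "R+FR",
}

R_BAND = (80.0, 250.0)
FR_BAND = (250.0, 500.0)

# artifact classes used for classifier training corpora
ARTIFACT_TYPES = {"emg_burst", "sharp_transient"}


_SPIKE_TYPES = {"spike", "spike+R", "spike+FR", "spike+R+FR"}
_RIPPLE_TYPES = {"spike+R", "spike+R+FR", "R", "R+FR"}
_FR_TYPES = {"spike+FR", "spike+R+FR", "FR", "R+FR"}


def event_type_flags(type_name: str) -> dict[str, bool]:
    """Ground-truth per-flag labels of a simulated event class."""
    return {
        "artifact": type_name in ARTIFACT_TYPES,
        "spike": type_name in _SPIKE_TYPES,
        "ripple": type_name in _RIPPLE_TYPES,
        "fast_ripple": type_name in _FR_TYPES,
    }


@dataclass(frozen=True)
class SimConfig:
    n_channels: int = 4                 # channels per SNR level
    duration: float = 120.0             # s
    fs: float = 2048.0
    events_per_channel: int = 42        # 6 per type
    snr_levels: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0)  # dB
    background_rms: float = 50.0        # µV
    spike_visibility: float = 3.0       # x background SD
    min_spacing: float = 0.5            # s between event centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.events_per_channel % len(EVENT_TYPES):
            raise ValueError("events_per_channel must be divisible by 7")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration*fs must be integral")


def make_background(duration: float, fs: float, seed: int,
                    rms: float = 50.0) -> np.ndarray:
    """Pink (1/f power) noise, zero mean, RMS-normalized, seeded.

    Synthesized in the frequency domain: white Gaussian spectrum shaped by
    f^-1/2 in amplitude, flattened below 1 Hz to keep the variance finite.
    """
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** -0.5
    spec = shape * (rng.standard_normal(len(freqs))
                    + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    x *= rms / np.sqrt(np.mean(x ** 2))
    return x


def _gaussian_burst(freq: float, duration: float, fs: float,
                    phase: float) -> np.ndarray:
    """Sinusoid under a Gaussian window with FWHM = duration (centered)."""
    half = duration  # buffer of +-1 duration holds >99.9% of the energy
    t = np.arange(-half, half, 1.0 / fs)
    sigma = duration / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * freq * t + phase)


def _spike_waveform(width: float, fs: float) -> np.ndarray:
    """Biphasic interictal-type spike, unit peak, total width ``width`` s.

    Sharp positive apex with exponential flanks followed by a slower
    opposing Gaussian wave; the non-smooth apex carries the broadband
    spectral tail characteristic of real epileptiform spikes.
    """
    half = 1.5 * width
    t = np.arange(-half, half, 1.0 / fs)
    tau = width / 8.0
    apex = np.exp(-np.abs(t) / tau)
    slow = -0.45 * np.exp(-0.5 * ((t - 0.45 * width) / (0.35 * width)) ** 2)
    s = apex + slow
    # light smoothing (~0.5 ms) keeps the apex sharp but not a literal kink
    k = max(1, int(round(0.0005 * fs)))
    kernel = np.hanning(2 * k + 1)
    s = np.convolve(s, kernel / kernel.sum(), mode="same")
    return s / np.abs(s).max()


def make_event_waveform(type_id: int, fs: float, rng: np.random.Generator,
                        params: dict | None = None) -> dict:
    """Build the (unscaled) components of one event, centered on a common grid.

    Returns {"components": {name: (band|None, waveform)}, "params": {...}}.
    Component waveforms share a common center sample so they superpose at
    the event center; parameters are drawn from the class ranges unless
    pinned via ``params``.
    """
    if type_id not in EVENT_TYPES:
        raise ValueError(f"unknown event type {type_id}")
    name = EVENT_TYPES[type_id]
    params = dict(params or {})
    comps: dict[str, tuple[tuple[float, float] | None, np.ndarray]] = {}
    drawn: dict[str, float] = {}
    if name in _SPIKE_TYPES:
        w = params.get("spike_width", rng.uniform(0.030, 0.070))
        comps["spike"] = (None, _spike_waveform(w, fs))
        drawn["spike_width"] = w
    # duration floors enforce the working definition of an HFO: at least
    # four oscillation cycles within the envelope FWHM
    if name in _RIPPLE_TYPES:
        f = params.get("r_freq", rng.uniform(*R_BAND))
        d = params.get("r_duration", rng.uniform(max(0.030, 4.0 / f), 0.100))
        comps["ripple"] = (R_BAND, _gaussian_burst(f, d, fs,
                                                   rng.uniform(0, 2 * np.pi)))
        drawn.update(r_freq=f, r_duration=d)
    if name in _FR_TYPES:
        f = params.get("fr_freq", rng.uniform(*FR_BAND))
        d = params.get("fr_duration", rng.uniform(max(0.010, 4.0 / f), 0.030))
        comps["fast_ripple"] = (FR_BAND, _gaussian_burst(f, d, fs,
                                                         rng.uniform(0, 2 * np.pi)))
        drawn.update(fr_freq=f, fr_duration=d)
    return {"type": name, "components": comps, "params": drawn}


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean band-limited power of a segment via its periodogram."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / n ** 2
    spec[1:] *= 2.0  # fold negative frequencies
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[sel].sum())


def component_snr_db(signal_seg: np.ndarray, background_seg: np.ndarray,
                     fs: float, band: tuple[float, float]) -> float:
    """Realized SNR of an inserted component (same estimator used to scale it)."""
    p_ev = _band_power(signal_seg, fs, band)
    p_bg = _band_power(background_seg, fs, band)
    return 10.0 * np.log10(p_ev / p_bg)


def insert_events(background: np.ndarray, events: list[dict], snr_db: float,
                  fs: float, spike_visibility: float = 3.0,
                  min_estimation_window: float = 0.100
                  ) -> tuple[np.ndarray, pd.DataFrame]:
    """Scale and sum event components into the background; return the log.

    Each event dict needs keys ``center`` (s) and the output of
    make_event_waveform.  HFO components are scaled so that band-limited
    event power over the event span equals ``snr_db`` dB above band-limited
    background power over the same span (estimated on a window of at least
    ``min_estimation_window`` s for spectral stability); spikes are scaled
    to ``spike_visibility`` x the background SD.  Events whose waveforms
    would overlap a clip edge are skipped and logged.
    """
    x = background.copy()
    bg_sd = background.std()
    n = len(background)
    log_rows = []
    for ev in events:
        c = int(round(ev["center"] * fs))
        comps = ev["components"]
        max_half = max(len(w) for _, w in comps.values()) // 2
        if c - max_half < 0 or c + max_half >= n:
            logger.warning("event at %.3f s overlaps clip edge; skipped",
                           ev["center"])
            continue
        for comp_name, (band, w) in comps.items():
            half = len(w) // 2
            lo, hi = c - half, c - half + len(w)
            if band is None:  # spike: fixed visibility, not an HFO
                gain = spike_visibility * bg_sd / np.abs(w).max()
            else:
                n_est = max(len(w), int(round(min_estimation_window * fs)))
                e_lo = max(0, c - n_est // 2)
                e_hi = min(n, e_lo + n_est)
                seg_bg = background[e_lo:e_hi]
                w_padded = np.zeros(e_hi - e_lo)
                w_lo = lo - e_lo
                w_padded[max(0, w_lo):max(0, w_lo) + len(w)] = w[:len(w_padded) - max(0, w_lo)]
                p_bg = _band_power(seg_bg, fs, band)
                p_ev = _band_power(w_padded, fs, band)
                gain = np.sqrt(10.0 ** (snr_db / 10.0) * p_bg / p_ev)
            x[lo:hi] += gain * w
        log_rows.append({
            "center_s": ev["center"],
            "type": ev["type"],
            "type_id": {v: k for k, v in EVENT_TYPES.items()}[ev["type"]],
            "snr_db": snr_db,
            **ev["params"],
        })
    return x, pd.DataFrame(log_rows)


def _draw_event_times(n_events: int, duration: float, min_spacing: float,
                      rng: np.random.Generator, edge: float = 0.5,
                      max_tries: int = 20000) -> np.ndarray:
    """Uniform event centers with pairwise spacing >= min_spacing."""
    times: list[float] = []
    tries = 0
    while len(times) < n_events:
        t = rng.uniform(edge, duration - edge)
        if all(abs(t - u) >= min_spacing for u in times):
            times.append(t)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place events with the required spacing; "
                "reduce events_per_channel or min_spacing")
    return np.sort(np.array(times))


def simulate_channel(cfg: SimConfig, snr_db: float, seed: int,
                     channel: str = "sim") -> tuple[np.ndarray, pd.DataFrame]:
    """One benchmark channel: background plus 6 events of each of the 7 types."""
    rng = np.random.default_rng(seed)
    bg_seed = int(rng.integers(2 ** 31))
    background = make_background(cfg.duration, cfg.fs, bg_seed,
                                 rms=cfg.background_rms)
    per_type = cfg.events_per_channel // len(EVENT_TYPES)
    type_ids = np.repeat(list(EVENT_TYPES), per_type)
    rng.shuffle(type_ids)
    times = _draw_event_times(cfg.events_per_channel, cfg.duration,
                              cfg.min_spacing, rng)
    events = []
    for t, tid in zip(times, type_ids):
        ev = make_event_waveform(int(tid), cfg.fs, rng)
        ev["center"] = float(t)
        events.append(ev)
    x, log = insert_events(background, events, snr_db, cfg.fs,
                           spike_visibility=cfg.spike_visibility)
    log.insert(0, "channel", channel)
    return x, log


def simulate_benchmark(cfg: SimConfig) -> tuple[Recording, pd.DataFrame]:
    """Full benchmark dataset: cfg.n_channels channels per SNR level.

    Returns a Recording (channels named sim_<snr>dB_<k>) and the combined
    ground-truth log.  Deterministic given cfg.seed.
    """
    root = np.random.default_rng(cfg.seed)
    child_seeds = root.integers(2 ** 31, size=len(cfg.snr_levels) * cfg.n_channels)
    traces, names, logs = [], [], []
    i = 0
    for snr in cfg.snr_levels:
        for k in range(cfg.n_channels):
            name = f"sim_{snr:g}dB_{k}"
            x, log = simulate_channel(cfg, snr, int(child_seeds[i]), channel=name)
            traces.append(x)
            names.append(name)
            logs.append(log)
            i += 1
    rec = Recording(data=np.vstack(traces), fs=cfg.fs, channel_names=names,
                    montage="bipolar")
    return rec, pd.concat(logs, ignore_index=True)


# ---------------------------------------------------------------------------
# Classifier training corpora
# ---------------------------------------------------------------------------

def _emg_burst(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Broadband noise burst 100-300 ms (electromyographic artifact)."""
    from scipy import signal as sps

    dur = rng.uniform(0.100, 0.300)
    n = int(round(2 * dur * fs))
    noise = rng.standard_normal(n)
    sos = sps.butter(4, [30.0, min(500.0, fs / 2 * 0.95)], btype="bandpass",
                     fs=fs, output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    t = np.arange(n) / fs - dur
    sigma = dur / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = noise * np.exp(-0.5 * (t / sigma) ** 2)
    return w / np.abs(w).max()


def _sharp_transient(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Isolated very sharp biphasic transient (1-4 ms), flat spectrum."""
    w = rng.uniform(0.001, 0.004)
    return _spike_waveform(w, fs)


def _simulate_single_event_clip(type_name: str, snr_db: float, fs: float,
                                rng: np.random.Generator,
                                clip_len: float = 4.0,
                                background_rms: float = 50.0,
                                spike_visibility: float = 3.0
                                ) -> tuple[np.ndarray, float]:
    """Short clip carrying exactly one centered event; returns (clip, center)."""
    bg = make_background(clip_len, fs, int(rng.integers(2 ** 31)),
                         rms=background_rms)
    center = clip_len / 2
    if type_name in ARTIFACT_TYPES:
        w = (_emg_burst(fs, rng) if type_name == "emg_burst"
             else _sharp_transient(fs, rng))
        c = int(center * fs)
        half = len(w) // 2
        amp = (4.0 if type_name == "emg_burst" else 6.0) * bg.std()
        x = bg.copy()
        x[c - half:c - half + len(w)] += amp * w
        return x, center
    tid = {v: k for k, v in EVENT_TYPES.items()}[type_name]
    ev = make_event_waveform(tid, fs, rng)
    ev["center"] = center
    x, _ = insert_events(bg, [ev], snr_db, fs, spike_visibility=spike_visibility)
    return x, center


def iter_training_events(n_per_class: int, fs: float = 2048.0,
                         snr_db: float = 15.0, seed: int = 0,
                         raster: tuple[int, int] = (64, 64),
                         with_artifacts: bool = True):
    """Yield (scalogram, image, flags_row) for simulated single-event clips.

    For every event class (the 7 benchmark types plus, optionally, the two
    artifact classes: EMG-like broadband bursts and isolated sharp
    transients) this simulates ``n_per_class`` clips, runs the detector to
    localize the event (falling back to the known center when the detector
    misses, so corpora stay balanced), computes the scalogram and image,
    and labels all four flags from generator ground truth.  Streaming lets
    large corpora be consumed without holding every scalogram in memory.
    """
    from .detector import DetectorConfig, detect_candidates
    from .scalogram import ScalogramConfig, event_scalogram, render_event_image

    rng = np.random.default_rng(seed)
    sg_cfg = ScalogramConfig(raster=raster)
    det_cfg = DetectorConfig()
    classes = list(EVENT_TYPES.values())
    if with_artifacts:
        classes += sorted(ARTIFACT_TYPES)
    for cls in classes:
        for _ in range(n_per_class):
            x, center = _simulate_single_event_clip(cls, snr_db, fs, rng)
            cands = detect_candidates(x, fs, det_cfg)
            if cands:
                t_peak = min(cands, key=lambda ev: abs(ev.t_peak - center)).t_peak
                if abs(t_peak - center) > 0.1:
                    t_peak = center
            else:
                t_peak = center
            sg = event_scalogram(x, fs, t_peak, sg_cfg)
            img = render_event_image(sg, sg_cfg)
            yield sg, img, {"class": cls, **event_type_flags(cls)}


def generate_training_corpus(n_per_class: int, fs: float = 2048.0,
                             snr_db: float = 15.0, seed: int = 0,
                             raster: tuple[int, int] = (64, 64),
                             with_artifacts: bool = True,
                             keep_scalograms: bool = True):
    """Materialize the labeled corpus of iter_training_events.

    Returns (scalograms, images, flags_frame); ``scalograms`` is None when
    keep_scalograms is False (the memory-friendly mode for large corpora).
    """
    scalograms, images, rows = [], [], []
    for sg, img, row in iter_training_events(
            n_per_class, fs=fs, snr_db=snr_db, seed=seed, raster=raster,
            with_artifacts=with_artifacts):
        if keep_scalograms:
            scalograms.append(sg)
        images.append(img)
        rows.append(row)
    return (scalograms if keep_scalograms else None, images,
            pd.DataFrame(rows))


def balanced_flag_dataset(images: list, flags: pd.DataFrame, flag: str,
                          n_per_class: int, seed: int = 0):
    """Balanced positive/negative image set for one binary flag.

    Returns (X, y): X is (2*n, H, W), y boolean.  Raises if either class
    has fewer than ``n_per_class`` members.
    """
    rng = np.random.default_rng(seed)
    y_all = flags[flag].to_numpy(dtype=bool)
    pos = np.flatnonzero(y_all)
    neg = np.flatnonzero(~y_all)
    if len(pos) < n_per_class or len(neg) < n_per_class:
        raise ValueError(f"not enough examples to balance flag {flag!r}")
    sel = np.concatenate([rng.choice(pos, n_per_class, replace=False),
                          rng.choice(neg, n_per_class, replace=False)])
    X = np.stack([images[i].pixels for i in sel])
    y = y_all[sel]
    return X, y
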
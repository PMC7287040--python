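"""Time-frequency representation of candidate events.

Each candidate is epoched in a 600 ms window centered on its envelope
peak (with >= 200 ms padding each side against edge effects) and mapped
through a Morlet wavelet transform at integer frequencies 1-500 Hz.  The
wavelet family is constant-Q: the mother wavelet at 1 Hz has a time-domain
Gaussian full-width-at-half-maximum of 3 s, so the wavelet at frequency f
has FWHM 3/f s (about 8 cycles at every frequency).  Before the transform
the raw trace is whitened with a first-order 8-490 Hz Butterworth filter
that suppresses the 1/f background while keeping the low-frequency shape
of interictal spikes.

The transform is implemented as an FFT-domain Gaussian filter bank: the
wavelet's Gaussian time envelope corresponds to a Gaussian frequency
response of standard deviation sigma_f = f * 2*sqrt(2*ln 2) / (3 * 2*pi),
and one FFT of the epoch serves all 500 center frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

__all__ = [
    "ScalogramConfig",
    "Scalogram",
    "EventImage",
    "prefilter_broadband",
    "extract_epoch",
    "morlet_scalogram",
    "render_event_image",
    "event_scalogram",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class ScalogramConfig:
    window: float = 0.600          # s, analysis window centered on t_peak
    crop: float = 0.200            # s, central window kept for classification
    pad: float = 0.200             # s, extra signal each side of the window
    f_lo: float = 1.0
    f_hi: float = 500.0
    f_step: float = 1.0
    mother_fwhm: float = 3.0       # s at 1 Hz; FWHM(f) = mother_fwhm / f
    prefilter_band: tuple[float, float] = (8.0, 490.0)
    smooth_sigma: tuple[float, float] = (1.0, 2.0)  # (freq bins, time samples)
    raster: tuple[int, int] = (224, 224)
    log_eps_rel: float = 1e-12     # epsilon floor relative to max power


@dataclass
class Scalogram:
    """Wavelet power of one event window: power[n_freqs, n_times]."""

    power: np.ndarray
    freqs: np.ndarray          # Hz, ascending
    times: np.ndarray          # s relative to clip start
    log_transformed: bool = False

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.freqs), len(self.times)):
            raise ValueError("power shape must be (n_freqs, n_times)")
        if not self.log_transformed and (self.power < 0).any():
            raise ValueError("raw wavelet power must be non-negative")


@dataclass
class EventImage:
    """Rasterized classifier input: central-crop log power scaled to [0,1]."""

    pixels: np.ndarray
    event: object = None  # provenance: the EventCandidate it came from

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixels).all():
            raise ValueError("event image must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("event image must lie in [0, 1]")


def prefilter_broadband(x: np.ndarray, fs: float,
                        band: tuple[float, float] = (8.0, 490.0)) -> np.ndarray:
    """Zero-phase first-order Butterworth band-pass (spectrum whitening).

    First order keeps the roll-off shallow so spike morphology below the
    pass band survives largely intact.
    """
    if fs < 2 * band[1]:
        raise ValueError(f"sampling rate {fs} cannot represent {band[1]} Hz")
    sos = sps.butter(1, band, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def extract_epoch(x: np.ndarray, fs: float, t_center: float,
                  cfg: ScalogramConfig = ScalogramConfig()) -> np.ndarray:
    """Slice the padded analysis window around t_center, mirror-padding at edges."""
    half = (cfg.window / 2 + cfg.pad)
    n_half = int(round(half * fs))
    c = int(round(t_center * fs))
    lo, hi = c - n_half, c + n_half
    pad_lo, pad_hi = max(0, -lo), max(0, hi - len(x))
    seg = x[max(0, lo):min(len(x), hi)]
    if pad_lo or pad_hi:
        warnings.warn("event window exceeds clip bounds; mirror-padded")
        seg = np.pad(seg, (pad_lo, pad_hi), mode="reflect")
    return seg


def morlet_scalogram(epoch: np.ndarray, fs: float,
                     cfg: ScalogramConfig = ScalogramConfig(),
                     t_center: float = 0.0) -> Scalogram:
    """Constant-Q Morlet wavelet power of the epoch, cropped to the window.

    The epoch must carry cfg.pad seconds of guard signal each side of the
    600 ms analysis window; power is computed over the whole padded epoch
    and cropped to the window, discarding wavelet edge effects.
    """
    epoch = np.asarray(epoch, dtype=float)
    n = len(epoch)
    freqs = np.arange(cfg.f_lo, cfg.f_hi + cfg.f_step / 2, cfg.f_step)
    X = np.fft.fft(epoch)
    f_axis = np.fft.fftfreq(n, d=1.0 / fs)
    power = np.empty((len(freqs), n))
    for i, f0 in enumerate(freqs):
        sigma_t = (cfg.mother_fwhm / f0) / _FWHM_TO_SIGMA
        sigma_f = 1.0 / (2.0 * np.pi * sigma_t)
        # analytic filter: Gaussian around +f0, negative frequencies zeroed
        H = np.exp(-0.5 * ((f_axis - f0) / sigma_f) ** 2)
        H[f_axis < 0] = 0.0
        w = np.fft.ifft(X * 2.0 * H)
        power[i] = np.abs(w) ** 2
    n_win = int(round(cfg.window * fs))
    start = (n - n_win) // 2
    # float32 halves the footprint of batch processing; the dynamic range
    # of wavelet power is far below float32 limits after the epsilon floor
    power = power[:, start:start + n_win].astype(np.float32)
    times = t_center - cfg.window / 2 + np.arange(n_win) / fs
    return Scalogram(power=power, freqs=freqs, times=times)


def render_event_image(sg: Scalogram, cfg: ScalogramConfig = ScalogramConfig(),
                       event: object = None) -> EventImage:
    """Log-transform, smooth, crop to the central window and rasterize.

    Produces the classifier input: log10 power with a relative epsilon
    floor, light 2-D Gaussian smoothing, the central ``cfg.crop`` seconds,
    min-max scaling to [0,1], and resampling to the configured raster.
    """
    if sg.log_transformed:
        raise ValueError("scalogram already log-transformed")
    from skimage.transform import resize

    pmax = sg.power.max()
    if pmax == 0:
        warnings.warn("all-zero scalogram; rendering all-zero image")
        return EventImage(pixels=np.zeros(cfg.raster), event=event)
    logp = np.log10(sg.power + cfg.log_eps_rel * pmax)
    logp = ndimage.gaussian_filter(logp, sigma=cfg.smooth_sigma)
    n_t = logp.shape[1]
    n_crop = int(round(n_t * cfg.crop / cfg.window))
    start = (n_t - n_crop) // 2
    cropped = logp[:, start:start + n_crop]
    rng = cropped.max() - cropped.min()
    scaled = np.zeros_like(cropped) if rng == 0 else (cropped - cropped.min()) / rng
    pixels = resize(scaled, cfg.raster, order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    return EventImage(pixels=np.clip(pixels, 0.0, 1.0), event=event)


def event_scalogram(x: np.ndarray, fs: float, t_peak: float,
                    cfg: ScalogramConfig = ScalogramConfig()) -> Scalogram:
    """Full per-event path: whiten the raw trace, epoch it, transform it."""
    whitened = prefilter_broadband(x, fs, cfg.prefilter_band)
    epoch = extract_epoch(whitened, fs, t_peak, cfg)
    return morlet_scalogram(epoch, fs, cfg, t_center=t_peak)


def save_event_images(images: list[EventImage], outdir, prefix: str = "event"):
    """Export event images as 8-bit grayscale PNGs with an index TSV.

    Returns the index DataFrame (columns: image_id, filename, t_peak,
    channel where available from provenance).
    """
    from pathlib import Path

    import imageio.v3 as iio
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        fname = f"{prefix}_{i:05d}.png"
        iio.imwrite(outdir / fname,
                    np.round(img.pixels * 255).astype(np.uint8))
        row = {"image_id": i, "filename": fname}
        ev = img.event
        if ev is not None:
            row["channel"] = getattr(ev, "channel", None)
            row["t_peak"] = getattr(ev, "t_peak", None)
        rows.append(row)
    index = pd.DataFrame(rows)
    index.to_csv(outdir / f"{prefix}_index.tsv", sep="\t", index=False)
    return index
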
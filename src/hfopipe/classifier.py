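"""Sequential event labeling: artifact -> spike -> ripple -> fast ripple.

Each candidate event receives four binary flags in that order; a positive
artifact decision finalizes the label (artifact dominance).  The flag
combination maps onto 9 categories: artifact, spike, R, FR, spike+R,
spike+FR, spike+R+FR, R+FR, and other (all four flags negative; treated
as artifact downstream).  Candidates whose category is neither artifact
nor other, and which carry an oscillatory (R or FR) flag, are quality
HFOs (qHFOs) — a pure spike is an interictal discharge, not an
oscillation, so it does not enter HFO rates.

Two interchangeable classifier backends implement the same contract:

* a deterministic reference classifier operating directly on the event
  scalogram, encoding the visual rules of time-frequency reading: true
  HFOs appear as isolated band-limited blobs, spikes as an elongated
  low-frequency-anchored ridge, and artifacts as a broadband column;
* a small trainable convolutional image classifier (seeded random
  convolutional feature bank + logistic head) trained per flag with
  SGD (momentum 0.9, minibatch 32, at most 3 epochs, learning rate 1e-4,
  cross-entropy loss).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .scalogram import EventImage, Scalogram

__all__ = [
    "CATEGORIES",
    "EventLabel",
    "flags_to_category",
    "is_qhfo",
    "BlobClassifierConfig",
    "reference_blob_classifier",
    "ReferenceClassifier",
    "SmallConvNet",
    "train_image_classifier",
    "ImageClassifierModel",
    "classify_events",
    "filter_qhfo",
]

CATEGORIES = (
    "artifact", "spike", "R", "FR",
    "spike+R", "spike+FR", "spike+R+FR", "R+FR", "other",
)

FLAG_ORDER = ("artifact", "spike", "ripple", "fast_ripple")


def flags_to_category(artifact: bool, spike: bool, ripple: bool,
                      fast_ripple: bool) -> str:
    """Map the four sequential binary flags to the 9-way category.

    Artifact dominates (sequence order); all-negative maps to "other".
    Total over all 16 flag combinations.
    """
    if artifact:
        return "artifact"
    parts = []
    if spike:
        parts.append("spike")
    if ripple:
        parts.append("R")
    if fast_ripple:
        parts.append("FR")
    return "+".join(parts) if parts else "other"


def is_qhfo(category: str, ripple: bool, fast_ripple: bool,
            require_oscillation: bool = True) -> bool:
    """Quality-HFO rule: not artifact/other and, by default, an R or FR flag."""
    if category in ("artifact", "other"):
        return False
    if require_oscillation:
        return ripple or fast_ripple
    return True


@dataclass
class EventLabel:
    artifact: bool
    spike: bool
    ripple: bool
    fast_ripple: bool
    category: str = field(init=False)
    qhfo: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.artifact:
            # sequence order: a positive artifact decision finalizes the label
            self.spike = self.ripple = self.fast_ripple = False
        self.category = flags_to_category(self.artifact, self.spike,
                                          self.ripple, self.fast_ripple)
        self.qhfo = is_qhfo(self.category, self.ripple, self.fast_ripple)


# ---------------------------------------------------------------------------
# Deterministic reference classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobClassifierConfig:
    """Thresholds of the rule-based scalogram reader.

    All scores are log10-power contrasts ("decades") of the event center
    against the per-row temporal median, the local background reference;
    the 1/f spectrum cancels row by row.  Defaults were calibrated once on
    simulated development corpora.
    """

    central_window: float = 0.200     # s; per-row peak-activation window
    mean_window: float = 0.100        # s; sustained-activation window
    profile_smooth: float = 2.0       # Gaussian sigma along frequency, bins
    # band-limited blob tests (ripple / fast ripple)
    blob_height: float = 1.6          # decades; peak of the per-row activation
    blob_prominence: float = 0.5      # decades; isolation of the peak
    r_band: tuple[float, float] = (78.0, 252.0)
    fr_band: tuple[float, float] = (253.0, 500.0)
    # spike test: sustained low-frequency ridge at the event center
    spike_band: tuple[float, float] = (12.0, 40.0)
    spike_window: float = 0.060       # s; tight window around the apex
    spike_z: float = 0.18             # decades (mean contrast, so lower scale)
    # artifact tests.  An EMG-like burst is high-frequency activation
    # sustained far longer than any HFO blob; a sharp transient is a
    # brief broadband column whose per-row power peaks line up in time
    # across the whole spectrum.
    column_hi_band: tuple[float, float] = (300.0, 500.0)
    emg_hi_z: float = 0.9             # decades in the high band
    emg_level: float = 0.5            # decades; width is measured at this level
    emg_min_width: float = 0.080      # s of sustained high-band activation
    sharp_hi_z: float = 1.2           # decades in the high band
    sharp_max_width: float = 0.040    # s; column brevity at level 0.6
    sharp_band: tuple[float, float] = (100.0, 490.0)
    sharp_aligned_frac: float = 0.80  # fraction of rows peaking at the center
    sharp_tolerance: float = 0.012    # s; per-row peak alignment tolerance
    sharp_min_contrast: float = 1.0   # decades; mean row contrast in the column
    column_window: float = 0.010      # s; half-width of the center column
    alignment_window: float = 0.400   # s; search span for per-row peaks


def _log_power(sg: Scalogram) -> np.ndarray:
    eps = 1e-12 * max(sg.power.max(), 1e-300)
    return sg.power if sg.log_transformed else np.log10(sg.power + eps)


def _central_slice(n_t: int, window: float, total: float) -> slice:
    n_c = min(max(int(round(n_t * window / total)), 1), n_t)
    start = (n_t - n_c) // 2
    return slice(start, start + n_c)


def _row_reference(logp: np.ndarray) -> np.ndarray:
    """Per-row background level: the temporal median over the full window.

    The median is robust to the centered event (which occupies well under
    half the window at every frequency of interest) and is a far stabler
    estimate than the window edges alone, whose few independent samples at
    low frequencies dominate the noise of any contrast measure.
    """
    return np.median(logp, axis=1)


def _window_span(sg: Scalogram) -> float:
    return float(sg.times[-1] - sg.times[0]) or 0.6


def _activation_profile(sg: Scalogram, cfg: BlobClassifierConfig,
                        sustained: bool = False) -> np.ndarray:
    """Per-frequency event contrast, in log10 decades above background.

    Peak mode (default): per-row maximum log power over the central window
    minus the row's edge median — sensitive to brief band-limited blobs.
    Sustained mode: per-row mean over a shorter central window — sensitive
    to activity that fills the window (EMG bursts), with far lower noise.
    """
    logp = _log_power(sg)
    span = _window_span(sg)
    ref = _row_reference(logp)
    if sustained:
        sl = _central_slice(logp.shape[1], cfg.mean_window, span)
        m = logp[:, sl].mean(axis=1) - ref
    else:
        sl = _central_slice(logp.shape[1], cfg.central_window, span)
        m = logp[:, sl].max(axis=1) - ref
    return ndimage.gaussian_filter1d(m, sigma=cfg.profile_smooth)


def _band_time_profile(sg: Scalogram, band: tuple[float, float],
                       cfg: BlobClassifierConfig) -> np.ndarray:
    """Band-averaged log-power time course, referenced to its temporal median.

    Averaging log power across the band's rows before any temporal
    reduction suppresses the per-row noise inflation, so coherent
    structures (a spike ridge, an artifact column) stand out.
    """
    logp = _log_power(sg)
    sel = (sg.freqs >= band[0]) & (sg.freqs <= band[1])
    prof = logp[sel].mean(axis=0)
    return prof - np.median(prof)


def _band_time_contrast(sg: Scalogram, band: tuple[float, float],
                        window: float, cfg: BlobClassifierConfig,
                        reduce: str = "max") -> float:
    """Temporal contrast of the band-averaged log power at the event center."""
    prof = _band_time_profile(sg, band, cfg)
    sl = _central_slice(len(prof), window, _window_span(sg))
    if reduce == "mean":
        return float(prof[sl].mean())
    return float(prof[sl].max())


def _band_activation_width(sg: Scalogram, band: tuple[float, float],
                           level: float, cfg: BlobClassifierConfig,
                           search_window: float = 0.400) -> float:
    """Seconds (within the central search window) the band stays above level."""
    prof = _band_time_profile(sg, band, cfg)
    sl = _central_slice(len(prof), search_window, _window_span(sg))
    dt = _window_span(sg) / max(len(prof) - 1, 1)
    return float((prof[sl] > level).sum() * dt)


def _column_alignment(sg: Scalogram, cfg: BlobClassifierConfig
                      ) -> tuple[float, float]:
    """(aligned fraction, mean column contrast) of the broadband rows.

    For every frequency row in ``sharp_band``, finds the time of its power
    maximum within the central search window; a sharp transient drives all
    rows to peak at the window center simultaneously.  Also returns the
    mean contrast (decades over the row median) inside the narrow center
    column, which a genuine broadband transient keeps high at every row.
    """
    logp = _log_power(sg)
    sel = (sg.freqs >= cfg.sharp_band[0]) & (sg.freqs <= cfg.sharp_band[1])
    sub = logp[sel]
    n_t = sub.shape[1]
    span = _window_span(sg)
    center = n_t // 2
    sl = _central_slice(n_t, cfg.alignment_window, span)
    argmax = sub[:, sl].argmax(axis=1) + sl.start
    tol = max(int(round(cfg.sharp_tolerance / span * n_t)), 1)
    aligned = float((np.abs(argmax - center) <= tol).mean())
    n_col = max(int(round(cfg.column_window / span * n_t)), 1)
    col = sub[:, center - n_col:center + n_col + 1]
    contrast = float((col.max(axis=1) - np.median(sub, axis=1)).mean())
    return aligned, contrast


def _longest_contiguous_hz(mask: np.ndarray, freqs: np.ndarray) -> float:
    if not mask.any():
        return 0.0
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    best = 0.0
    for a, b in zip(edges[::2], edges[1::2]):
        best = max(best, freqs[b - 1] - freqs[a])
    return best


def _band_blob(m: np.ndarray, freqs: np.ndarray, band: tuple[float, float],
               cfg: BlobClassifierConfig) -> bool:
    """Is there an isolated (high, prominent) activation peak in the band?"""
    padded = np.concatenate(([m[0] - 1.0], m, [m[-1] - 1.0]))  # boundary maxima
    peaks, props = sps.find_peaks(padded, height=cfg.blob_height,
                                  prominence=0.0)
    for p, h, prom in zip(peaks, props["peak_heights"], props["prominences"]):
        f = freqs[min(max(p - 1, 0), len(freqs) - 1)]
        if band[0] <= f <= band[1] and min(prom, h) > cfg.blob_prominence:
            return True
    return False


def reference_blob_classifier(sg: Scalogram,
                              cfg: BlobClassifierConfig = BlobClassifierConfig()
                              ) -> dict[str, bool]:
    """Rule-based four-flag decision on one (un-cropped) event scalogram.

    Decisions run in sequence order; a positive artifact decision
    short-circuits the remaining flags.

    artifact — either signature of a non-physiological event: a broadband
    column (high contrast both above 300 Hz and in the 100-200 Hz
    mid-band, with no low-frequency spike ridge: the sharp-transient
    pattern), or sustained broadband activation spanning a wide contiguous
    frequency range (the EMG-burst pattern).
    spike — a coherent low-frequency ridge: high band-averaged contrast
    over 10-40 Hz in a tight window around the event apex.
    ripple / fast ripple — an isolated, prominent peak of the per-row
    activation profile inside the 80-250 / 250-500 Hz band (the
    band-limited blob that distinguishes a true oscillation).
    """
    if sg.power.max() == 0:
        return {k: False for k in FLAG_ORDER}
    freqs = sg.freqs
    spike_score = _band_time_contrast(sg, cfg.spike_band, cfg.spike_window,
                                      cfg, reduce="mean")
    spike = bool(spike_score > cfg.spike_z)

    col_hi = _band_time_contrast(sg, cfg.column_hi_band, cfg.mean_window, cfg)
    emg_like = (
        col_hi > cfg.emg_hi_z
        and _band_activation_width(sg, cfg.column_hi_band, cfg.emg_level,
                                   cfg) > cfg.emg_min_width)
    aligned, col_contrast = _column_alignment(sg, cfg)
    sharp_column = (
        col_hi > cfg.sharp_hi_z
        and aligned > cfg.sharp_aligned_frac
        and col_contrast > cfg.sharp_min_contrast
        and _band_activation_width(sg, cfg.column_hi_band, 0.6, cfg)
        < cfg.sharp_max_width)
    if sharp_column or emg_like:
        return {"artifact": True, "spike": False, "ripple": False,
                "fast_ripple": False}

    m = _activation_profile(sg, cfg)
    ripple = _band_blob(m, freqs, cfg.r_band, cfg)
    fast_ripple = _band_blob(m, freqs, cfg.fr_band, cfg)
    return {"artifact": False, "spike": spike, "ripple": ripple,
            "fast_ripple": fast_ripple}


@dataclass
class ReferenceClassifier:
    """Deterministic classifier backend operating on scalograms."""

    cfg: BlobClassifierConfig = field(default_factory=BlobClassifierConfig)
    kind: str = "reference"

    def predict_flags(self, sg: Scalogram, image: EventImage | None = None
                      ) -> dict[str, bool]:
        return reference_blob_classifier(sg, self.cfg)


# ---------------------------------------------------------------------------
# Small trainable convolutional classifier
# ---------------------------------------------------------------------------

class SmallConvNet:
    """Binary image classifier: fixed conv feature bank + logistic head.

    Transfer-learning style at desk scale: the convolutional stage is a
    seeded random filter bank (ReLU, average pooling) plus global
    row/column average-pooling profiles, none of it trained; only the
    logistic output layer learns, with plain SGD: momentum 0.9, minibatch
    32, cross-entropy loss, learning rate 1e-4 and at most 3 epochs.  The
    feature normalization constant ``feature_scale`` sets the effective
    step size of that schedule.  Deterministic given the seed.
    """

    def __init__(self, input_shape: tuple[int, int], seed: int = 0,
                 n_filters: int = 16, kernel: int = 5, stride: int = 2,
                 pool: int = 4, feature_scale: float = 30.0):
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.filters = rng.standard_normal((n_filters, kernel, kernel))
        self.filters /= kernel  # keep feature scale O(1)
        self.kernel, self.stride, self.pool = kernel, stride, pool
        self.feature_scale = feature_scale
        self.mu: np.ndarray | None = None
        self.sd: np.ndarray | None = None
        self.w: np.ndarray | None = None
        self.b: float = 0.0

    # -- feature extraction -------------------------------------------------
    def _conv_features(self, X: np.ndarray) -> np.ndarray:
        # per-image standardization (normalization layer)
        X = (X - X.mean(axis=(1, 2), keepdims=True)) / (
            X.std(axis=(1, 2), keepdims=True) + 1e-9)
        k, s, p = self.kernel, self.stride, self.pool
        win = np.lib.stride_tricks.sliding_window_view(X, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (n, H', W', k, k)
        maps = np.einsum("nhwij,fij->nfhw", win, self.filters)
        maps = np.maximum(maps, 0.0)
        h, w = maps.shape[2] // p * p, maps.shape[3] // p * p
        maps = maps[:, :, :h, :w]
        pooled = maps.reshape(maps.shape[0], maps.shape[1],
                              h // p, p, w // p, p).mean(axis=(3, 5))
        # global average-pooling profiles along each image axis
        rows = X.mean(axis=2)
        cols = X.mean(axis=1)
        return np.concatenate(
            [pooled.reshape(X.shape[0], -1), rows, cols], axis=1)

    def features(self, X: np.ndarray, fit_scaler: bool = False) -> np.ndarray:
        F = self._conv_features(np.asarray(X, dtype=float))
        if fit_scaler:
            self.mu = F.mean(axis=0)
            self.sd = F.std(axis=0) + 1e-9
        if self.mu is None:
            raise RuntimeError("model not trained")
        return (F - self.mu) / self.sd * self.feature_scale

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, lr: float = 1e-4,
            momentum: float = 0.9, batch_size: int = 32,
            epochs: int = 3) -> None:
        y = np.asarray(y, dtype=float)
        F = self.features(X, fit_scaler=True)
        rng = np.random.default_rng(self.seed + 1)
        n, d = F.shape
        self.w = np.zeros(d)
        self.b = 0.0
        vw = np.zeros(d)
        vb = 0.0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                z = F[idx] @ self.w + self.b
                p = 1.0 / (1.0 + np.exp(-z))
                err = p - y[idx]  # gradient of mean cross-entropy
                gw = F[idx].T @ err / len(idx)
                gb = err.mean()
                vw = momentum * vw - lr * gw
                vb = momentum * vb - lr * gb
                self.w += vw
                self.b += vb

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.w is None:
            raise RuntimeError("model not trained")
        F = self.features(X)
        return 1.0 / (1.0 + np.exp(-(F @ self.w + self.b)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X) > 0.5


@dataclass
class TrainedFlagModel:
    flag: str
    net: SmallConvNet
    seed: int
    validation_accuracy: float
    n_train: int = 0
    n_val: int = 0


def train_image_classifier(X: np.ndarray, y: np.ndarray, flag: str = "ripple",
                           split: float = 0.8, seed: int = 0,
                           epochs: int = 3, lr: float = 1e-4,
                           batch_size: int = 32,
                           momentum: float = 0.9) -> TrainedFlagModel:
    """Train one binary flag classifier on labeled event images.

    X is (n, H, W) in [0,1], y boolean.  The data are split (seeded,
    stratified) into ``split`` training and 1-split validation; held-out
    accuracy is recorded in the returned model.  Deterministic given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(X) == 0:
        raise ValueError("empty dataset")
    if y.all() or (~y).all():
        raise ValueError(f"dataset for flag {flag!r} contains a single class")
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(split * len(idx)))
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx))
    net = SmallConvNet(input_shape=X.shape[1:], seed=seed)
    net.fit(X[train_idx], y[train_idx], lr=lr, momentum=momentum,
            batch_size=batch_size, epochs=epochs)
    if len(val_idx):
        acc = float((net.predict(X[val_idx]) == y[val_idx]).mean())
    else:
        acc = float("nan")
    return TrainedFlagModel(flag=flag, net=net, seed=seed,
                            validation_accuracy=acc,
                            n_train=len(train_idx), n_val=len(val_idx))


@dataclass
class ImageClassifierModel:
    """Trained four-flag backend: one SmallConvNet per flag, sequence order."""

    models: dict[str, TrainedFlagModel]
    kind: str = "cnn"

    def __post_init__(self) -> None:
        missing = [f for f in FLAG_ORDER if f not in self.models]
        if missing:
            raise ValueError(f"missing flag models: {missing}")

    def predict_flags(self, sg: Scalogram | None,
                      image: EventImage | None = None) -> dict[str, bool]:
        if image is None:
            raise ValueError("image classifier needs an EventImage per event")
        shape = self.models[FLAG_ORDER[0]].net.input_shape
        if image.pixels.shape != shape:
            raise ValueError(
                f"image raster {image.pixels.shape} does not match model {shape}")
        X = image.pixels[None]
        return {f: bool(self.models[f].net.predict(X)[0]) for f in FLAG_ORDER}


# ---------------------------------------------------------------------------
# Batch labeling and qHFO filtering
# ---------------------------------------------------------------------------

def classify_events(scalograms: list[Scalogram], model,
                    images: list[EventImage] | None = None) -> list[EventLabel]:
    """Label a batch of events, order preserved.

    ``model`` is any backend with predict_flags (reference or trained).
    Artifact precedence is applied when the label is built.
    """
    if images is None:
        images = [None] * len(scalograms)
    if len(images) != len(scalograms):
        raise ValueError("one image per scalogram required")
    labels = []
    for sg, img in zip(scalograms, images):
        flags = model.predict_flags(sg, img)
        labels.append(EventLabel(**flags))
    return labels


def labels_to_frame(labels: list[EventLabel]) -> "pd.DataFrame":
    """Serialize labels to the report table layout (one row per event)."""
    import pandas as pd

    return pd.DataFrame([{
        "event_id": i, "artifact": l.artifact, "spike": l.spike,
        "ripple": l.ripple, "fast_ripple": l.fast_ripple,
        "category": l.category, "qhfo": l.qhfo} for i, l in enumerate(labels)])


def save_model(model: ImageClassifierModel, path) -> None:
    """Persist a trained four-flag model (weights + metadata) as one .npz."""
    arrays, meta = {}, {}
    for fl, m in model.models.items():
        net = m.net
        arrays.update({f"{fl}__filters": net.filters, f"{fl}__w": net.w,
                       f"{fl}__mu": net.mu, f"{fl}__sd": net.sd})
        meta[fl] = {"b": net.b, "seed": m.seed,
                    "validation_accuracy": m.validation_accuracy,
                    "n_train": m.n_train, "n_val": m.n_val,
                    "input_shape": net.input_shape,
                    "kernel": net.kernel, "stride": net.stride,
                    "pool": net.pool, "feature_scale": net.feature_scale}
    import json

    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path) -> ImageClassifierModel:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    models = {}
    for fl, m in meta.items():
        net = SmallConvNet(input_shape=tuple(m["input_shape"]),
                           seed=m["seed"],
                           n_filters=data[f"{fl}__filters"].shape[0],
                           kernel=m["kernel"], stride=m["stride"],
                           pool=m["pool"], feature_scale=m["feature_scale"])
        net.filters = data[f"{fl}__filters"]
        net.w = data[f"{fl}__w"]
        net.mu = data[f"{fl}__mu"]
        net.sd = data[f"{fl}__sd"]
        net.b = m["b"]
        models[fl] = TrainedFlagModel(
            flag=fl, net=net, seed=m["seed"],
            validation_accuracy=m["validation_accuracy"],
            n_train=m["n_train"], n_val=m["n_val"])
    return ImageClassifierModel(models=models)


def filter_qhfo(labels: list[EventLabel], subset: str | None = None) -> list[int]:
    """Indices of quality HFOs, optionally restricted to a sub-population.

    subset: None (all qHFOs), "with_spike", "without_spike", "with_fr",
    "without_fr" — the sub-populations compared in SOZ concordance.
    """
    if subset not in (None, "with_spike", "without_spike",
                      "with_fr", "without_fr"):
        raise ValueError(f"unknown qHFO subset {subset!r}")
    out = []
    for i, lab in enumerate(labels):
        if not lab.qhfo:
            continue
        if subset == "with_spike" and not lab.spike:
            continue
        if subset == "without_spike" and lab.spike:
            continue
        if subset == "with_fr" and not lab.fast_ripple:
            continue
        if subset == "without_fr" and lab.fast_ripple:
            continue
        out.append(i)
    return out
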
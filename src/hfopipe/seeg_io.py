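"""Reading, writing and preprocessing of SEEG recordings and volumes.

Recordings are exchanged as EDF, electrode contacts as TSV
(columns: electrode, index, x_mm, y_mm, z_mm), volumes as NIfTI-1.
All signals are held in microvolts; the extreme-amplitude screening rule
downstream is stated in µV, so the unit is fixed at read time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ContactTable",
    "BipolarChannel",
    "VolumeImage",
    "FormatError",
    "UnsupportedInputError",
    "read_recording",
    "write_recording",
    "read_contacts",
    "read_volume",
    "write_volume",
    "make_bipolar",
    "notch_filter",
]


class FormatError(ValueError):
    """A file could not be parsed as its declared format."""


class UnsupportedInputError(ValueError):
    """Input is well formed but outside what the pipeline supports."""


@dataclass
class Recording:
    """Multichannel time series in µV.

    data has shape (n_channels, n_samples); fs is the sampling rate in Hz.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    montage: str = "monopolar"  # "monopolar" | "bipolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.montage not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.n_samples / self.fs


@dataclass
class ContactTable:
    """Electrode contact positions in subject-space millimetres."""

    table: pd.DataFrame  # columns: electrode, index, x_mm, y_mm, z_mm

    REQUIRED = ("electrode", "index", "x_mm", "y_mm", "z_mm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"contact table missing columns: {missing}")
        dup = self.table.duplicated(subset=["electrode", "index"])
        if dup.any():
            raise ValueError("duplicate (electrode, index) pairs in contact table")

    def contact_name(self, electrode: str, index: int) -> str:
        return f"{electrode}{index}"

    def position(self, electrode: str, index: int) -> np.ndarray:
        row = self.table[
            (self.table["electrode"] == electrode) & (self.table["index"] == index)
        ]
        if row.empty:
            raise KeyError(f"no contact {electrode}{index} in table")
        return row[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)[0]

    def electrodes(self) -> list[str]:
        return list(dict.fromkeys(self.table["electrode"]))


@dataclass
class BipolarChannel:
    """Difference channel between two adjacent contacts on one shaft."""

    name: str
    anode: tuple[str, int]  # (electrode, contact index), the deeper contact
    cathode: tuple[str, int]  # the adjacent shallower contact
    anode_xyz: np.ndarray
    cathode_xyz: np.ndarray
    midpoint: np.ndarray = field(init=False)
    flags: dict = field(default_factory=lambda: {
        "outside_brain": False,
        "out_of_gray": False,
        "low_amplitude": False,
        "extreme_amplitude": False,
    })

    def __post_init__(self) -> None:
        if self.anode[0] != self.cathode[0]:
            raise ValueError("bipolar pair must share an electrode shaft")
        if abs(self.anode[1] - self.cathode[1]) != 1:
            raise ValueError("bipolar pair must be adjacent contacts")
        self.anode_xyz = np.asarray(self.anode_xyz, dtype=float)
        self.cathode_xyz = np.asarray(self.cathode_xyz, dtype=float)
        self.midpoint = (self.anode_xyz + self.cathode_xyz) / 2.0

    @property
    def included(self) -> bool:
        return not any(self.flags.values())


@dataclass
class VolumeImage:
    """3-D grid with a voxel-to-mm affine.

    interpretation is one of {"brain_mask", "gray_mask", "heatmap"}; masks
    hold only {0, 1}.
    """

    grid: np.ndarray
    affine: np.ndarray
    interpretation: str = "heatmap"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("volume grid must be 3-D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("volume affine is not invertible")
        if self.interpretation not in ("brain_mask", "gray_mask", "heatmap"):
            raise ValueError(f"unknown interpretation {self.interpretation!r}")
        if self.interpretation.endswith("mask"):
            vals = np.unique(self.grid)
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError("mask volumes must be binary")

    def mm_to_voxel(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Nearest-voxel index for a subject-space mm point (may be out of grid)."""
        inv = np.linalg.inv(self.affine)
        hom = np.append(np.asarray(xyz_mm, dtype=float), 1.0)
        return np.round(inv @ hom)[:3].astype(int)

    def in_bounds(self, ijk: np.ndarray) -> bool:
        return bool(np.all(ijk >= 0) and np.all(ijk < np.array(self.grid.shape)))

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _format_phys(x: float) -> float:
    """Return x rounded so its 8-char EDF ASCII field parses back exactly."""
    for fmt in ("%8g", "%8.6g", "%8.4g"):
        s = fmt % x
        if len(s.strip()) <= 8:
            return float(s)
    return float("%8.2e" % x)


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a plain EDF file (16-bit, 1 s data records).

    The sampling rate must be a whole number of samples per second; the
    final partial second, if any, is zero-padded to a full record.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise UnsupportedInputError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / fs))
    data = rec.data
    if rec.n_samples % fs:
        pad = n_rec * fs - rec.n_samples
        warnings.warn(f"zero-padding final EDF record by {pad} samples")
        data = np.pad(data, ((0, 0), (0, pad)))

    # per-signal physical scaling, symmetric about zero, 16-bit digital range;
    # the digitization affine must match the EDF reader convention
    # (phys_max-phys_min)/(dig_max-dig_min) exactly for a faithful round trip
    dig_min, dig_max = -32768, 32767
    phys_max = np.array([_format_phys(max(np.abs(ch).max(), 1e-6)) for ch in data])
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - dig_min * scale

    header_bytes = 256 * (1 + n_sig)
    with open(path, "wb") as f:
        f.write(_edf_ascii("0", 8))
        f.write(_edf_ascii("X", 80))            # patient id (anonymous)
        f.write(_edf_ascii("X", 80))            # recording id
        f.write(_edf_ascii("01.01.00", 8))
        f.write(_edf_ascii("00.00.00", 8))
        f.write(_edf_ascii(header_bytes, 8))
        f.write(_edf_ascii("", 44))
        f.write(_edf_ascii(n_rec, 8))
        f.write(_edf_ascii(1, 8))               # record duration, s
        f.write(_edf_ascii(n_sig, 4))
        for name in rec.channel_names:
            f.write(_edf_ascii(name, 16))
        f.write(b"".join(_edf_ascii("SEEG", 80) for _ in range(n_sig)))
        f.write(b"".join(_edf_ascii("uV", 8) for _ in range(n_sig)))
        for v in phys_min:
            f.write(_edf_ascii("%g" % v, 8))
        for v in phys_max:
            f.write(_edf_ascii("%g" % v, 8))
        f.write(b"".join(_edf_ascii(dig_min, 8) for _ in range(n_sig)))
        f.write(b"".join(_edf_ascii(dig_max, 8) for _ in range(n_sig)))
        f.write(b"".join(_edf_ascii("", 80) for _ in range(n_sig)))
        f.write(b"".join(_edf_ascii(fs, 8) for _ in range(n_sig)))
        f.write(b"".join(_edf_ascii("", 32) for _ in range(n_sig)))
        digital = np.clip(np.round((data - offset[:, None]) / scale[:, None]),
                          dig_min, dig_max).astype("<i2")
        for r in range(n_rec):
            block = digital[:, r * fs:(r + 1) * fs]
            f.write(block.tobytes())


def _read_edf_header_labels(path: Path) -> tuple[list[str], list[float]]:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"{path} is too short to be an EDF file")
        try:
            n_sig = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise FormatError(f"{path} has an unreadable EDF header") from exc
        labels = [
            f.read(16).decode("ascii", errors="replace").strip() for _ in range(n_sig)
        ]
        f.seek(256 + n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        spr = [float(f.read(8).decode("ascii", errors="replace").strip() or "nan")
               for _ in range(n_sig)]
    return labels, spr


def read_recording(path: str | Path) -> Recording:
    """Read an EDF recording into a monopolar µV Recording.

    All signal channels must share one sampling rate; annotation channels
    are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    labels, spr = _read_edf_header_labels(path)
    data_labels = [l for l in labels if "annotation" not in l.lower()]
    if len(set(data_labels)) != len(data_labels):
        raise FormatError(f"{path}: duplicate channel names in EDF header")
    data_spr = [s for l, s in zip(labels, spr) if "annotation" not in l.lower()]
    if len(set(data_spr)) > 1:
        raise UnsupportedInputError(
            f"{path}: channels with mismatched sampling rates {sorted(set(data_spr))}"
        )

    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"could not read {path} as EDF: {exc}") from exc
    picks = [i for i, name in enumerate(raw.ch_names)
             if "annotation" not in name.lower()]
    data_v = raw.get_data()[picks]
    names = [raw.ch_names[i] for i in picks]
    return Recording(data=data_v * 1e6, fs=float(raw.info["sfreq"]),
                     channel_names=names, montage="monopolar")


# ---------------------------------------------------------------------------
# Contacts, volumes
# ---------------------------------------------------------------------------

def read_contacts(path: str | Path) -> ContactTable:
    """Read a contact TSV (electrode, index, x_mm, y_mm, z_mm)."""
    df = pd.read_csv(path, sep="\t")
    return ContactTable(df)


def read_volume(path: str | Path, interpretation: str = "heatmap",
                mask_threshold: float = 0.5) -> VolumeImage:
    """Load a NIfTI volume.

    Mask interpretations are binarized at ``mask_threshold`` if the stored
    values are not already {0,1} (probability maps).
    """
    import nibabel as nib

    img = nib.load(str(path))
    grid = np.asarray(img.get_fdata(), dtype=float)
    affine = np.asarray(img.affine, dtype=float)
    if interpretation.endswith("mask"):
        vals = np.unique(grid)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            grid = (grid >= mask_threshold).astype(float)
    return VolumeImage(grid=grid, affine=affine, interpretation=interpretation)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(vol.grid.astype(np.float32), vol.affine), str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def notch_filter(rec: Recording, base: float = 50.0,
                 max_harmonic: float = 450.0, half_width: float = 2.0) -> Recording:
    """Zero-phase 3rd-order Butterworth band-stop at base, 2·base, … ≤ max_harmonic.

    half_width is the stop-band half-width in Hz (±2 Hz default, the
    conventional setting for clinical line noise).
    """
    from scipy import signal

    if base >= rec.fs / 2:
        raise ValueError("notch base frequency must be below Nyquist")
    if max_harmonic >= rec.fs / 2:
        raise ValueError("max_harmonic must be below Nyquist")
    data = rec.data.copy()
    h = base
    while h <= max_harmonic + 1e-9:
        sos = signal.butter(3, [h - half_width, h + half_width],
                            btype="bandstop", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)
        h += base
    return Recording(data=data, fs=rec.fs,
                     channel_names=list(rec.channel_names), montage=rec.montage)


def make_bipolar(rec: Recording, contacts: ContactTable
                 ) -> tuple[Recording, list[BipolarChannel]]:
    """Re-reference a monopolar recording to adjacent-contact bipolar pairs.

    Pairing direction is contact k minus contact k+1 along each shaft.
    Electrodes with a single contact are skipped with a warning; a contact
    with no matching recording channel is an error.
    """
    name_to_row = {n: i for i, n in enumerate(rec.channel_names)}
    traces: list[np.ndarray] = []
    names: list[str] = []
    pairs: list[BipolarChannel] = []
    for elec in contacts.electrodes():
        sub = contacts.table[contacts.table["electrode"] == elec].sort_values("index")
        idxs = sub["index"].tolist()
        if len(idxs) < 2:
            warnings.warn(f"electrode {elec} has a single contact; skipped")
            continue
        for a, b in zip(idxs[:-1], idxs[1:]):
            if b != a + 1:
                continue  # gap in the shaft: contacts are not adjacent
            ch_a = contacts.contact_name(elec, a)
            ch_b = contacts.contact_name(elec, b)
            for ch in (ch_a, ch_b):
                if ch not in name_to_row:
                    raise KeyError(f"contact {ch} has no matching recording channel")
            trace = rec.data[name_to_row[ch_a]] - rec.data[name_to_row[ch_b]]
            traces.append(trace)
            names.append(f"{ch_a}-{ch_b}")
            pairs.append(BipolarChannel(
                name=f"{ch_a}-{ch_b}", anode=(elec, a), cathode=(elec, b),
                anode_xyz=contacts.position(elec, a),
                cathode_xyz=contacts.position(elec, b)))
    if not traces:
        raise ValueError("no bipolar pairs could be formed")
    bip = Recording(data=np.vstack(traces), fs=rec.fs,
                    channel_names=names, montage="bipolar")
    return bip, pairs
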
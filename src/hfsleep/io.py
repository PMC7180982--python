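"""Recordings, hypnograms, EDF files and epoch segmentation.

A :class:`Recording` is a named multi-channel signal container in microvolts
with a single sampling rate; a :class:`Hypnogram` is the per-30-s-epoch stage
sequence aligned to it.  Signals are exchanged as 16-bit EDF; hypnograms as a
two-column CSV (``epoch_index,stage``).

EDF reading delegates sample decoding to :mod:`mne` after a manual header
check; writing is done directly (no EDF writer library is available), with
one-second data records and the physical range taken from the data, so the
round-trip error is bounded by the 16-bit quantization step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np

from .stages import STAGES, normalize_stage

EPOCH_SECONDS = 30
CONTEXT_SECONDS = 90


class EdfFormatError(ValueError):
    """Malformed or unsupported EDF structure."""


class UnitError(ValueError):
    """A channel's physical dimension is not a supported voltage unit."""


def is_emg_channel(name: str) -> bool:
    """True for chin-EMG channel names ('EMG', 'Chin EMG', 'EMG1', ...)."""
    return "emg" in name.lower()


@dataclass
class Recording:
    """Multi-channel biosignal recording in microvolts at one sampling rate.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject/night.
    fs : float
        Sampling rate in Hz; ``fs * 30`` must be an integer so that 30-s
        epochs contain a whole number of samples.
    channels : dict of str -> ndarray
        Channel name (e.g. ``"C3-A2"``, ``"O2-A1"``, ``"EMG"``) to
        equal-length 1-D sample arrays in µV.
    start_time : optional
        Recording start; informational only.
    """

    subject_id: str
    fs: float
    channels: Dict[str, np.ndarray]
    start_time: Optional[object] = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        spe = self.fs * EPOCH_SECONDS
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError(
                f"fs*{EPOCH_SECONDS} must be an integer number of samples, got fs={self.fs}"
            )
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {k: v.shape for k, v in self.channels.items()}
        for k, shape in lengths.items():
            if len(shape) != 1:
                raise ValueError(f"channel {k!r} is not 1-D")
        sizes = {v.size for v in self.channels.values()}
        if len(sizes) > 1:
            raise ValueError(f"channels differ in length: { {k: v.size for k, v in self.channels.items()} }")

    @property
    def n_samples(self) -> int:
        if not self.channels:
            return 0
        return next(iter(self.channels.values())).size

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.fs

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.fs * EPOCH_SECONDS))

    @property
    def n_epochs(self) -> int:
        """Number of complete 30-s epochs (trailing partial epoch discarded)."""
        return self.n_samples // self.samples_per_epoch

    def eeg_channel_names(self) -> list[str]:
        return [c for c in self.channels if not is_emg_channel(c)]


@dataclass
class Hypnogram:
    """Per-30-s-epoch sleep stage labels over {W, R, N1, N2, N3}."""

    stages: Sequence[str]
    epoch_len: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        if self.epoch_len != EPOCH_SECONDS:
            raise ValueError(f"epoch_len is fixed at {EPOCH_SECONDS} s")
        self.stages = tuple(normalize_stage(s) for s in self.stages)

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)

    def counts(self) -> dict[str, int]:
        arr = self.as_array()
        return {s: int(np.sum(arr == s)) for s in STAGES}


def check_alignment(recording: Recording, hypnogram: Hypnogram) -> None:
    """Hard error when the hypnogram does not cover exactly the full epochs.

    Misalignment silently corrupts labels, so no truncation is attempted.
    """
    if hypnogram.n_epochs != recording.n_epochs:
        raise ValueError(
            f"hypnogram has {hypnogram.n_epochs} epochs but recording "
            f"{recording.subject_id!r} has {recording.n_epochs} complete 30-s epochs"
        )


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(recording: Recording) -> Dict[str, np.ndarray]:
    """Split every channel into complete 30-s epochs.

    Returns a mapping channel -> array of shape ``(n_epochs, fs*30)``.  Epoch
    ``i`` covers samples ``[i*30*fs, (i+1)*30*fs)`` (0-based, half-open); the
    trailing partial epoch is discarded.
    """
    if recording.duration < EPOCH_SECONDS:
        raise ValueError(
            f"recording is {recording.duration:.1f} s long; need at least {EPOCH_SECONDS} s"
        )
    spe = recording.samples_per_epoch
    n = recording.n_epochs
    return {
        name: x[: n * spe].reshape(n, spe).copy()
        for name, x in recording.channels.items()
    }


def context_window(x: np.ndarray, samples_per_epoch: int, epoch_index: int) -> np.ndarray:
    """90-s context window ending with epoch ``epoch_index`` of a raw signal.

    For ``epoch_index >= 2`` this is the contiguous slice of epochs
    ``{i-2, i-1, i}``.  For the first two epochs the window is left-padded by
    reflecting the earliest available signal, so the output length is always
    ``3 * samples_per_epoch`` and no future samples are used.
    """
    ne = samples_per_epoch
    n_epochs = x.size // ne
    if not 0 <= epoch_index < n_epochs:
        raise IndexError(f"epoch index {epoch_index} out of range [0, {n_epochs})")
    i = epoch_index
    if i >= 2:
        return x[(i - 2) * ne:(i + 1) * ne].copy()
    head = x[: (i + 1) * ne]
    pad = (2 - i) * ne
    return np.pad(head, (pad, 0), mode="reflect")


def epoch_with_context(recording: Recording, channel: str, epoch_index: int) -> np.ndarray:
    """90-s segment of ``channel``: epoch ``epoch_index`` plus its previous 60 s."""
    if channel not in recording.channels:
        raise KeyError(f"channel {channel!r} not in recording {sorted(recording.channels)}")
    return context_window(
        recording.channels[channel], recording.samples_per_epoch, epoch_index
    )


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram_csv(hypnogram: Hypnogram, path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, s in enumerate(hypnogram.stages):
            w.writerow([i, s])
    return path


def read_hypnogram_csv(path) -> Hypnogram:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or [c.strip().lower() for c in rows[0][:2]] != ["epoch_index", "stage"]:
        raise ValueError(f"{path}: expected header 'epoch_index,stage'")
    stages = []
    for k, row in enumerate(rows[1:]):
        if int(row[0]) != k:
            raise ValueError(f"{path}: epoch indices must be consecutive from 0, got {row[0]} at row {k}")
        stages.append(row[1])
    return Hypnogram(stages)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_SUPPORTED_UNITS = {"uV"}


def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    if not s.isascii():
        s = s.encode("ascii", "replace").decode()
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical min/max so it fits the 8-char EDF header field."""
    for fmt in ("%.6g", "%.4g", "%.2e"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise EdfFormatError(f"cannot format physical bound {v} in 8 chars")


def write_edf(recording: Recording, path) -> Path:
    """Write a Recording as a 16-bit EDF file (physical dimension µV).

    Uses one-second data records, which requires an integer sampling rate.
    Physical min/max are taken from each channel's data range (with a small
    outward margin) and re-parsed from the header text so that the scaling
    used for quantization is exactly the one a reader will reconstruct.
    """
    path = Path(path)
    if not recording.channels:
        raise EdfFormatError("recording has no channels; nothing to write")
    if abs(recording.fs - round(recording.fs)) > 1e-9:
        raise EdfFormatError(
            f"EDF writer uses 1-s records and needs an integer sampling rate, got {recording.fs}"
        )
    fs = int(round(recording.fs))
    names = list(recording.channels)
    data = [recording.channels[c] for c in names]
    for c, x in zip(names, data):
        if not np.all(np.isfinite(x)):
            raise ValueError(f"channel {c!r} contains non-finite samples")
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise EdfFormatError("recording shorter than one 1-s data record")
    ns = len(names)

    phys_min, phys_max = [], []
    for x in data:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        margin = (hi - lo) * 1e-4
        lo_s, hi_s = _fmt_phys(lo - margin), _fmt_phys(hi + margin)
        # re-parse so header text and scaling agree exactly
        lo_f, hi_f = float(lo_s), float(hi_s)
        if not (lo_f <= lo and hi_f >= hi):  # formatting rounded inward; widen
            lo_s, hi_s = _fmt_phys(lo - (hi - lo) * 0.01 - 1e-9), _fmt_phys(hi + (hi - lo) * 0.01 + 1e-9)
            lo_f, hi_f = float(lo_s), float(hi_s)
        phys_min.append((lo_s, lo_f))
        phys_max.append((hi_s, hi_f))

    dig_min, dig_max = -32768, 32767
    header = bytearray()
    header += _ascii_field("0", 8)
    header += _ascii_field(recording.subject_id, 80)
    header += _ascii_field("Startdate 01-JAN-2000", 80)
    header += _ascii_field("01.01.00", 8)
    header += _ascii_field("00.00.00", 8)
    header += _ascii_field(str(256 * (ns + 1)), 8)
    header += _ascii_field("", 44)
    header += _ascii_field(str(n_records), 8)
    header += _ascii_field("1", 8)          # record duration, seconds
    header += _ascii_field(str(ns), 4)
    for name in names:
        header += _ascii_field(name, 16)
    for _ in names:
        header += _ascii_field("", 80)      # transducer
    for _ in names:
        header += _ascii_field("uV", 8)
    for lo_s, _ in phys_min:
        header += _ascii_field(lo_s, 8)
    for hi_s, _ in phys_max:
        header += _ascii_field(hi_s, 8)
    for _ in names:
        header += _ascii_field(str(dig_min), 8)
    for _ in names:
        header += _ascii_field(str(dig_max), 8)
    for _ in names:
        header += _ascii_field("", 80)      # prefiltering
    for _ in names:
        header += _ascii_field(str(fs), 8)  # samples per record
    for _ in names:
        header += _ascii_field("", 32)

    digital = []
    for x, (_, lo), (_, hi) in zip(data, phys_min, phys_max):
        scale = (dig_max - dig_min) / (hi - lo)
        d = np.rint((x[: n_records * fs] - lo) * scale + dig_min)
        digital.append(np.clip(d, dig_min, dig_max).astype("<i2"))

    with path.open("wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())
    return path


def _read_edf_header(path: Path) -> dict:
    with path.open("rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EdfFormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(fixed[236:244].decode("ascii").strip())
            rec_dur = float(fixed[244:252].decode("ascii").strip())
            ns = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EdfFormatError(f"{path}: invalid EDF header: {exc}") from exc
        sig = fh.read(256 * ns)

    labels = [sig[i * 16:(i + 1) * 16].decode("ascii").strip() for i in range(ns)]
    pos = 16 * ns + 80 * ns
    dims = [sig[pos + i * 8: pos + (i + 1) * 8].decode("ascii").strip() for i in range(ns)]
    # after dims: phys min/max, dig min/max (8 chars each), prefiltering (80)
    pos2 = pos + 8 * ns + 8 * ns * 4 + 80 * ns
    spr = [int(sig[pos2 + i * 8: pos2 + (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]
    return {
        "patient": fixed[8:88].decode("ascii").strip(),
        "n_records": n_records,
        "record_duration": rec_dur,
        "labels": labels,
        "dims": dims,
        "samples_per_record": spr,
    }


def read_edf(path) -> Recording:
    """Read an EDF/EDF+ file into a Recording (µV).

    The header is checked first: channels with differing sampling rates are
    rejected rather than resampled (silent resampling would change the
    high-frequency content this package analyses), and unsupported physical
    dimensions raise :class:`UnitError`.  Sample decoding is delegated to
    :func:`mne.io.read_raw_edf`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hdr = _read_edf_header(path)
    signal_idx = [i for i, lab in enumerate(hdr["labels"]) if lab != "EDF Annotations"]
    if not signal_idx:
        raise EdfFormatError(f"{path}: no signal channels")
    rates = {hdr["labels"][i]: hdr["samples_per_record"][i] / hdr["record_duration"]
             for i in signal_idx}
    if len(set(rates.values())) > 1:
        raise EdfFormatError(
            f"{path}: channels have mixed sampling rates, refusing to resample: {rates}"
        )
    for i in signal_idx:
        if hdr["dims"][i] not in _SUPPORTED_UNITS:
            raise UnitError(
                f"{path}: channel {hdr['labels'][i]!r} has unsupported unit "
                f"{hdr['dims'][i]!r}; expected one of {sorted(_SUPPORTED_UNITS)}"
            )

    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne returns volts for µV-dimension channels
    channels = {name: data[k] for k, name in enumerate(raw.ch_names)}
    subject = hdr["patient"] or path.stem
    return Recording(subject_id=subject, fs=fs, channels=channels)
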
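"""Spectral band energies of 30-s segments.

Energies are Welch power-spectral-density estimates (2-s Hamming windows,
50 % overlap — 0.5 Hz resolution) summed over half-open frequency intervals
``[low, high)`` and multiplied by the bin width, giving µV².  Half-open
intervals on a shared grid make adjacent bands exactly additive:
``E(80,250) = E(80,150) + E(150,250)``.

Two band sets matter downstream:

* the six analysis bands used for the EEG–EMG correlation study,
* the three high-frequency classifier bands whose log10 energies are
  appended to the scattering features of an unfiltered recording.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.signal import welch

Band = Tuple[float, float]

#: Bands of the correlation study: classic EEG ranges + high-frequency ranges.
ANALYSIS_BANDS: tuple[Band, ...] = (
    (0.5, 15), (15, 35), (35, 80), (80, 150), (150, 250), (80, 250),
)

#: High-frequency bands appended as classifier features.
CLASSIFIER_BANDS: tuple[Band, ...] = ((35, 80), (80, 150), (150, 250))

#: Additive floor inside the log, µV²; keeps zero-signal epochs finite.
LOG_FLOOR = 1e-12

WELCH_WINDOW_SECONDS = 2.0


def validate_bands(bands: Sequence[Band], fs: float) -> None:
    for lo, hi in bands:
        if not 0 <= lo < hi <= fs / 2:
            raise ValueError(
                f"band ({lo}, {hi}) Hz invalid for fs={fs} (need 0 <= low < high <= fs/2)"
            )


def _welch_psd(segment: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(WELCH_WINDOW_SECONDS * fs))
    if segment.size < nperseg:
        raise ValueError(
            f"segment of {segment.size} samples is shorter than one "
            f"{WELCH_WINDOW_SECONDS:.0f}-s Welch window ({nperseg} samples)"
        )
    return welch(
        segment, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )


def band_energy(segment: np.ndarray, fs: float, band: Band) -> float:
    """Energy (µV²) of a segment inside ``[low, high)`` Hz."""
    validate_bands([band], fs)
    f, pxx = _welch_psd(np.asarray(segment, dtype=float), fs)
    return float(band_energies_from_psd(f, pxx, [band])[0])


def band_energies(segment: np.ndarray, fs: float, bands: Sequence[Band]) -> np.ndarray:
    """Energies for several bands from a single Welch estimate."""
    validate_bands(bands, fs)
    f, pxx = _welch_psd(np.asarray(segment, dtype=float), fs)
    return band_energies_from_psd(f, pxx, bands)


def band_energies_from_psd(
    freqs: np.ndarray, psd: np.ndarray, bands: Sequence[Band]
) -> np.ndarray:
    """Integrate a one-sided PSD over half-open bands (shared grid)."""
    df = freqs[1] - freqs[0]
    psd = np.atleast_2d(psd)
    out = np.empty((psd.shape[0], len(bands)))
    for j, (lo, hi) in enumerate(bands):
        sel = (freqs >= lo) & (freqs < hi)
        out[:, j] = psd[:, sel].sum(axis=1) * df
    return out[0] if out.shape[0] == 1 else out


def stft_features(
    segment: np.ndarray,
    fs: float,
    bands: Sequence[Band] = CLASSIFIER_BANDS,
) -> np.ndarray:
    """log10 band energies of a 30-s epoch — the high-frequency features.

    One entry per band: ``log10(E + 1e-12)``; the additive floor keeps a
    silent epoch finite (all entries −12) so downstream CCA and SVM always
    see finite features.  Scaling the segment by ``a`` shifts every entry by
    exactly ``2·log10(a)``... up to the floor.
    """
    e = band_energies(segment, fs, bands)
    return np.log10(np.asarray(e, dtype=float) + LOG_FLOOR)


def band_energy_table(
    pairs,
    channels: Sequence[str],
    bands: Sequence[Band] = ANALYSIS_BANDS,
    log: bool = True,
):
    """Long-format per-epoch band-energy table for several subjects.

    ``pairs`` are (Recording, Hypnogram) tuples; the result is a pandas
    DataFrame with columns subject, epoch_index, stage, channel and one
    column per band (``e_<low>_<high>``), suitable for CSV export.
    """
    import pandas as pd

    rows = []
    for rec, hyp in pairs:
        n_ep = rec.n_epochs
        for ch in channels:
            e = epoch_band_energies(rec.channels[ch], rec.fs, bands, log=log)
            for i in range(n_ep):
                row = {
                    "subject": rec.subject_id,
                    "epoch_index": i,
                    "stage": hyp.stages[i],
                    "channel": ch,
                }
                for (lo, hi), v in zip(bands, np.atleast_2d(e)[i]):
                    row[f"e_{lo:g}_{hi:g}"] = v
                rows.append(row)
    return pd.DataFrame(rows)


def epoch_band_energies(
    x: np.ndarray, fs: float, bands: Sequence[Band], log: bool = True
) -> np.ndarray:
    """Per-epoch band energies of a whole-channel signal.

    Splits ``x`` into complete 30-s epochs and returns an array of shape
    ``(n_epochs, n_bands)``; with ``log=True`` (the package default for all
    correlation work) entries are log10(E + floor).
    """
    validate_bands(bands, fs)
    ne = int(round(fs * 30))
    n_ep = x.size // ne
    if n_ep < 1:
        raise ValueError("signal shorter than one 30-s epoch")
    segs = np.asarray(x[: n_ep * ne], dtype=float).reshape(n_ep, ne)
    f, pxx = _welch_psd(segs, fs)
    e = band_energies_from_psd(f, pxx, bands)
    e = np.atleast_2d(e)
    return np.log10(e + LOG_FLOOR) if log else e
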
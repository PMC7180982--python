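"""Synthetic polysomnography with controllable EMG-into-EEG leakage.

The generator emulates the structure of an overnight hospital recording:

* a hypnogram sampled from a first-order Markov chain over the five stages;
* EEG channels built, epoch by epoch, from Gaussian noise shaped to a
  stage-dependent piecewise-flat power spectral density (delta/theta/alpha/
  beta levels plus a stage-independent gamma level and a broadband floor);
* a chin-EMG channel whose amplitude tracks muscle tone by stage — atonic in
  REM, most active while awake;
* a controllable fraction ``g`` of the *same* EMG noise process, high-pass
  shaped above ~35 Hz, added into every EEG channel.  This induces the
  EEG–EMG high-frequency band-energy correlation that the analysis modules
  measure, with known ground truth.

Because both the EEG base activity and the leakage are spectrally flat
within bands, every band energy downstream is analytically predictable:
``E[band] = Σ PSD_level × overlap + g²·σ_emg²·|H_hp|²·overlap/BW_emg``.

Stage boundaries are cross-faded over 0.5 s to avoid spectral splatter from
hard concatenation.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

from .io import Hypnogram, Recording, is_emg_channel
from .stages import STAGES

Band = Tuple[float, float]

#: Default per-stage EEG PSD levels, µV²/Hz on (low, high) Hz bands.
#: REM and N1 are deliberately identical below 35 Hz: in this generator the
#: two stages are distinguishable only through muscle tone, mirroring the
#: physiological picture (REM atonia vs. active N1) that motivates using
#: high-frequency EEG content as an EMG surrogate.
DEFAULT_BAND_PSD: Dict[str, Dict[Band, float]] = {
    "W":  {(0.5, 4): 10.0, (4, 8): 5.0,  (8, 15): 15.0, (15, 35): 5.0, (35, 80): 0.1},
    "R":  {(0.5, 4): 20.0, (4, 8): 15.0, (8, 15): 5.0,  (15, 35): 3.0, (35, 80): 0.1},
    "N1": {(0.5, 4): 20.0, (4, 8): 15.0, (8, 15): 5.0,  (15, 35): 3.0, (35, 80): 0.1},
    "N2": {(0.5, 4): 40.0, (4, 8): 15.0, (8, 15): 8.0,  (15, 35): 4.0, (35, 80): 0.1},
    "N3": {(0.5, 4): 120.0, (4, 8): 20.0, (8, 15): 5.0, (15, 35): 2.0, (35, 80): 0.1},
}

#: Default chin-EMG tone amplitudes, µV (standard deviation of the band-
#: limited EMG process).  Ordering: REM < N3 <= N2 < N1 < Awake.
DEFAULT_SIGMA_EMG: Dict[str, float] = {"W": 15.0, "R": 1.0, "N1": 8.0, "N2": 3.0, "N3": 2.0}


@dataclass(frozen=True)
class StageSpectrumModel:
    """Stage-dependent spectra, EMG tone and leakage parameters.

    Parameters
    ----------
    band_psd : mapping stage -> mapping (low, high) -> level
        One-sided EEG PSD levels in µV²/Hz; piecewise-flat.
    sigma_emg : mapping stage -> float
        EMG process standard deviation per stage, µV.
    leakage_gain : float
        Fraction ``g >= 0`` of the (high-pass shaped) EMG process added
        into each EEG channel.
    leak_highpass_hz : float
        Corner of the leakage shaping filter.  The default 35 Hz with a
        gentle (order-2 Butterworth magnitude) slope leaves the 35–80 Hz
        leakage partially masked by the in-band gamma activity while the
        >80 Hz leakage stands clear of the broadband floor.
    emg_band : (low, high)
        Spectral support of the EMG process, Hz.
    broadband_floor : float
        Stage-independent EEG noise floor, µV²/Hz, up to Nyquist.
    """

    band_psd: Mapping[str, Mapping[Band, float]] = field(
        default_factory=lambda: DEFAULT_BAND_PSD)
    sigma_emg: Mapping[str, float] = field(default_factory=lambda: DEFAULT_SIGMA_EMG)
    leakage_gain: float = 0.3
    leak_highpass_hz: float = 35.0
    leak_highpass_order: int = 2
    emg_band: Band = (25.0, 250.0)
    broadband_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.leakage_gain < 0:
            raise ValueError("leakage gain must be >= 0")
        if self.broadband_floor < 0:
            raise ValueError("broadband floor must be >= 0")
        for stage in STAGES:
            if stage not in self.band_psd:
                raise ValueError(f"band_psd missing stage {stage}")
            if stage not in self.sigma_emg:
                raise ValueError(f"sigma_emg missing stage {stage}")
            if self.sigma_emg[stage] < 0:
                raise ValueError(f"sigma_emg[{stage}] must be >= 0")
            for (lo, hi), level in self.band_psd[stage].items():
                if not (0 <= lo < hi):
                    raise ValueError(f"invalid band ({lo}, {hi})")
                if level < 0:
                    raise ValueError(f"negative PSD level in stage {stage}")

    @classmethod
    def from_dict(cls, params: Mapping) -> "StageSpectrumModel":
        """Build a model from a plain key-value mapping (config files).

        Band keys in ``band_psd`` are strings ``"low-high"`` in Hz, e.g.
        ``{"N3": {"0.5-4": 120.0, ...}, ...}``; all other fields carry
        their dataclass names.
        """
        kwargs: dict = {}
        if "band_psd" in params:
            kwargs["band_psd"] = {
                stage: {
                    tuple(float(v) for v in key.split("-")): float(level)
                    for key, level in bands.items()
                }
                for stage, bands in params["band_psd"].items()
            }
        if "sigma_emg" in params:
            kwargs["sigma_emg"] = {k: float(v) for k, v in params["sigma_emg"].items()}
        for field_name in ("leakage_gain", "leak_highpass_hz", "leak_highpass_order",
                           "broadband_floor"):
            if field_name in params:
                kwargs[field_name] = params[field_name]
        if "emg_band" in params:
            kwargs["emg_band"] = tuple(params["emg_band"])
        return cls(**kwargs)

    def eeg_psd(self, stage: str, freqs: np.ndarray) -> np.ndarray:
        """One-sided EEG PSD (µV²/Hz) of ``stage`` on a frequency grid."""
        psd = np.full(freqs.shape, self.broadband_floor, dtype=float)
        psd[freqs <= 0] = 0.0
        for (lo, hi), level in self.band_psd[stage].items():
            psd[(freqs >= lo) & (freqs < hi)] += level
        return psd

    def leak_response(self, freqs: np.ndarray) -> np.ndarray:
        """Magnitude response of the leakage high-pass shaping filter."""
        h = np.zeros_like(freqs, dtype=float)
        pos = freqs > 0
        ratio = self.leak_highpass_hz / freqs[pos]
        h[pos] = 1.0 / np.sqrt(1.0 + ratio ** (2 * self.leak_highpass_order))
        return h


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic 5x5 stage transition matrix plus initial distribution."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        p0 = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "initial", p0)
        if m.shape != (5, 5) or p0.shape != (5,):
            raise ValueError("need a 5x5 matrix and a length-5 initial distribution")
        if np.any(m < 0) or np.any(p0 < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1 (within 1e-12)")
        if abs(p0.sum() - 1.0) > 1e-12:
            raise ValueError("initial distribution must sum to 1 (within 1e-12)")

    @classmethod
    def default(cls) -> "TransitionModel":
        """A plausible overnight stage dynamic (sticky stages, wake start)."""
        m = np.array([
            # to:  W     R     N1    N2    N3          from:
            [0.90, 0.01, 0.07, 0.02, 0.00],          # W
            [0.02, 0.90, 0.05, 0.03, 0.00],          # R
            [0.09, 0.05, 0.70, 0.16, 0.00],          # N1
            [0.02, 0.03, 0.04, 0.85, 0.06],          # N2
            [0.01, 0.00, 0.01, 0.10, 0.88],          # N3
        ])
        return cls(matrix=m, initial=np.array([1.0, 0, 0, 0, 0]))


def simulate_hypnogram(
    n_epochs: int,
    model: TransitionModel | None = None,
    seed: int = 0,
) -> Hypnogram:
    """Sample a stage sequence from the Markov chain; deterministic per seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    model = model or TransitionModel.default()
    rng = np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(5, p=model.initial)
    for k in range(1, n_epochs):
        states[k] = rng.choice(5, p=model.matrix[states[k - 1]])
    return Hypnogram([STAGES[s] for s in states])


def _crossfade_ramp(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.pi * (np.arange(n) + 0.5) / n))


def simulate_recording(
    hypnogram: Hypnogram,
    model: StageSpectrumModel | None = None,
    fs: float = 500.0,
    channels: Sequence[str] = ("C3-A2", "O2-A1"),
    seed: int = 0,
    subject_id: str = "synthetic",
    emg_channel: str = "EMG",
) -> Recording:
    """Generate EEG channels + chin EMG matching a hypnogram.

    Per epoch with stage ``s``::

        EMG      = sigma_emg(s) * u
        EEG_ch   = base_ch(s)   + g * highpass(sigma_emg(s) * u)

    where ``u`` is unit-variance noise band-limited to ``emg_band`` and the
    *same realization* of ``u`` feeds the EMG channel and every EEG channel,
    so the EEG–EMG high-band energy correlation is induced by construction.
    ``base_ch`` are independent per channel.  Epoch boundaries are
    cross-faded over 0.5 s.
    """
    model = model or StageSpectrumModel()
    if model.emg_band[1] > fs / 2:
        raise ValueError(
            f"emg_band {model.emg_band} exceeds Nyquist {fs / 2} Hz; raise fs"
        )
    if any(is_emg_channel(c) for c in channels):
        raise ValueError("'channels' lists EEG names only; the EMG channel is added separately")
    rng = np.random.default_rng(seed)
    ne = int(round(fs * 30))
    nfade = int(round(fs * 0.5))
    next_ = ne + nfade                     # extended epoch for cross-fading
    freqs = np.fft.rfftfreq(next_, 1.0 / fs)
    df = fs / next_

    # frequency-domain shaping gains: white N(0,1) noise has two-sided PSD
    # 1/fs, so |H| = sqrt(S_target * fs / 2) yields one-sided PSD S_target
    eeg_gain = {
        s: np.sqrt(model.eeg_psd(s, freqs) * fs / 2.0) for s in STAGES
    }
    lo, hi = model.emg_band
    bw = hi - lo
    emg_gain = np.where((freqs >= lo) & (freqs < hi), np.sqrt(fs / (2.0 * bw)), 0.0)
    leak_gain = emg_gain * model.leak_response(freqs)

    n_ep = hypnogram.n_epochs
    total = n_ep * ne
    out = {c: np.zeros(total) for c in channels}
    out[emg_channel] = np.zeros(total)
    ramp = _crossfade_ramp(nfade)

    prev_tail: Dict[str, np.ndarray] | None = None
    for k, stage in enumerate(hypnogram.stages):
        sigma = model.sigma_emg[stage]
        wu = np.fft.rfft(rng.standard_normal(next_))
        u = np.fft.irfft(wu * emg_gain, next_)
        leak = np.fft.irfft(wu * leak_gain, next_)
        seg = {emg_channel: sigma * u}
        for c in channels:
            wb = np.fft.rfft(rng.standard_normal(next_))
            base = np.fft.irfft(wb * eeg_gain[stage], next_)
            seg[c] = base + model.leakage_gain * sigma * leak
        start = k * ne
        for c, x in seg.items():
            if prev_tail is None:
                out[c][start:start + nfade] = x[:nfade]
            else:
                out[c][start:start + nfade] = (
                    (1.0 - ramp) * prev_tail[c] + ramp * x[:nfade]
                )
            out[c][start + nfade:start + ne] = x[nfade:ne]
        prev_tail = {c: x[ne:next_] for c, x in seg.items()}

    return Recording(subject_id=subject_id, fs=fs, channels=out)


def simulate_subject(
    subject_id: str,
    n_epochs: int = 720,
    spectrum: StageSpectrumModel | None = None,
    transitions: TransitionModel | None = None,
    fs: float = 500.0,
    channels: Sequence[str] = ("C3-A2", "O2-A1"),
    seed: int = 0,
) -> tuple[Recording, Hypnogram]:
    """One synthetic night: hypnogram + recording, both from one seed.

    ``seed`` may be an int or a ``numpy.random.SeedSequence`` (as spawned
    by :func:`simulate_dataset`).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_hyp, s_rec = ss.spawn(2)
    hyp = simulate_hypnogram(n_epochs, transitions, seed=s_hyp)
    rec = simulate_recording(
        hyp, spectrum, fs=fs, channels=channels, seed=s_rec, subject_id=subject_id
    )
    return rec, hyp


def simulate_dataset(
    n_subjects: int,
    n_epochs: int = 720,
    spectrum: StageSpectrumModel | None = None,
    transitions: TransitionModel | None = None,
    fs: float = 500.0,
    channels: Sequence[str] = ("C3-A2", "O2-A1"),
    seed: int = 0,
) -> list[tuple[Recording, Hypnogram]]:
    """Independent synthetic subjects ``sub-01 .. sub-NN`` from one seed."""
    ss = np.random.SeedSequence(seed)
    return [
        simulate_subject(
            f"sub-{i + 1:02d}", n_epochs, spectrum, transitions, fs, channels, seed=child
        )
        for i, child in enumerate(ss.spawn(n_subjects))
    ]


def lowpass_version(recording: Recording, cutoff: float = 50.0) -> Recording:
    """50 Hz low-passed copy of a recording (EEG channels only).

    Emulates the clinically exported signal version in which high-frequency
    EEG content is removed; the EMG channel passes through unchanged.
    Zero-phase (forward-backward) 8th-order Butterworth.
    """
    from scipy.signal import butter, sosfiltfilt

    if cutoff >= recording.fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {recording.fs / 2} Hz")
    sos = butter(8, cutoff, btype="low", fs=recording.fs, output="sos")
    channels = {}
    for name, x in recording.channels.items():
        channels[name] = x.copy() if is_emg_channel(name) else sosfiltfilt(sos, x)
    return Recording(
        subject_id=recording.subject_id,
        fs=recording.fs,
        channels=channels,
        start_time=recording.start_time,
    )
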
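"""Order-2 wavelet scattering transform for 90-s EEG context windows.

The transform cascades analytic band-pass filtering and complex modulus:

* order 0:  ``S0    = mean |x * phi|``
* order 1:  ``S1(l1) = mean |x * psi_l1|``
* order 2:  ``S2(l1,l2) = mean ||x * psi_l1| * psi_l2|`` for
  ``center(l2) < center(l1)``

with a *global* average over the window, so one feature vector describes one
90-s context.  The result is translation-tolerant and stable to small time
warps, which is why it suits EEG whose waveforms deform between epochs.

Filters are Gaussians in frequency on the positive half-axis (hence
analytic by construction), geometrically spaced with ``Q`` wavelets per
octave over ``J`` octaves below ``0.4·fs``.  Each layer's bank is
renormalized point-wise so its Littlewood–Paley sum ``Σ|ψ̂|² + |φ̂|²`` equals
1 on the sampled grid — a tight frame, which gives the non-expansiveness
bound directly.

Implementation is FFT-based with periodic boundary handling; the window is
tapered with a 1-s cosine ramp at each end to suppress wrap-around
artifacts.  Filter outputs are subsampled to the smallest dyadic length
that oversamples the filter's frequency support twice, which keeps the
transform fast without changing its invariances (scaling the input still
scales every raw coefficient exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

LOG_EPS = 1e-12
XI_MAX_FACTOR = 0.4       # highest wavelet center frequency = 0.4 * fs
SIGMA_FACTOR = 0.6        # bandwidth = factor * center * (2**(1/Q) - 1)
SUPPORT_SIGMAS = 6.0      # filter support truncated at this many sigmas
MIN_SUB_LEN = 32


class ScatteringConfigError(ValueError):
    """Inconsistent scattering configuration for the given window length."""


@dataclass(frozen=True)
class ScatteringConfig:
    """Hyperparameters of the scattering transform.

    ``Q1``/``Q2`` are wavelets per octave in the first/second layer, ``J``
    the number of octaves covered below ``0.4·fs`` (J=10 at 500 Hz reaches
    ~0.2 Hz).  ``log_transform`` applies ``log(coef + 1e-12)`` so feature
    scales are comparable with the log band energies before CCA.
    """

    Q1: int = 8
    Q2: int = 1
    J: int = 10
    max_order: int = 2
    log_transform: bool = True
    taper_seconds: float = 1.0

    def __post_init__(self) -> None:
        if self.Q1 < 1 or self.Q2 < 1:
            raise ValueError("Q1 and Q2 must be >= 1")
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.max_order not in (1, 2):
            raise ValueError("max_order must be 1 or 2")


@dataclass(frozen=True)
class ScatteringFeatures:
    """Scattering coefficients of one window, with a fixed flat layout.

    ``vector`` is ``[S0, S1 in order of decreasing center frequency, S2
    ordered by (first-layer index asc, second-layer index asc)]``.  Raw
    coefficients are non-negative; when the config's log transform is on,
    entries are natural-log values with a 1e-12 floor.
    """

    s0: float
    s1: np.ndarray
    s2: np.ndarray
    pairs: Tuple[Tuple[int, int], ...]
    log_transformed: bool

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate(([self.s0], self.s1, self.s2))


def _center_freqs(fs: float, Q: int, J: int) -> np.ndarray:
    xi_max = XI_MAX_FACTOR * fs
    j = np.arange(Q * J)
    return xi_max * 2.0 ** (-j / Q)


def _sub_len(n: int, n_bins_needed: float) -> int:
    """Smallest dyadic divisor length of ``n`` with >= n_bins_needed bins."""
    m = n
    while m % 2 == 0 and m // 2 >= max(n_bins_needed, MIN_SUB_LEN):
        m //= 2
    return m


class FilterBank:
    """Sampled frequency-domain filters for a fixed (config, fs, n).

    Holds, per first-layer wavelet, the normalized transfer function on the
    DFT grid up to its truncated support, plus the subsampled output length;
    second-layer wavelets are sampled on the same grid spacing (subsampling
    by dyadic factors preserves the bin width ``fs/n``).
    """

    def __init__(self, config: ScatteringConfig, fs: float, n: int):
        if n < 2 ** config.J:
            raise ScatteringConfigError(
                f"window of {n} samples is shorter than 2^J = {2 ** config.J}; "
                f"use a smaller J"
            )
        self.config = config
        self.fs = float(fs)
        self.n = int(n)
        df = fs / n
        self.df = df
        nb_half = n // 2 + 1

        self.xi1 = _center_freqs(fs, config.Q1, config.J)
        self.sigma1 = SIGMA_FACTOR * self.xi1 * (2.0 ** (1.0 / config.Q1) - 1.0)
        self.xi2 = _center_freqs(fs, config.Q2, config.J)
        self.sigma2 = SIGMA_FACTOR * self.xi2 * (2.0 ** (1.0 / config.Q2) - 1.0)
        self.sigma_phi = SIGMA_FACTOR * float(self.xi1[-1])

        freqs = np.arange(nb_half) * df
        self.phi_hat_raw = np.exp(-0.5 * (freqs / self.sigma_phi) ** 2)

        def lp_raw(xis, sigmas):
            # |psi_hat|^2 = exp(-(f-xi)^2 / sigma^2) for the raw Gaussians
            s = self.phi_hat_raw ** 2
            for xi, sg in zip(xis, sigmas):
                s = s + np.exp(-((freqs - xi) ** 2) / sg ** 2)
            return s

        s1 = lp_raw(self.xi1, self.sigma1)
        s2 = lp_raw(self.xi2, self.sigma2)
        self._norm1 = 1.0 / np.sqrt(s1)
        self._norm2 = 1.0 / np.sqrt(s2)

        # first layer: sampled filters (truncated support) + output lengths
        self.psi1_hat: List[np.ndarray] = []
        self.len1: List[int] = []
        for j, (xi, sg) in enumerate(zip(self.xi1, self.sigma1)):
            f_hi = fs / 2 if j == 0 else min(xi + SUPPORT_SIGMAS * sg, fs / 2)
            m = _sub_len(n, 2.0 * f_hi / df)
            nb = min(nb_half, m)
            raw = np.exp(-0.5 * ((freqs[:nb] - xi) / sg) ** 2)
            self.psi1_hat.append(raw * self._norm1[:nb])
            self.len1.append(m)

        # second layer filters, sampled on the same df grid
        self.psi2_hat: List[np.ndarray] = []
        for xi, sg in zip(self.xi2, self.sigma2):
            f_hi = min(xi + SUPPORT_SIGMAS * sg, fs / 2)
            nb = min(nb_half, int(np.ceil(f_hi / df)) + 1)
            raw = np.exp(-0.5 * ((freqs[:nb] - xi) / sg) ** 2)
            self.psi2_hat.append(raw * self._norm2[:nb])

        self.phi_len = _sub_len(n, 2.0 * SUPPORT_SIGMAS * self.sigma_phi / df)
        nbp = min(nb_half, self.phi_len)
        self.phi_hat = self.phi_hat_raw[:nbp] * self._norm1[:nbp]

        self.pairs: Tuple[Tuple[int, int], ...] = tuple(
            (j1, j2)
            for j1 in range(len(self.xi1))
            for j2 in range(len(self.xi2))
            if self.xi2[j2] < self.xi1[j1]
        )
        # subsampling plan for the second layer: output length per pair
        self.len2: dict[Tuple[int, int], int] = {}
        for j1, j2 in self.pairs:
            f_hi = min(self.xi2[j2] + SUPPORT_SIGMAS * self.sigma2[j2], fs / 2)
            self.len2[(j1, j2)] = _sub_len(self.len1[j1], 2.0 * f_hi / df)
        self.pair_map: dict[int, List[int]] = {}
        for j1, j2 in self.pairs:
            self.pair_map.setdefault(j1, []).append(j2)

    # -- diagnostics ------------------------------------------------------

    def littlewood_paley(self) -> np.ndarray:
        """LP sum ``Σ|ψ̂|² + |φ̂|²`` of the *stored* layer-1 filters.

        Built from the truncated, normalized filters actually used by the
        transform, so it measures both the normalization and the support
        truncation.  Returned on the full positive DFT grid.
        """
        s = np.zeros(self.n // 2 + 1)
        s[: len(self.phi_hat)] += self.phi_hat ** 2
        for psi in self.psi1_hat:
            s[: len(psi)] += psi ** 2
        return s

    def frame_deviation(self) -> float:
        """Max deviation of the layer-1 LP sum from 1 (frame tightness)."""
        return float(np.max(np.abs(self.littlewood_paley() - 1.0)))


def build_filter_bank(config: ScatteringConfig, fs: float, n: int) -> FilterBank:
    """Construct the analytic filter bank for windows of ``n`` samples."""
    return FilterBank(config, fs, n)


def scattering_feature_length(config: ScatteringConfig) -> int:
    """Output length: 1 (order 0) + Q1·J (order 1) + admissible pairs."""
    xi1 = _center_freqs(1.0, config.Q1, config.J)   # fs cancels in comparisons
    xi2 = _center_freqs(1.0, config.Q2, config.J)
    n1 = len(xi1)
    n_pairs = 0
    if config.max_order == 2:
        n_pairs = int(sum((xi2[j2] < xi1[j1]) for j1 in range(len(xi1))
                          for j2 in range(len(xi2))))
    return 1 + n1 + n_pairs


def _subsampled_analytic(spec_pos: np.ndarray, n_full: int, m: int) -> np.ndarray:
    """Analytic signal of a positive-frequency spectrum, at dyadic length m.

    ``spec_pos`` holds bins ``0..len-1`` of the full-length spectrum; bins
    beyond it are zero.  Subsampling y[::n/m] equals the length-m inverse
    DFT of the first m bins scaled by m/n, because the analytic spectrum is
    (numerically) supported inside them.
    """
    z = np.zeros(m, dtype=complex)
    nb = min(len(spec_pos), m)
    z[:nb] = spec_pos[:nb]
    return np.fft.ifft(z) * (m / n_full)


def scattering_transform(
    segment: np.ndarray,
    config: ScatteringConfig | None = None,
    fs: float = 500.0,
    filter_bank: FilterBank | None = None,
    taper: bool | None = None,
) -> ScatteringFeatures:
    """Scattering coefficients of one window.

    Pass a prebuilt ``filter_bank`` when transforming many windows of the
    same length — bank construction dominates otherwise.  ``taper=None``
    applies the config's cosine taper; set False for invariance checks that
    need exact circular-shift behavior.
    """
    x = np.asarray(segment, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    config = config or (filter_bank.config if filter_bank else ScatteringConfig())
    fb = filter_bank or build_filter_bank(config, fs, x.size)
    if x.size != fb.n:
        raise ValueError(f"segment length {x.size} != filter bank length {fb.n}")

    if taper is None:
        taper = config.taper_seconds > 0
    if taper and config.taper_seconds > 0:
        nt = int(round(config.taper_seconds * fb.fs))
        nt = min(nt, x.size // 2)
        if nt > 0:
            w = np.ones(x.size)
            ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(nt) + 0.5) / nt))
            w[:nt] = ramp
            w[-nt:] = ramp[::-1]
            x = x * w

    n = fb.n
    X = np.fft.rfft(x)

    s0 = float(np.mean(np.abs(_subsampled_analytic(fb.phi_hat * X[: len(fb.phi_hat)],
                                                   n, fb.phi_len))))
    s1 = np.empty(len(fb.psi1_hat))
    s2_vals: List[float] = []
    order2 = config.max_order == 2

    for j1, (psi1, m1) in enumerate(zip(fb.psi1_hat, fb.len1)):
        u = np.abs(_subsampled_analytic(psi1 * X[: len(psi1)], n, m1))
        s1[j1] = float(u.mean())
        if not order2 or j1 not in fb.pair_map:
            continue
        U = np.fft.rfft(u)
        for j2 in fb.pair_map[j1]:
            psi2 = fb.psi2_hat[j2]
            m2 = fb.len2[(j1, j2)]
            nb = min(len(psi2), len(U), m2)
            y2 = _subsampled_analytic(psi2[:nb] * U[:nb], m1, m2)
            s2_vals.append(float(np.mean(np.abs(y2))))

    s2 = np.asarray(s2_vals) if order2 else np.empty(0)
    if config.log_transform:
        s0v = float(np.log(s0 + LOG_EPS))
        s1v = np.log(s1 + LOG_EPS)
        s2v = np.log(s2 + LOG_EPS) if s2.size else s2
    else:
        s0v, s1v, s2v = s0, s1, s2
    return ScatteringFeatures(
        s0=s0v, s1=s1v, s2=s2v,
        pairs=fb.pairs if order2 else (),
        log_transformed=config.log_transform,
    )
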
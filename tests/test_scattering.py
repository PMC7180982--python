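"""Scattering transform: frame property, invariances, stability."""

import numpy as np
import pytest

import hfsleep as hf
from hfsleep.scattering import (
    ScatteringConfig,
    ScatteringConfigError,
    build_filter_bank,
)

FS = 100.0
N = int(FS * 90)
CFG = ScatteringConfig(J=7)
CFG_RAW = ScatteringConfig(J=7, log_transform=False)


@pytest.fixture(scope="module")
def bank():
    return build_filter_bank(CFG_RAW, FS, N)


class TestFilterBank:
    def test_order1_filter_count(self):
        fb = build_filter_bank(ScatteringConfig(), 500.0, 45000)
        assert len(fb.psi1_hat) == 8 * 10  # Q1 * J

    def test_frame_bound(self, bank):
        """Littlewood-Paley sum of the stored filters stays within
        [1 - delta, 1] with delta <= 0.2 on the full DFT grid."""
        lp = bank.littlewood_paley()
        assert lp.max() <= 1.0 + 1e-9
        assert lp.min() >= 1.0 - 0.2
        assert bank.frame_deviation() <= 0.2

    def test_center_frequencies_strictly_decreasing(self, bank):
        assert np.all(np.diff(bank.xi1) < 0)
        assert np.all(np.diff(bank.xi2) < 0)

    def test_window_shorter_than_2_pow_J_rejected(self):
        with pytest.raises(ScatteringConfigError, match="smaller J"):
            build_filter_bank(ScatteringConfig(J=12), FS, 1000)

    def test_filters_are_bandpass(self, bank):
        for psi in bank.psi1_hat:
            assert psi[0] < 1e-6  # negligible DC response


class TestFeatureLength:
    def test_order1_count(self):
        assert hf.scattering_feature_length(
            ScatteringConfig(max_order=1)) == 1 + 80

    @pytest.mark.parametrize("cfg,n", [(CFG, N), (ScatteringConfig(), 45000)])
    def test_formula_matches_output(self, cfg, n, rng):
        fs = 100.0 if n == N else 500.0
        x = rng.standard_normal(n)
        out = hf.scattering_transform(x, cfg, fs)
        assert out.vector.size == hf.scattering_feature_length(cfg)

    def test_monotone_in_J(self):
        a = hf.scattering_feature_length(ScatteringConfig(J=5))
        b = hf.scattering_feature_length(ScatteringConfig(J=10))
        assert b > a


class TestTransform:
    def test_zero_input(self, bank):
        out = hf.scattering_transform(np.zeros(N), filter_bank=bank)
        assert np.all(out.vector == 0.0)
        out_log = hf.scattering_transform(np.zeros(N), CFG, FS)
        np.testing.assert_allclose(out_log.vector, np.log(1e-12))

    def test_positive_homogeneity_exact(self, bank, rng):
        x = rng.standard_normal(N)
        a = 3.7
        s1 = hf.scattering_transform(x, filter_bank=bank).vector
        s2 = hf.scattering_transform(a * x, filter_bank=bank).vector
        np.testing.assert_allclose(s2, a * s1, rtol=1e-12)

    def test_determinism(self, bank, rng):
        x = rng.standard_normal(N)
        v1 = hf.scattering_transform(x, filter_bank=bank).vector
        v2 = hf.scattering_transform(x.copy(), filter_bank=bank).vector
        np.testing.assert_array_equal(v1, v2)

    def test_non_finite_rejected(self, bank):
        x = np.zeros(N)
        x[0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            hf.scattering_transform(x, filter_bank=bank)

    def test_energy_decay(self, bank, rng):
        """Order-2 coefficients carry less energy than order-1 for noise."""
        x = rng.standard_normal(N)
        out = hf.scattering_transform(x, filter_bank=bank)
        assert np.sum(out.s2 ** 2) < np.sum(out.s1 ** 2)

    def test_translation_tolerance(self, bank, rng):
        """Circular shifts <= 1 s move the averaged features by < 1 %
        relative norm for band-limited input.  Taper disabled: this
        isolates the operator (and its subsampling scheme) in the exact
        circular setting; the boundary taper is tested separately."""
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (1, 30), btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(N))
        v0 = hf.scattering_transform(x, filter_bank=bank, taper=False).vector
        for shift_s in (0.5, 1.0):
            xs = np.roll(x, int(shift_s * FS))
            vs = hf.scattering_transform(xs, filter_bank=bank, taper=False).vector
            assert np.linalg.norm(vs - v0) < 0.01 * np.linalg.norm(v0)

    def test_taper_effect_is_modest(self, bank, rng):
        """The 1-s boundary taper perturbs shifted-window features only at
        the few-percent level (it exists to suppress wrap-around splatter,
        not to change the representation)."""
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (1, 30), btype="bandpass", fs=FS, output="sos")
        x = sosfiltfilt(sos, rng.standard_normal(N))
        v0 = hf.scattering_transform(x, filter_bank=bank).vector
        vs = hf.scattering_transform(np.roll(x, int(FS)), filter_bank=bank).vector
        assert np.linalg.norm(vs - v0) < 0.05 * np.linalg.norm(v0)

    def test_non_expansive_on_random_pairs(self, bank, rng):
        """||S(x) - S(y)|| <= (1 + delta) ||x - y|| over 50 random pairs
        (tight frame + modulus contraction + averaging)."""
        delta = bank.frame_deviation()
        for _ in range(50):
            x = rng.standard_normal(N)
            y = rng.standard_normal(N)
            sx = hf.scattering_transform(x, filter_bank=bank, taper=False).vector
            sy = hf.scattering_transform(y, filter_bank=bank, taper=False).vector
            assert np.linalg.norm(sx - sy) <= (1 + delta) * np.linalg.norm(x - y)

    def test_warp_stability_on_chirp(self):
        """A 1 % time warp moves the features much less than the signal:
        the relative feature distance is below the relative signal
        distance (direct computation of both, the stability oracle)."""
        fs, n = FS, N
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * (1.0 * t + 0.15 * t ** 2 / 2))
        tau = 0.01
        xw = np.sin(2 * np.pi * (1.0 * (t * (1 + tau)) + 0.15 * (t * (1 + tau)) ** 2 / 2))
        bank = build_filter_bank(CFG_RAW, fs, n)
        sx = hf.scattering_transform(x, filter_bank=bank).vector
        sw = hf.scattering_transform(xw, filter_bank=bank).vector
        sig_dist = np.linalg.norm(x - xw) / np.linalg.norm(x)
        feat_dist = np.linalg.norm(sx - sw) / np.linalg.norm(sx)
        assert feat_dist < sig_dist

    def test_length_mismatch_rejected(self, bank):
        with pytest.raises(ValueError, match="length"):
            hf.scattering_transform(np.zeros(N - 1), filter_bank=bank)
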
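"""Properties of the synthetic polysomnography generator."""

import numpy as np
import pytest

import hfsleep as hf
from hfsleep.bands import epoch_band_energies
from hfsleep.simulate import DEFAULT_SIGMA_EMG, StageSpectrumModel, TransitionModel


class TestTransitionModel:
    def test_rows_must_be_stochastic(self):
        m = np.full((5, 5), 0.2)
        m[0, 0] = 0.3  # row sums to 1.1
        with pytest.raises(ValueError, match="sum to 1"):
            TransitionModel(matrix=m, initial=np.full(5, 0.2))

    def test_default_is_valid(self):
        tm = TransitionModel.default()
        np.testing.assert_allclose(tm.matrix.sum(axis=1), 1.0, atol=1e-12)


class TestSimulateHypnogram:
    def test_absorbing_chain_stays_in_n2(self):
        tm = TransitionModel(matrix=np.eye(5), initial=np.array([0, 0, 0, 1.0, 0]))
        hyp = hf.simulate_hypnogram(50, tm, seed=3)
        assert set(hyp.stages) == {"N2"}

    def test_deterministic_given_seed(self):
        a = hf.simulate_hypnogram(200, seed=11)
        b = hf.simulate_hypnogram(200, seed=11)
        assert a.stages == b.stages
        assert a.stages != hf.simulate_hypnogram(200, seed=12).stages

    def test_uniform_chain_frequencies(self):
        """Empirical stage frequencies of a uniform chain stay within 3
        standard errors of 0.2 (multinomial CI oracle)."""
        n = 10_000
        tm = TransitionModel(matrix=np.full((5, 5), 0.2), initial=np.full(5, 0.2))
        hyp = hf.simulate_hypnogram(n, tm, seed=5)
        se = np.sqrt(0.2 * 0.8 / n)
        for count in hyp.counts().values():
            assert abs(count / n - 0.2) < 3 * se

    def test_n_epochs_validated(self):
        with pytest.raises(ValueError):
            hf.simulate_hypnogram(0)


class TestSimulateRecording:
    def test_deterministic_given_seed(self):
        hyp = hf.simulate_hypnogram(5, seed=1)
        a = hf.simulate_recording(hyp, seed=9)
        b = hf.simulate_recording(hyp, seed=9)
        for c in a.channels:
            np.testing.assert_array_equal(a.channels[c], b.channels[c])

    def test_nyquist_guard(self):
        hyp = hf.simulate_hypnogram(2, seed=1)
        with pytest.raises(ValueError, match="Nyquist|emg_band"):
            hf.simulate_recording(hyp, fs=200.0)  # emg_band reaches 250 Hz

    def test_emg_amplitude_tracks_stage(self):
        """Mean log EMG epoch energy in N1 exceeds REM when sigma differs."""
        model = StageSpectrumModel(
            sigma_emg={**DEFAULT_SIGMA_EMG, "R": 1.0, "N1": 20.0})
        stages = ["R"] * 20 + ["N1"] * 20
        rec = hf.simulate_recording(hf.Hypnogram(stages), model, seed=2)
        e = epoch_band_energies(rec.channels["EMG"], rec.fs, [(25, 250)])[:, 0]
        assert e[20:].mean() > e[:20].mean()

    def test_no_leakage_means_independent_high_band(self):
        """g=0: log EEG and EMG (80,250) Hz energies are uncorrelated."""
        from scipy import stats

        model = StageSpectrumModel(leakage_gain=0.0)
        hyp = hf.Hypnogram(["N1"] * 500)
        rec = hf.simulate_recording(hyp, model, seed=21)
        x = epoch_band_energies(rec.channels["C3-A2"], rec.fs, [(80, 250)])[:, 0]
        y = epoch_band_energies(rec.channels["EMG"], rec.fs, [(80, 250)])[:, 0]
        r, p = stats.pearsonr(x, y)
        assert abs(r) < 0.1
        assert p > 0.05

    def test_leakage_induces_high_band_correlation(self):
        """g=0.3 on an all-N1 night: shared EMG process dominates the EEG
        high band, so the log energies correlate strongly.  The threshold
        is calibrated to the generator: with leaked power a and floor
        power b per bin, the per-bin periodogram correlation is a/(a+b)
        (~0.71 at the defaults), so pooled r lands near 0.73."""
        model = StageSpectrumModel(leakage_gain=0.3)
        hyp = hf.Hypnogram(["N1"] * 500)
        rec = hf.simulate_recording(hyp, model, seed=22)
        x = epoch_band_energies(rec.channels["C3-A2"], rec.fs, [(80, 250)])[:, 0]
        y = epoch_band_energies(rec.channels["EMG"], rec.fs, [(80, 250)])[:, 0]
        assert hf.pearson_r(x, y) > 0.6

    def test_monotone_leakage(self):
        """Pooled (80,250) Hz log-energy correlation is non-decreasing in g."""
        rs = []
        for g in (0.0, 0.1, 0.3, 1.0):
            model = StageSpectrumModel(leakage_gain=g)
            hyp = hf.simulate_hypnogram(150, seed=31)
            rec = hf.simulate_recording(hyp, model, seed=32)
            x = epoch_band_energies(rec.channels["C3-A2"], rec.fs, [(80, 250)])[:, 0]
            y = epoch_band_energies(rec.channels["EMG"], rec.fs, [(80, 250)])[:, 0]
            rs.append(hf.pearson_r(x, y))
        assert all(b >= a for a, b in zip(rs, rs[1:])), rs

    def test_stage_separability_in_high_band(self):
        """With g>0, N1 epochs carry more (150,250) Hz EEG energy than REM."""
        hyp = hf.Hypnogram(["R"] * 30 + ["N1"] * 30)
        rec = hf.simulate_recording(hyp, StageSpectrumModel(leakage_gain=0.3), seed=4)
        e = epoch_band_energies(rec.channels["C3-A2"], rec.fs, [(150, 250)], log=False)[:, 0]
        assert e[30:].mean() > e[:30].mean()

    def test_spectrum_model_from_dict(self):
        m = StageSpectrumModel.from_dict({
            "leakage_gain": 0.5,
            "sigma_emg": {"W": 10, "R": 1, "N1": 5, "N2": 3, "N3": 2},
            "band_psd": {s: {"0.5-4": 10.0, "15-35": 2.0} for s in
                         ("W", "R", "N1", "N2", "N3")},
            "emg_band": [25, 200],
        })
        assert m.leakage_gain == 0.5
        assert m.band_psd["N2"][(0.5, 4.0)] == 10.0
        assert m.emg_band == (25, 200)

    def test_default_atonia_ordering(self):
        s = DEFAULT_SIGMA_EMG
        assert s["R"] < s["N3"] <= s["N2"] < s["N1"] < s["W"]


class TestLowpassVersion:
    def test_stopband_and_passband_sinusoids(self):
        fs = 500.0
        t = np.arange(int(fs * 60)) / fs
        for freq, keep in [(100.0, False), (10.0, True)]:
            x = np.sin(2 * np.pi * freq * t)
            rec = hf.Recording("s", fs, {"C3-A2": x})
            y = hf.lowpass_version(rec).channels["C3-A2"]
            ratio = np.sqrt(np.mean(y**2) / np.mean(x**2))
            if keep:
                assert abs(ratio - 1) < 0.01
            else:
                assert ratio < 0.01

    def test_high_band_attenuation_on_noise(self):
        """Broadband noise loses >= 40 dB of (80,250) Hz energy."""
        fs = 500.0
        x = np.random.default_rng(0).standard_normal(int(fs * 90))
        rec = hf.Recording("s", fs, {"C3-A2": x})
        y = hf.lowpass_version(rec).channels["C3-A2"]
        e_in = hf.band_energy(x[:15000], fs, (80, 250))
        e_out = hf.band_energy(y[:15000], fs, (80, 250))
        assert 10 * np.log10(e_in / e_out) >= 40

    def test_emg_passes_unchanged(self, small_recording):
        out = hf.lowpass_version(small_recording)
        np.testing.assert_array_equal(out.channels["EMG"], small_recording.channels["EMG"])
        assert not np.array_equal(out.channels["C3-A2"], small_recording.channels["C3-A2"])

    def test_cutoff_validated(self, small_recording):
        with pytest.raises(ValueError, match="Nyquist"):
            hf.lowpass_version(small_recording, cutoff=250.0)
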
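"""Feature assembly, SVM training and LOSOCV contracts."""

import numpy as np
import pytest

import hfsleep as hf
from hfsleep.scattering import ScatteringConfig
from hfsleep.staging import FeatureTable, _Standardizer


@pytest.fixture(scope="module")
def cfg():
    return hf.StagerConfig()


@pytest.fixture(scope="module")
def table(small_pairs, cfg):
    return hf.build_feature_table(small_pairs, cfg)


@pytest.fixture(scope="module")
def table_no_hf(small_pairs):
    return hf.build_feature_table(
        small_pairs, hf.StagerConfig(use_high_freq=False))


class TestAssembleFeatures:
    def test_dimension_without_high_freq(self, table_no_hf):
        d = hf.scattering_feature_length(ScatteringConfig(J=7))
        for v in table_no_hf.views.values():
            assert v.shape[1] == d

    def test_high_freq_adds_three_bands_per_channel(self, table, table_no_hf):
        for c in table.channels:
            assert table.views[c].shape[1] == table_no_hf.views[c].shape[1] + 3

    def test_padded_flags_first_two_epochs(self, small_pairs, cfg):
        t = hf.assemble_features(*small_pairs[0], cfg)
        assert t.padded[:2].all()
        assert not t.padded[2:].any()

    def test_label_alignment_enforced(self, small_pairs, cfg):
        rec, _ = small_pairs[0]
        bad_hyp = hf.Hypnogram(["N2"] * (rec.n_epochs - 1))
        with pytest.raises(ValueError, match="epochs"):
            hf.assemble_features(rec, bad_hyp, cfg)

    def test_missing_channel_rejected(self, small_pairs):
        cfg = hf.StagerConfig(channels=("C3-A2", "F3-A2"))
        with pytest.raises(KeyError, match="F3-A2"):
            hf.assemble_features(*small_pairs[0], cfg)

    def test_all_features_finite(self, table):
        for v in table.views.values():
            assert np.all(np.isfinite(v))


class TestStandardizer:
    def test_constant_columns_survive(self):
        x = np.hstack([np.ones((10, 1)), np.arange(10.0)[:, None]])
        s = _Standardizer.fit(x)
        out = s.transform(x)
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out[:, 0], 0.0)


class TestTrainSvm:
    def test_separable_blobs_fit_perfectly(self, rng):
        x = np.vstack([rng.normal(0, 0.3, (100, 2)), rng.normal(5, 0.3, (100, 2))])
        y = np.array(["W"] * 100 + ["R"] * 100)
        groups = np.tile(["a", "b", "c", "d"], 50)
        clf, hp = hf.train_svm(x, y, groups)
        assert (clf.predict(x) == y).mean() >= 0.99
        assert set(hp) == {"C", "gamma"}

    def test_single_class_rejected(self, rng):
        x = rng.standard_normal((20, 3))
        with pytest.raises(ValueError, match="single class"):
            hf.train_svm(x, np.array(["W"] * 20), np.array(["a"] * 20))

    def test_duplicating_rows_preserves_decisions(self, rng):
        """With fixed hyperparameters the decision function depends on the
        data distribution, not the row count."""
        cfg = hf.StagerConfig(svm_C=(10.0,), svm_gamma_factors=(1.0,))
        x = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(3, 1, (60, 3))])
        y = np.array(["N1"] * 60 + ["N2"] * 60)
        g = np.tile(["a", "b", "c"], 40)
        clf1, _ = hf.train_svm(x, y, g, cfg)
        clf2, _ = hf.train_svm(np.vstack([x, x]), np.concatenate([y, y]),
                               np.concatenate([g, g]), cfg)
        probe = rng.standard_normal((50, 3)) * 2 + 1.5
        # duplication is equivalent to doubling C, so small boundary
        # movement is expected; decisions stay stable away from it
        assert (clf1.predict(probe) == clf2.predict(probe)).mean() >= 0.9

    def test_chance_level_on_permuted_labels(self, rng):
        """Labels shuffled independently of features: held-out accuracy sits
        at the 1/5 chance level (within 3 binomial standard errors)."""
        n = 500
        x = rng.standard_normal((n, 6))
        y = np.asarray(hf.STAGES)[rng.integers(0, 5, n)]
        g = np.asarray([f"s{i % 5}" for i in range(n)])
        acc = []
        for hold in range(5):
            te = g == f"s{hold}"
            clf, _ = hf.train_svm(x[~te], y[~te], g[~te])
            acc.append((clf.predict(x[te]) == y[te]).mean())
        rate = float(np.mean(acc))
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(rate - 0.2) < 3 * se


@pytest.fixture(scope="module")
def losocv_result(table):
    return hf.losocv(table)


class TestLosocv:
    @pytest.fixture()
    def result(self, losocv_result):
        return losocv_result

    def test_one_fold_per_subject(self, result, small_pairs):
        _, folds = result
        assert len(folds) == len(small_pairs)

    def test_every_epoch_predicted_exactly_once(self, result, table):
        preds, _ = result
        assert len(preds) == table.n_rows
        key = preds[["subject", "epoch_index"]].apply(tuple, axis=1)
        assert key.is_unique

    def test_subject_order_invariance(self, table):
        """Fold content is subject-determined: shuffling row order does not
        change any epoch's prediction."""
        preds1, _ = hf.losocv(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_rows)
        shuffled = table.subset(perm)
        preds2, _ = hf.losocv(shuffled)
        merged = preds1.merge(preds2, on=["subject", "epoch_index"],
                              suffixes=("_a", "_b"))
        assert (merged["predicted_stage_a"] == merged["predicted_stage_b"]).all()

    def test_too_few_subjects_rejected(self, table):
        one = table.subset(table.subjects == table.subjects[0])
        with pytest.raises(ValueError, match="at least 3"):
            hf.losocv(one)


class TestSleepStager:
    def test_fit_losocv_results_object(self, table, cfg):
        res = hf.SleepStager(table, cfg).fit_losocv()
        assert res.confusion.total == table.n_rows
        assert 0 <= res.metrics.accuracy <= 100
        text = res.summary()
        assert "LOSOCV" in text and "kappa" in text

    def test_fit_then_predict_roundtrip(self, table, cfg):
        model = hf.SleepStager(table, cfg).fit()
        pred = model.predict_table(table)
        assert pred.shape == (table.n_rows,)
        assert set(pred) <= set(hf.STAGES)

    def test_save_load_round_trip(self, table, cfg, tmp_path):
        """A persisted model predicts identically after reload."""
        model = hf.SleepStager(table, cfg).fit()
        p = tmp_path / "model.pkl"
        model.save(p)
        restored = hf.SleepStager.load(p)
        np.testing.assert_array_equal(
            restored.predict_table(table), model.predict_table(table))

    def test_save_requires_fit(self, table, cfg, tmp_path):
        with pytest.raises(RuntimeError, match="fit"):
            hf.SleepStager(table, cfg).save(tmp_path / "m.pkl")

    def test_feature_table_concatenate_and_subset(self, table):
        half = table.subset(np.arange(table.n_rows) < table.n_rows // 2)
        rest = table.subset(np.arange(table.n_rows) >= table.n_rows // 2)
        glued = FeatureTable.concatenate([half, rest])
        np.testing.assert_array_equal(glued.subjects, table.subjects)
        for c in table.channels:
            np.testing.assert_array_equal(glued.views[c], table.views[c])
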
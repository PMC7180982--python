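"""Sleep staging: feature assembly, CCA fusion, kernel SVM, LOSOCV.

The pipeline follows a fixed recipe per 30-s epoch and EEG channel:

1. scattering features of the 90-s context window (current epoch plus the
   previous 60 s), computed on a 100 Hz-decimated copy of the channel —
   the classic staging information lives below 50 Hz, and the
   high-frequency content enters separately;
2. optionally (``use_high_freq``), the log10 energies of the (35,80),
   (80,150) and (150,250) Hz bands of the native-rate epoch — the
   muscle-tone surrogate features;
3. per-feature standardization (training-fold statistics), CCA fusion of
   the two channel views, and an RBF-kernel SVM with class weights inverse
   to stage frequency (N1 and N3 are rare; an unweighted SVM collapses
   them).

Evaluation is leave-one-subject-out cross-validation: CCA, scaling and the
SVM (including its inner hyperparameter search, grouped by subject) see
training subjects only; each epoch is predicted exactly once, by the fold
that holds out its subject.

The off/on pair of ``use_high_freq`` — run once on a 50 Hz low-passed copy
without band features, once on the raw recording with them — isolates the
contribution of the >35 Hz content to staging accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from sklearn.metrics import f1_score
from sklearn.svm import SVC

from .bands import CLASSIFIER_BANDS, Band, epoch_band_energies
from .cca import apply_cca, fit_cca
from .evaluate import ConfusionMatrix, MetricsReport, confusion, metrics
from .io import Hypnogram, Recording, check_alignment, context_window
from .scattering import ScatteringConfig, build_filter_bank, scattering_transform


@dataclass(frozen=True)
class StagerConfig:
    """End-to-end pipeline configuration.

    ``scatter_fs`` is the rate the scattering input is decimated to; with
    the default 100 Hz, ``scattering.J=7`` covers ~0.3–40 Hz.  ``cca_k``
    defaults to min(50, view dimension).  The SVM grid is C x gamma-factor,
    where the kernel width gamma = factor / (n_features * variance).
    """

    channels: Tuple[str, str] = ("C3-A2", "O2-A1")
    use_high_freq: bool = True
    stft_bands: Tuple[Band, ...] = CLASSIFIER_BANDS
    scatter_fs: float = 100.0
    scattering: ScatteringConfig = field(default_factory=lambda: ScatteringConfig(J=7))
    cca_k: int | None = None
    cca_reg: float = 1e-4
    svm_C: Tuple[float, ...] = (1.0, 10.0, 100.0)
    svm_gamma_factors: Tuple[float, ...] = (0.3, 1.0, 3.0)
    inner_folds: int = 3
    seed: int = 0


@dataclass
class FeatureTable:
    """Per-(subject, epoch) feature rows for the two channel views.

    ``views`` maps channel name -> (n_rows, d) matrix; rows are aligned
    with ``subjects``, ``epochs``, ``stages`` and the ``padded`` flag
    marking the first two epochs of each night, whose 90-s context was
    reflection-padded.
    """

    subjects: np.ndarray
    epochs: np.ndarray
    stages: np.ndarray
    padded: np.ndarray
    views: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n = self.subjects.size
        for name, m in self.views.items():
            if m.shape[0] != n:
                raise ValueError(f"view {name!r} has {m.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"non-finite features in view {name!r}")

    @property
    def n_rows(self) -> int:
        return int(self.subjects.size)

    @property
    def channels(self) -> list[str]:
        return list(self.views)

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            subjects=self.subjects[mask],
            epochs=self.epochs[mask],
            stages=self.stages[mask],
            padded=self.padded[mask],
            views={k: v[mask] for k, v in self.views.items()},
        )

    @classmethod
    def concatenate(cls, tables: Sequence["FeatureTable"]) -> "FeatureTable":
        chans = tables[0].channels
        return cls(
            subjects=np.concatenate([t.subjects for t in tables]),
            epochs=np.concatenate([t.epochs for t in tables]),
            stages=np.concatenate([t.stages for t in tables]),
            padded=np.concatenate([t.padded for t in tables]),
            views={c: np.vstack([t.views[c] for t in tables]) for c in chans},
        )


def _decimate(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Antialiased rational-rate resampling (sampling rates are rational)."""
    if target_fs == fs:
        return np.asarray(x, dtype=float)
    f = Fraction(target_fs / fs).limit_denominator(1000)
    return resample_poly(np.asarray(x, dtype=float), f.numerator, f.denominator)


_BANK_CACHE: dict = {}


def _bank(config: ScatteringConfig, fs: float, n: int):
    key = (config, fs, n)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = build_filter_bank(config, fs, n)
    return _BANK_CACHE[key]


def assemble_features(
    recording: Recording,
    hypnogram: Hypnogram,
    config: StagerConfig | None = None,
) -> FeatureTable:
    """Feature rows for one subject (recording must be notch-filtered).

    Per epoch and channel: scattering of the 90-s context window,
    concatenated with the high-frequency band features of the 30-s epoch
    when ``use_high_freq`` is on.  Epochs 0 and 1 are flagged as padded.
    """
    config = config or StagerConfig()
    check_alignment(recording, hypnogram)
    missing = [c for c in config.channels if c not in recording.channels]
    if missing:
        raise KeyError(f"channels {missing} missing in {recording.subject_id!r}")
    n_ep = recording.n_epochs
    views: Dict[str, np.ndarray] = {}
    for ch in config.channels:
        x = recording.channels[ch]
        xd = _decimate(x, recording.fs, config.scatter_fs)
        ne_d = int(round(config.scatter_fs * 30))
        n90 = 3 * ne_d
        fb = _bank(config.scattering, config.scatter_fs, n90)
        feats = []
        for i in range(n_ep):
            win = context_window(xd[: n_ep * ne_d], ne_d, i)
            feats.append(
                scattering_transform(win, filter_bank=fb).vector
            )
        mat = np.asarray(feats)
        if config.use_high_freq:
            hf = epoch_band_energies(x, recording.fs, config.stft_bands, log=True)
            mat = np.hstack([mat, np.atleast_2d(hf)[:n_ep]])
        views[ch] = mat
    padded = np.zeros(n_ep, dtype=bool)
    padded[: min(2, n_ep)] = True
    return FeatureTable(
        subjects=np.repeat(recording.subject_id, n_ep),
        epochs=np.arange(n_ep),
        stages=hypnogram.as_array()[:n_ep],
        padded=padded,
        views=views,
    )


def build_feature_table(
    pairs: Sequence[Tuple[Recording, Hypnogram]],
    config: StagerConfig | None = None,
) -> FeatureTable:
    """Assemble and stack features for several subjects."""
    config = config or StagerConfig()
    return FeatureTable.concatenate(
        [assemble_features(rec, hyp, config) for rec, hyp in pairs]
    )


# ---------------------------------------------------------------------------
# Standardization + CCA + SVM
# ---------------------------------------------------------------------------

@dataclass
class _Standardizer:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "_Standardizer":
        std = x.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        return cls(mean=x.mean(axis=0), std=std)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std


def train_svm(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    config: StagerConfig | None = None,
) -> tuple[SVC, dict]:
    """RBF-SVM with an inner subject-grouped grid search.

    Hyperparameters (C, kernel width) are chosen by ``inner_folds``-fold
    cross-validation *grouped by subject* on the training data only, scored
    by macro F1; class weights are inverse to class frequency.  Returns the
    refitted classifier and the chosen hyperparameters.
    """
    config = config or StagerConfig()
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set contains a single class")
    d = features.shape[1]
    var = float(features.var())
    gamma_base = 1.0 / (d * var) if var > 0 else 1.0 / d
    grid = [
        (C, gf * gamma_base)
        for C in config.svm_C
        for gf in config.svm_gamma_factors
    ]

    unique_groups = np.unique(groups)
    n_folds = min(config.inner_folds, unique_groups.size)
    best = None
    if len(grid) > 1 and n_folds >= 2:
        fold_of = {g: i % n_folds for i, g in enumerate(unique_groups)}
        fold_idx = np.asarray([fold_of[g] for g in groups])
        for C, gamma in grid:
            scores = []
            for f in range(n_folds):
                tr, va = fold_idx != f, fold_idx == f
                if np.unique(labels[tr]).size < 2 or va.sum() == 0:
                    continue
                clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced",
                          cache_size=200)
                clf.fit(features[tr], labels[tr])
                scores.append(
                    f1_score(labels[va], clf.predict(features[va]),
                             average="macro", zero_division=0)
                )
            score = float(np.mean(scores)) if scores else -np.inf
            if best is None or score > best[0]:
                best = (score, C, gamma)
        _, C, gamma = best
    else:
        C, gamma = grid[0]

    clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight="balanced", cache_size=200)
    clf.fit(features, labels)
    return clf, {"C": C, "gamma": gamma}


@dataclass
class FoldResult:
    subject: str
    n_test: int
    hyperparams: dict
    cca_correlations: np.ndarray
    feature_dim: int


def losocv(table: FeatureTable, config: StagerConfig | None = None):
    """Leave-one-subject-out predictions for every epoch.

    One fold per subject; standardization, CCA and the SVM (with its inner
    grouped search) are fitted on the remaining subjects only.  Returns a
    DataFrame (subject, epoch_index, true_stage, predicted_stage, padded)
    covering each epoch exactly once, plus per-fold metadata.
    """
    config = config or StagerConfig()
    subjects = np.unique(table.subjects)
    if subjects.size < 3:
        raise ValueError(f"LOSOCV needs at least 3 subjects, got {subjects.size}")
    ch1, ch2 = table.channels[:2]
    rows: List[pd.DataFrame] = []
    folds: List[FoldResult] = []
    for subj in subjects:
        test_mask = table.subjects == subj
        train = table.subset(~test_mask)
        test = table.subset(test_mask)
        assert not set(np.unique(train.subjects)) & {subj}, "subject leaked into training fold"

        s1 = _Standardizer.fit(train.views[ch1])
        s2 = _Standardizer.fit(train.views[ch2])
        v1_tr, v2_tr = s1.transform(train.views[ch1]), s2.transform(train.views[ch2])
        d = min(v1_tr.shape[1], v2_tr.shape[1])
        k = min(config.cca_k or 50, d, v1_tr.shape[0] - 2)
        proj = fit_cca(v1_tr, v2_tr, k=k, reg=config.cca_reg)
        f_tr = apply_cca(proj, v1_tr, v2_tr)
        f_te = apply_cca(proj, s1.transform(test.views[ch1]), s2.transform(test.views[ch2]))

        clf, hp = train_svm(f_tr, train.stages, train.subjects, config)
        pred = clf.predict(f_te)
        rows.append(pd.DataFrame({
            "subject": test.subjects,
            "epoch_index": test.epochs,
            "true_stage": test.stages,
            "predicted_stage": pred,
            "padded": test.padded,
        }))
        folds.append(FoldResult(
            subject=str(subj), n_test=int(test_mask.sum()), hyperparams=hp,
            cca_correlations=proj.correlations, feature_dim=f_tr.shape[1],
        ))
    predictions = pd.concat(rows, ignore_index=True)
    assert len(predictions) == table.n_rows
    return predictions, folds


# ---------------------------------------------------------------------------
# Model-style interface
# ---------------------------------------------------------------------------

class SleepStager:
    """Staging model over a multi-subject feature table.

    Build with :meth:`from_recordings` (which applies the 60 Hz notch and
    assembles features) or directly from a :class:`FeatureTable`.  ``fit``
    trains the fusion + classifier on all subjects; ``fit_losocv`` runs the
    leave-one-subject-out evaluation and returns a results object with the
    confusion matrix, every reported metric and a ``summary()``.
    """

    def __init__(self, table: FeatureTable, config: StagerConfig | None = None):
        self.table = table
        self.config = config or StagerConfig()
        self._fitted: dict | None = None

    @classmethod
    def from_recordings(
        cls,
        pairs: Sequence[Tuple[Recording, Hypnogram]],
        config: StagerConfig | None = None,
        notch_hz: float | None = 60.0,
    ) -> "SleepStager":
        from .preprocess import notch_recording

        config = config or StagerConfig()
        processed = []
        for rec, hyp in pairs:
            if notch_hz:
                rec = notch_recording(rec, f0=notch_hz)
            processed.append((rec, hyp))
        return cls(build_feature_table(processed, config), config)

    def fit(self) -> "SleepStager":
        """Train standardizers, CCA and SVM on the full table (in-sample)."""
        ch1, ch2 = self.table.channels[:2]
        s1 = _Standardizer.fit(self.table.views[ch1])
        s2 = _Standardizer.fit(self.table.views[ch2])
        v1, v2 = s1.transform(self.table.views[ch1]), s2.transform(self.table.views[ch2])
        k = min(self.config.cca_k or 50, v1.shape[1], v2.shape[1], v1.shape[0] - 2)
        proj = fit_cca(v1, v2, k=k, reg=self.config.cca_reg)
        fused = apply_cca(proj, v1, v2)
        clf, hp = train_svm(fused, self.table.stages, self.table.subjects, self.config)
        self._fitted = {"s1": s1, "s2": s2, "proj": proj, "clf": clf, "hyperparams": hp}
        return self

    def predict_table(self, table: FeatureTable) -> np.ndarray:
        if self._fitted is None:
            raise RuntimeError("call fit() first")
        ch1, ch2 = self.table.channels[:2]
        f = apply_cca(
            self._fitted["proj"],
            self._fitted["s1"].transform(table.views[ch1]),
            self._fitted["s2"].transform(table.views[ch2]),
        )
        return self._fitted["clf"].predict(f)

    def fit_losocv(self) -> "StagingResults":
        predictions, folds = losocv(self.table, self.config)
        return StagingResults(predictions=predictions, folds=folds, config=self.config)

    def save(self, path) -> None:
        """Persist the fitted model (scalers, CCA projection, SVM) plus the
        configuration to a versioned archive file."""
        import pickle

        from . import __version__

        if self._fitted is None:
            raise RuntimeError("call fit() before save()")
        payload = {
            "format_version": 1,
            "package_version": __version__,
            "config": self.config,
            "fitted": self._fitted,
            "channels": self.table.channels,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SleepStager":
        """Restore a saved model; prediction works without the training data."""
        import pickle

        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported model archive version: {payload.get('format_version')}")
        n_feat = {c: payload["fitted"]["s1" if i == 0 else "s2"].mean.size
                  for i, c in enumerate(payload["channels"][:2])}
        empty = FeatureTable(
            subjects=np.empty(0, dtype=object),
            epochs=np.empty(0, dtype=int),
            stages=np.empty(0, dtype=object),
            padded=np.empty(0, dtype=bool),
            views={c: np.empty((0, d)) for c, d in n_feat.items()},
        )
        model = cls(empty, payload["config"])
        model._fitted = payload["fitted"]
        return model


@dataclass
class StagingResults:
    """Cross-validated staging predictions and their evaluation."""

    predictions: pd.DataFrame
    folds: List[FoldResult]
    config: StagerConfig

    @property
    def confusion(self) -> ConfusionMatrix:
        return confusion(
            self.predictions["true_stage"], self.predictions["predicted_stage"]
        )

    @property
    def metrics(self) -> MetricsReport:
        return metrics(self.confusion)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"LOSOCV over {len(self.folds)} subjects, "
            f"{len(self.predictions)} epochs "
            f"({'with' if self.config.use_high_freq else 'without'} high-frequency features)",
            "",
            m.summary(),
            "",
            "per-fold hyperparameters:",
        ]
        for f in self.folds:
            lines.append(
                f"  {f.subject}: n={f.n_test}, C={f.hyperparams['C']}, "
                f"gamma={f.hyperparams['gamma']:.3g}, fused dim={f.feature_dim}"
            )
        return "\n".join(lines)
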
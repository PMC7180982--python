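"""Confusion matrix and staging performance metrics.

All metrics are computed from the unnormalized 5x5 confusion matrix
``M``, where ``M[p, q]`` counts expert-assigned stage-``p`` epochs predicted
as stage ``q`` (rows = expert, columns = predicted; class order Awake, REM,
N1, N2, N3):

* per-class precision ``PR_p = M_pp / column_p`` and recall
  ``RE_p = M_pp / row_p`` (as percentages),
* per-class F1 as their harmonic mean,
* overall accuracy ``ACC = trace(M) / total``,
* Cohen's kappa ``(p_o - p_e) / (1 - p_e)`` with the chance agreement
  ``p_e`` from the row/column marginals,
* Macro F1: the unweighted mean of the five per-class F1 values.

Zero-denominator conventions: a precision or recall with empty denominator
is defined as 0, and the F1 of a class with both zero is 0, so Macro F1
always averages five finite numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .stages import STAGES, normalize_stage


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of printed clinical tables;
    numpy's default rounds half to even)."""
    factor = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    """5x5 integer counts; rows = expert stage, columns = predicted stage."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.counts)
        if m.shape != (5, 5):
            raise ValueError(f"confusion matrix must be 5x5, got {m.shape}")
        if np.any(m < 0) or not np.all(m == np.rint(m)):
            raise ValueError("confusion matrix entries must be non-negative integers")
        object.__setattr__(self, "counts", m.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> np.ndarray:
        """Row-normalized percentages rounded half away from zero to
        integers — the style used in printed staging tables."""
        rows = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(rows > 0, 100.0 * self.counts / rows, 0.0)
        return round_half_away(pct).astype(int)

    def to_csv(self, path) -> Path:
        path = Path(path)
        header = "," + ",".join(STAGES)
        lines = [header] + [
            s + "," + ",".join(str(v) for v in row)
            for s, row in zip(STAGES, self.counts)
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        lines = [ln for ln in Path(path).read_text().strip().splitlines() if ln.strip()]
        if len(lines) != 6:
            raise ValueError(f"{path}: expected a header row plus 5 class rows")
        header = [c.strip() for c in lines[0].split(",")][1:]
        if [normalize_stage(h) for h in header] != list(STAGES):
            raise ValueError(f"{path}: header columns must be {STAGES}, got {header}")
        counts = np.zeros((5, 5), dtype=np.int64)
        for i, ln in enumerate(lines[1:]):
            cells = [c.strip() for c in ln.split(",")]
            if normalize_stage(cells[0]) != STAGES[i]:
                raise ValueError(f"{path}: row {i} labelled {cells[0]!r}, expected {STAGES[i]}")
            counts[i] = [int(c) for c in cells[1:6]]
        return cls(counts)


def confusion(true: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Unnormalized confusion matrix of two equal-length stage sequences."""
    t = [normalize_stage(s) for s in true]
    p = [normalize_stage(s) for s in predicted]
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    idx = {s: i for i, s in enumerate(STAGES)}
    m = np.zeros((5, 5), dtype=np.int64)
    for a, b in zip(t, p):
        m[idx[a], idx[b]] += 1
    return ConfusionMatrix(m)


@dataclass(frozen=True)
class MetricsReport:
    """Per-class PR/RE/F1 (percent), overall ACC (percent), kappa, Macro F1."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    kappa: float
    macro_f1: float

    def rounded(self) -> dict:
        """Values at the print precision: 2 decimals for percentages, 4 for
        kappa; per-class values additionally as integers (table style)."""
        return {
            "accuracy_pct": float(round_half_away(self.accuracy, 2)),
            "macro_f1_pct": float(round_half_away(self.macro_f1, 2)),
            "kappa": float(round_half_away(self.kappa, 4)),
            "per_class": {
                s: {
                    "precision_pct": int(round_half_away(self.precision[i])),
                    "recall_pct": int(round_half_away(self.recall[i])),
                    "f1_pct": int(round_half_away(self.f1[i])),
                }
                for i, s in enumerate(STAGES)
            },
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.rounded(), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def summary(self) -> str:
        lines = [
            f"{'stage':<6}{'PR%':>8}{'RE%':>8}{'F1%':>8}",
        ]
        for i, s in enumerate(STAGES):
            lines.append(
                f"{s:<6}{self.precision[i]:>8.2f}{self.recall[i]:>8.2f}{self.f1[i]:>8.2f}"
            )
        lines.append("")
        lines.append(f"overall accuracy: {self.accuracy:.2f}%")
        lines.append(f"macro F1:         {self.macro_f1:.2f}%")
        lines.append(f"Cohen's kappa:    {self.kappa:.4f}")
        return "\n".join(lines)


def metrics(matrix: ConfusionMatrix) -> MetricsReport:
    """All staging metrics from a confusion matrix, unrounded intermediates."""
    m = matrix.counts.astype(float)
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(m)
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(col > 0, diag / col, 0.0) * 100.0
        re = np.where(row > 0, diag / row, 0.0) * 100.0
        denom = pr + re
        f1 = np.where(denom > 0, 2.0 * pr * re / denom, 0.0)
    po = diag.sum() / total
    pe = float(row @ col) / total ** 2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return MetricsReport(
        precision=pr,
        recall=re,
        f1=f1,
        accuracy=100.0 * po,
        kappa=float(kappa),
        macro_f1=float(f1.mean()),
    )
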
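"""Published reference confusion matrices for metric verification.

These are the two printed leave-one-subject-out confusion matrices from a
ten-subject overnight polysomnography study (7556 thirty-second epochs,
C3-A2 and O2-A1 channels) comparing sleep staging on 50 Hz low-passed
versus unfiltered 500 Hz EEG.  They serve as exact worked examples for the
:mod:`hfsleep.evaluate` metrics: the published headline numbers are
ACC 78.70 % / Macro F1 66.97 % / kappa 0.6803 for the filtered run and
ACC 79.52 % / Macro F1 70.30 % / kappa 0.6972 for the unfiltered run.

Rows are expert stages, columns predicted stages, order (Awake, REM, N1,
N2, N3).
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

_FILTERED = np.array([
    [1894,   26,   91,   67,    1],
    [  27,  470,   54,  162,    0],
    [ 258,  137,  181,  238,    2],
    [  97,   83,  116, 3143,  152],
    [   0,    0,    1,   97,  259],
])

_UNFILTERED = np.array([
    [1817,   36,  164,   62,    0],
    [  15,  576,   48,   74,    0],
    [ 262,   90,  249,  213,    2],
    [  84,   54,  184, 3106,  163],
    [   0,    0,    1,   95,  261],
])


def reference_confusion(variant: str) -> ConfusionMatrix:
    """Published confusion matrix: ``"filtered"`` (50 Hz low-passed EEG) or
    ``"unfiltered"`` (raw 500 Hz EEG)."""
    if variant == "filtered":
        return ConfusionMatrix(_FILTERED.copy())
    if variant == "unfiltered":
        return ConfusionMatrix(_UNFILTERED.copy())
    raise ValueError(f"variant must be 'filtered' or 'unfiltered', got {variant!r}")
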
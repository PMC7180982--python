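"""The five AASM sleep stages and their canonical order.

Every confusion matrix, transition matrix and per-stage table in this
package uses the fixed order (Awake, REM, N1, N2, N3).
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("W", "R", "N1", "N2", "N3")
"""Short stage codes in canonical order: Awake, REM, N1, N2, N3."""

STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

LONG_NAMES: dict[str, str] = {
    "W": "Awake",
    "R": "REM",
    "N1": "N1",
    "N2": "N2",
    "N3": "N3",
}

_ALIASES = {
    "W": "W", "WAKE": "W", "AWAKE": "W",
    "R": "R", "REM": "R",
    "N1": "N1", "1": "N1",
    "N2": "N2", "2": "N2",
    "N3": "N3", "3": "N3",
}


def normalize_stage(label: str) -> str:
    """Map a stage label (short code or long name) to its short code.

    Raises ``ValueError`` for anything outside the 5-class vocabulary.
    """
    key = str(label).strip().upper()
    try:
        return _ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown sleep stage label {label!r}; expected one of {STAGES}"
        ) from None
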
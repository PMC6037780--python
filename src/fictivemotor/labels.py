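"""Motor-pattern label vocabulary.

The isolated larval nerve cord produces a small repertoire of fictive motor
patterns: forward waves (FW, activity propagating posterior->anterior),
backward waves (BW, anterior->posterior), anterior bursts (AT, synchronous
activity in anterior neuromeres, often left/right asymmetric), posterior
bursts (PT, posterior-most neuromeres), and quiescence (QS).  Windows whose
activity matches none of these are left unlabeled (UL).
"""

from __future__ import annotations

from enum import Enum


class MotorLabel(str, Enum):
    """Closed set of per-window / per-frame motor-pattern labels."""

    AT = "AT"  # anterior burst
    BW = "BW"  # backward wave (anterior -> posterior)
    FW = "FW"  # forward wave (posterior -> anterior)
    PT = "PT"  # posterior burst
    QS = "QS"  # quiescence
    UL = "UL"  # unlabeled

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


#: The four named motor patterns scored against ground truth.
PATTERNS = (MotorLabel.AT, MotorLabel.BW, MotorLabel.FW, MotorLabel.PT)

#: The five states used for Markov transition analysis (UL excluded).
MARKOV_STATES = (
    MotorLabel.AT,
    MotorLabel.BW,
    MotorLabel.FW,
    MotorLabel.PT,
    MotorLabel.QS,
)


def as_label(value: "str | MotorLabel") -> MotorLabel:
    """Coerce a string to a :class:`MotorLabel`, raising on unknown names."""
    if isinstance(value, MotorLabel):
        return value
    try:
        return MotorLabel(value)
    except ValueError as exc:
        raise ValueError(f"unknown motor label {value!r}") from exc
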
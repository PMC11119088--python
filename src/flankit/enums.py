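"""Shared categorical vocabulary for the task engine and scoring pipeline."""

from enum import Enum


class Condition(str, Enum):
    """Assessment variant: fixed-deadline flanker or gamified adaptive flanker."""

    TRADITIONAL = "TRADITIONAL"
    GAMIFIED = "GAMIFIED"


class Phase(str, Enum):
    PRACTICE = "PRACTICE"
    TEST = "TEST"


class Congruency(str, Enum):
    CONGRUENT = "CONGRUENT"
    INCONGRUENT = "INCONGRUENT"


class Direction(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Response(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    NONE = "NONE"


class Outcome(str, Enum):
    """Trial classification: correct, wrong-direction press, or no response in time."""

    CORRECT = "CORRECT"
    COMMISSION = "COMMISSION"
    OMISSION = "OMISSION"


class Feedback(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


class OrderPosition(str, Enum):
    FIRST = "FIRST"
    SECOND = "SECOND"


class Preference(str, Enum):
    """Forced-choice 'which would you play again' answer."""

    GA = "GA"
    FLANKER = "FLANKER"
    NONE = "NONE"
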
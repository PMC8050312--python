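"""Shared enumerations and exception types for the pincontrol package."""

from __future__ import annotations

from enum import Enum


class Direction(str, Enum):
    """Horizontal sway direction: anteroposterior (x) or mediolateral (y)."""

    AP = "AP"
    ML = "ML"


class Condition(str, Enum):
    """Sensory condition of a standing trial."""

    EO = "EO"  # eyes open
    EC = "EC"  # eyes closed
    FB = "FB"  # weight-bearing feedback


class Group(str, Enum):
    """Stander category: prosthesis user, mechanically constrained, or free."""

    TPU = "TPU"
    AB_CONSTRAINED = "AB_constrained"
    AB_FREE = "AB_free"


class Limb(str, Enum):
    """Role of the limb whose CoP enters a correlation."""

    CONSTRAINED = "constrained_prosthetic"
    UNCONSTRAINED = "unconstrained_intact"
    TOTAL = "total"


class Definition(str, Enum):
    """Which inverted-pendulum test a correlation belongs to."""

    KINETIC = "kinetic"
    KINEMATIC = "kinematic"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class PinControlError(Exception):
    """Base class for package errors."""


class ConfigError(PinControlError):
    """Invalid or inconsistent configuration (user error)."""


class UnstableSimulationError(PinControlError):
    """The closed-loop simulation diverged; message names the offending gains."""


class NoStanceError(PinControlError):
    """All samples of a wrench fall below the vertical-force threshold."""


class DegenerateTrialError(PinControlError):
    """A correlation was requested on a zero-variance series."""


class SchemaError(PinControlError):
    """A trial file does not conform to the canonical schema."""


class GapError(PinControlError):
    """A marker gap exceeds the maximum interpolatable run length."""
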
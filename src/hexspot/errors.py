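"""Exception hierarchy for hexspot.

All errors raised on bad user input derive from :class:`HexspotError` so the
CLI can map them to stable exit codes (2 for invalid input, 3 for images
without exploitable grid structure).
"""


class HexspotError(Exception):
    """Base class for all hexspot errors."""


class InvalidInputError(HexspotError, ValueError):
    """Input violates a precondition (non-finite pixels, empty image, ...)."""


class NoStructureError(HexspotError, RuntimeError):
    """The image or profile carries no exploitable grid structure."""


class NoPeriodError(NoStructureError):
    """No periodicity could be detected in a luminance profile."""


class PatternError(NoStructureError):
    """Inflexion positions do not follow the alternating line pattern."""


class PairingError(HexspotError, ValueError):
    """Two spot collections cannot be paired one-to-one by grid index."""


class CannotAnchorError(HexspotError, ValueError):
    """Lattice inference has neither detections nor an extent to anchor on."""


class UndefinedMetricError(HexspotError, ArithmeticError):
    """A quality metric is undefined for this input (e.g. CV with zero mean)."""
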
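"""Core containers shared across the pipeline.

Image-processing functions in this package operate directly on numpy arrays
(the scikit-image idiom); :class:`IntensityImage` is a thin wrapper used by
file IO and the pipeline to carry bit-depth metadata alongside the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError


def validate_pixels(pixels: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Return ``pixels`` as a float64 2D array, checking basic invariants.

    Raises
    ------
    InvalidInputError
        If the array is empty, not 2D, contains non-finite values or
        negative values.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError(f"{name} must be a non-empty 2D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite pixel values")
    if arr.min() < 0:
        raise InvalidInputError(f"{name} contains negative pixel values")
    return arr


@dataclass
class IntensityImage:
    """Single-channel intensity image with grid metadata.

    Parameters
    ----------
    pixels:
        2D array of luminance values (nominal range ``1 .. 2**bit_depth``).
    bit_depth:
        Bit depth of the acquisition, 16 for microarray scanners.
    """

    pixels: np.ndarray
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.pixels = validate_pixels(self.pixels)

    @property
    def M(self) -> int:
        """Image height in pixels (number of rows)."""
        return self.pixels.shape[0]

    @property
    def N(self) -> int:
        """Image width in pixels (number of columns)."""
        return self.pixels.shape[1]

    @property
    def dynamic_max(self) -> int:
        return 2 ** self.bit_depth


@dataclass
class SpotGeometry:
    """Average spot geometry of a grid image.

    ``a``/``b`` are the horizontal/vertical spot radii in pixels; ``pitch_x``
    is the centre-to-centre spacing along a line of spots and ``pitch_y`` the
    spacing between consecutive lines.
    """

    a: float
    b: float
    pitch_x: float
    pitch_y: float

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise InvalidInputError("spot radii must be >= 1 pixel")
        if self.pitch_x < self.a or self.pitch_y <= 0:
            raise InvalidInputError("pitches inconsistent with spot radii")
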
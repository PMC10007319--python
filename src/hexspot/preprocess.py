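"""Image preprocessing: log enhancement, top-hat background removal, rotation.

Weakly expressed spots sit orders of magnitude below strong ones in raw
16-bit scans; a point-wise ``log(1 + p)`` followed by a min-max stretch to
the full dynamic range makes them detectable by the profile machinery.  A
white top-hat with a structuring element slightly larger than a spot strips
slowly varying background.  Misaligned scans are squared up by scanning
Radon projections for the angle whose profile has maximal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import radon

from .core import validate_pixels
from .errors import InvalidInputError, NoStructureError
from .grid import elliptical_se


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    dynamic_max:
        Upper end of the intensity dynamic range, ``2**bit_depth`` (65536
        for 16-bit scans; intensities nominally span 1..dynamic_max).
    tophat_radius_factor:
        Structuring-element radius as a multiple of the expected spot
        radius; slightly larger than a spot (default 1.5) removes
        background while preserving spots.
    rotation_search_degrees / rotation_step_degrees:
        Half-range and resolution of the rotation search.
    """

    dynamic_max: int = 2 ** 16
    tophat_radius_factor: float = 1.5
    rotation_search_degrees: float = 5.0
    rotation_step_degrees: float = 0.05
    median_radius: int = 1

    def __post_init__(self) -> None:
        if self.dynamic_max < 2:
            raise InvalidInputError("dynamic_max must be >= 2")
        if self.tophat_radius_factor <= 1.0:
            raise InvalidInputError("tophat_radius_factor must be > 1")
        if self.rotation_step_degrees <= 0:
            raise InvalidInputError("rotation_step_degrees must be > 0")
        if self.median_radius < 0:
            raise InvalidInputError("median_radius must be >= 0")


def log_enhance(pixels: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Point-wise ``log(1 + p)`` stretched linearly onto ``[1, dynamic_max]``.

    Monotone non-decreasing in the input, so pixel ranking is preserved.
    Constant images are returned unchanged (the stretch is degenerate).
    """
    cfg = cfg or PreprocessConfig()
    arr = validate_pixels(pixels)
    logged = np.log1p(arr)
    lo, hi = float(logged.min()), float(logged.max())
    if hi == lo:
        return arr.copy()
    return 1.0 + (logged - lo) / (hi - lo) * (cfg.dynamic_max - 1.0)


def denoise_median(pixels: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median filter with a ``(2r+1)``-square window; ``radius=0`` is a no-op.

    Applied between the log stretch and the top-hat: the log transform
    amplifies background noise into pixel-scale bright speckle that a
    top-hat would otherwise pass straight through.  A one-pixel-radius
    median removes the speckle without touching spots of the nominal
    (>= 3 px) diameter.
    """
    arr = validate_pixels(pixels)
    if radius == 0:
        return arr.copy()
    return ndimage.median_filter(arr, size=2 * radius + 1)


def top_hat(pixels: np.ndarray, se_radius_x: int, se_radius_y: int) -> np.ndarray:
    """White top-hat: image minus its opening with an elliptical element.

    Isolates bright structures smaller than the structuring element from
    slowly varying background; the result is >= 0 and <= the input
    everywhere (anti-extensivity of opening).  The opening uses reflected
    borders so the background estimate near the image edges has the same
    statistics as in the interior — a truncated-window policy would leave
    an elevated halo one element wide along every border.
    """
    arr = validate_pixels(pixels)
    footprint = elliptical_se(se_radius_x, se_radius_y)
    if footprint.shape[0] > arr.shape[0] or footprint.shape[1] > arr.shape[1]:
        raise InvalidInputError(
            f"structuring element {footprint.shape} larger than image {arr.shape}"
        )
    opened = ndimage.grey_opening(arr, footprint=footprint, mode="reflect")
    return arr - opened


def estimate_rotation(pixels: np.ndarray, cfg: PreprocessConfig | None = None) -> float:
    """Deviation of the grid-row direction from horizontal, in degrees.

    Radon projections are computed over ``±rotation_search_degrees`` around
    the row direction in steps of ``rotation_step_degrees``; the angle whose
    projection profile has maximal variance is the one at which the grid
    rows line up, i.e. the rotation to undo with :func:`correct_rotation`.
    """
    cfg = cfg or PreprocessConfig()
    arr = validate_pixels(pixels)
    if arr.max() == arr.min():
        raise NoStructureError("constant image: all projections are flat")
    offsets = np.arange(
        -cfg.rotation_search_degrees,
        cfg.rotation_search_degrees + cfg.rotation_step_degrees / 2,
        cfg.rotation_step_degrees,
    )
    # radon theta=90 integrates along image rows; a grid rotated by +t has
    # its rows aligned at theta = 90 + t.
    sinogram = radon(arr - arr.mean(), theta=90.0 + offsets, circle=False)
    variances = sinogram.var(axis=0)
    return float(offsets[int(np.argmax(variances))])


def correct_rotation(pixels: np.ndarray, angle: float) -> np.ndarray:
    """Rotate the image by ``-angle`` about its centre (bilinear).

    Out-of-frame pixels are filled with the image minimum so no false
    bright edges are created; dimensions are unchanged.  ``angle == 0``
    returns a copy untouched by interpolation.
    """
    arr = validate_pixels(pixels)
    if abs(angle) > 45:
        raise InvalidInputError("|angle| must be <= 45 degrees")
    if angle == 0.0:
        return arr.copy()
    return ndimage.rotate(
        arr, -angle, reshape=False, order=1, mode="constant", cval=float(arr.min())
    )
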
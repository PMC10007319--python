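"""Hexagonal-grid decomposition into two rectangular sub-grids.

A hexagonal layout interleaves two rectangular grids: the even-indexed and
uneven-indexed lines of spots, with alternate lines shifted by half a pitch.
The vertical-profile inflexions delimit each line; a band for line ``k``
runs from the centre of line ``k-1`` to the centre of line ``k+1``, so it
contains the full line plus the half-spots of its vertical neighbours.
Padding each band with background rows and opening it with an elliptical
structuring element of the spot radii removes those half-spots, and placing
the cleaned bands of one parity back into a background-valued frame yields
the rectangular sub-images ``I_ev`` / ``I_uev`` whose superposition (pixel
maximum) carries every spot of the original image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SpotGeometry, validate_pixels
from .errors import InvalidInputError, NoStructureError, PatternError
from .profiles import (
    InflexionSet,
    ShockConfig,
    autocorrelation_period,
    autocorrelation_radius,
    find_shock_inflexions,
    horizontal_profile,
    plateau_pairs,
    shock_filter_1d,
    vertical_profile,
)

#: fraction of a profile's dynamic range a jump must exceed to count as a shock
DEFAULT_MIN_JUMP_FRAC = 0.10

#: a line plateau must reach this fraction of the median line amplitude;
#: a vertical-profile line aggregates a whole line of spots, so genuine
#: lines are never this weak while border artefacts (rotation wedges,
#: margin noise) are
MIN_LINE_AMPLITUDE_FRAC = 0.5


@dataclass
class LineBand:
    """One line of spots and its vertical extent.

    ``top``/``bottom`` are the separation lines (half-open row interval);
    ``center`` is the row of the line's spot centres; ``index`` is the
    ordinal ``u`` within the parity family (the first uneven line, which has
    an extrapolated upper separation line, is ``u = 0``).
    """

    parity: str
    index: int
    top: int
    bottom: int
    center: float

    def __post_init__(self) -> None:
        if self.parity not in ("even", "uneven"):
            raise InvalidInputError("parity must be 'even' or 'uneven'")
        if self.top >= self.bottom:
            raise InvalidInputError("band top must be above bottom")


@dataclass
class GridDecomposition:
    """Result of splitting a hexagonal image into its two rectangular grids."""

    bands: list[LineBand]
    I_ev: np.ndarray
    I_uev: np.ndarray
    n_lines: int
    geometry: SpotGeometry
    layout: str = "hexagonal"  # or "rectangular"


def elliptical_se(a: int, b: int) -> np.ndarray:
    """Binary elliptical structuring element with radii ``a`` (x), ``b`` (y).

    Shape ``(2b+1, 2a+1)``; true where ``(x/a)**2 + (y/b)**2 <= 1``.
    """
    a, b = int(a), int(b)
    if a < 1 or b < 1:
        raise InvalidInputError("structuring-element radii must be >= 1")
    y, x = np.mgrid[-b:b + 1, -a:a + 1]
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


def detect_line_bands(pos: InflexionSet | np.ndarray) -> list[LineBand]:
    """Turn vertical-profile inflexions into per-line bands.

    Each physical line of spots contributes a rising and a falling
    inflexion; the midpoint of the pair is the line centre.  Line ``k``'s
    separation lines are the centres of lines ``k-1`` and ``k+1``
    (extrapolated by the local line spacing at the grid borders), so bands
    of the same parity tile without overlap while each band still contains
    the half-spots of the neighbouring (opposite-parity) lines.
    """
    positions = pos.positions if isinstance(pos, InflexionSet) else np.asarray(pos)
    positions = np.asarray(positions, dtype=np.float64).ravel()
    if positions.size < 4:
        raise NoStructureError(
            f"need at least 4 inflexions to delimit a line, got {positions.size}"
        )
    if positions.size % 2:
        raise PatternError(
            f"expected an even number of inflexions (rise/fall per line), got {positions.size}"
        )
    centers = 0.5 * (positions[0::2] + positions[1::2])
    spacing = np.diff(centers)
    if np.any(spacing <= 0):
        raise PatternError("line centres are not strictly increasing")
    med = float(np.median(spacing))
    if np.any(np.abs(spacing - med) > 0.5 * med):
        raise PatternError(
            "inflexion pattern violates alternating line spacing: "
            f"spacings {spacing.tolist()} vs median {med:.1f}"
        )
    n = centers.size
    ext = np.empty(n + 2)
    ext[1:-1] = centers
    ext[0] = centers[0] - spacing[0]
    ext[-1] = centers[-1] + spacing[-1]
    bands = []
    for k in range(1, n + 1):  # 1-based physical line number
        parity = "uneven" if k % 2 else "even"
        u = (k - 1) // 2 if parity == "uneven" else k // 2
        bands.append(
            LineBand(
                parity=parity,
                index=u,
                top=int(round(ext[k - 1])),
                bottom=int(round(ext[k + 1])),
                center=float(centers[k - 1]),
            )
        )
    return bands


def extract_parity_subimage(
    pixels: np.ndarray, bands: list[LineBand], geom: SpotGeometry
) -> np.ndarray:
    """Rebuild the rectangular sub-image of one parity family.

    Each band strip is padded with ``ceil(b/2)`` rows above and below and
    ``ceil(a/2)`` columns left and right at the image minimum, then opened
    with the elliptical structuring element of the spot radii (removing
    the neighbouring lines' half-spots), and placed back at its rows in an
    otherwise minimum-valued frame.  The horizontal padding matters too:
    without it the erosion windows at the strip borders are truncated, and
    border noise survives the opening as spot-sized blobs.
    """
    arr = validate_pixels(pixels)
    if not bands:
        raise InvalidInputError("need at least one band")
    M = arr.shape[0]
    # background-valued fill: robust low end rather than the absolute
    # minimum, which can be a single clipped pixel far below the background
    lo = float(np.percentile(arr, 1))
    se = elliptical_se(int(round(geom.a)), int(round(geom.b)))
    pad_y = math.ceil(geom.b / 2)
    pad_x = math.ceil(geom.a / 2)
    out = np.full_like(arr, lo)
    for band in bands:
        top = max(0, band.top)
        bottom = min(M, band.bottom)
        if top >= bottom:  # band entirely outside the image
            raise InvalidInputError(f"band rows {band.top}:{band.bottom} outside image")
        strip = arr[top:bottom]
        padded = np.full(
            (strip.shape[0] + 2 * pad_y, strip.shape[1] + 2 * pad_x), lo
        )
        padded[pad_y:pad_y + strip.shape[0], pad_x:pad_x + strip.shape[1]] = strip
        opened = ndimage.grey_opening(padded, footprint=se, mode="reflect")[
            pad_y:pad_y + strip.shape[0], pad_x:pad_x + strip.shape[1]
        ]
        out[top:bottom] = np.maximum(out[top:bottom], opened)
    return out


def _band_core_rows(band: LineBand, b: float, M: int) -> tuple[int, int]:
    """Rows within +-b of the line centre (excludes neighbour half-spots)."""
    top = max(0, int(round(band.center - b)))
    bottom = min(M, int(round(band.center + b)) + 1)
    return top, bottom


def _plateau_radius(pairs: list[tuple[int, int]], fallback: float) -> float:
    """Half the median plateau width of a shock-filtered profile.

    The shock filter develops its discontinuities at the edges of the
    original bumps, so plateau widths measure object extent directly; this
    is more reliable on preprocessed (sharpened) profiles than the
    autocorrelation half-width.
    """
    if not pairs:
        return fallback
    widths = np.array([down - up for up, down in pairs], dtype=np.float64)
    return max(2.0, float(np.median(widths)) / 2.0)


def _estimate_x_geometry(
    arr: np.ndarray,
    bands: list[LineBand],
    b: float,
    min_lag: int,
    shock_cfg: ShockConfig,
) -> tuple[float, float]:
    """Median pitch_x and radius ``a`` over per-line core-strip profiles."""
    pitches, radii = [], []
    for band in bands:
        top, bottom = _band_core_rows(band, b, arr.shape[0])
        profile = horizontal_profile(arr[top:bottom])
        rng = float(profile.max() - profile.min())
        if rng == 0.0:
            continue
        try:
            pitches.append(autocorrelation_period(profile, min_lag))
        except NoStructureError:
            continue
        sf = shock_filter_1d(profile, shock_cfg)
        pairs = plateau_pairs(sf, DEFAULT_MIN_JUMP_FRAC * float(sf.max() - sf.min()))
        widths = [down - up for up, down in pairs]
        if widths:
            radii.append(max(2.0, float(np.median(widths)) / 2.0))
    if not pitches:
        raise NoStructureError("no line strip shows horizontal periodicity")
    pitch_x = float(np.median(pitches))
    a = float(np.median(radii)) if radii else pitch_x / 4.0
    return pitch_x, min(a, pitch_x / 2.0)


def _hex_offset_estimate(
    arr: np.ndarray, bands: list[LineBand], b: float, pitch_x: float
) -> float:
    """Median |x-shift| between adjacent lines via profile cross-correlation."""
    shifts = []
    max_shift = int(round(pitch_x / 2))
    for first, second in zip(bands[:-1], bands[1:]):
        strips = []
        for band in (first, second):
            top, bottom = _band_core_rows(band, b, arr.shape[0])
            prof = horizontal_profile(arr[top:bottom])
            strips.append(prof - prof.mean())
        lags = np.arange(-max_shift, max_shift + 1)
        scores = [
            float(np.dot(strips[0], np.roll(strips[1], int(lag)))) for lag in lags
        ]
        shifts.append(abs(int(lags[int(np.argmax(scores))])))
    return float(np.median(shifts)) if shifts else 0.0


def decompose(
    pixels: np.ndarray,
    shock_cfg: ShockConfig | None = None,
    geometry: SpotGeometry | None = None,
    min_lag: int = 4,
    intensity_image: np.ndarray | None = None,
) -> GridDecomposition:
    """Full grid decomposition of a preprocessed image.

    Pipeline: vertical profile -> shock filter -> inflexions -> line bands;
    autocorrelation of the profiles supplies the spot radii and pitches
    (unless ``geometry`` overrides them); each parity family is then
    rebuilt as a rectangular sub-image by padding + morphological opening.
    Rectangular layouts (no x-shift between adjacent lines) are detected
    and routed entirely to the even family with tight, non-overlapping
    bands.

    ``intensity_image`` optionally supplies a different rendering of the
    same scene for the sub-image extraction and x-axis geometry (e.g. the
    log-enhanced image before background removal, whose margins are flat):
    band detection always runs on ``pixels``.
    """
    arr = validate_pixels(pixels)
    inten = arr if intensity_image is None else validate_pixels(intensity_image)
    if inten.shape != arr.shape:
        raise InvalidInputError("intensity_image must match the image shape")
    shock_cfg = shock_cfg or ShockConfig()
    V = vertical_profile(arr)
    if V.max() == V.min():
        raise NoStructureError("constant image: no grid structure")
    sf = shock_filter_1d(V, shock_cfg)
    min_jump = DEFAULT_MIN_JUMP_FRAC * float(sf.max() - sf.min())
    pairs = plateau_pairs(sf, min_jump)
    if pairs:
        amps = np.array([float(sf[up + 1: down + 1].max() - sf[up]) for up, down in pairs])
        keep = amps >= MIN_LINE_AMPLITUDE_FRAC * float(np.median(amps))
        pairs = [pair for pair, ok in zip(pairs, keep) if ok]
    # two inflexions per line of spots; unpaired jumps (image margins,
    # residual noise plateaus) are discarded by the pairing.  A jump at
    # left index `up` means the plateau starts at up+1, so the rising
    # positions are shifted by one to keep pair midpoints unbiased.
    pos = np.asarray([idx for up, down in pairs for idx in (up + 1, down)], dtype=np.float64)
    bands = detect_line_bands(pos)
    if len(bands) < 2:
        raise NoStructureError("fewer than 2 lines of spots detected")

    if geometry is None:
        pitch_y = float(autocorrelation_period(V, min_lag))
        b = min(_plateau_radius(pairs, fallback=pitch_y / 4.0), pitch_y / 2.0)
        pitch_x, a = _estimate_x_geometry(inten, bands, b, min_lag, shock_cfg)
        geometry = SpotGeometry(a=a, b=b, pitch_x=pitch_x, pitch_y=pitch_y)

    offset = _hex_offset_estimate(inten, bands, geometry.b, geometry.pitch_x)
    layout = "hexagonal" if offset > geometry.pitch_x / 4 else "rectangular"

    if layout == "rectangular":
        # single-grid mode: all lines in one family, tight bands, no
        # neighbour half-spots to remove
        centers = [band.center for band in bands]
        edges = [centers[0] - geometry.pitch_y / 2]
        edges += [0.5 * (c0 + c1) for c0, c1 in zip(centers[:-1], centers[1:])]
        edges += [centers[-1] + geometry.pitch_y / 2]
        bands = [
            LineBand(
                parity="even",
                index=k,
                top=int(round(max(0, edges[k]))),
                bottom=int(round(min(arr.shape[0], edges[k + 1]))),
                center=c,
            )
            for k, c in enumerate(centers, start=0)
        ]
        I_ev = extract_parity_subimage(inten, bands, geometry)
        I_uev = np.full_like(inten, float(inten.min()))
    else:
        even = [band for band in bands if band.parity == "even"]
        uneven = [band for band in bands if band.parity == "uneven"]
        I_ev = extract_parity_subimage(inten, even, geometry) if even else np.full_like(inten, float(inten.min()))
        I_uev = extract_parity_subimage(inten, uneven, geometry) if uneven else np.full_like(inten, float(inten.min()))

    return GridDecomposition(
        bands=bands,
        I_ev=I_ev,
        I_uev=I_uev,
        n_lines=len(bands),
        geometry=geometry,
        layout=layout,
    )


def bands_to_csv(bands: list[LineBand], path) -> None:
    """Write bands as a ``parity,u,top,bottom`` CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {"parity": b.parity, "u": b.index, "top": b.top, "bottom": b.bottom}
            for b in bands
        ]
    ).to_csv(path, index=False)
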
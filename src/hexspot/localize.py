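"""Per-line spot localisation and per-spot areas of interest.

Within a rectangular sub-image, the horizontal profile of each line band is
shock-filtered; plateaus bracketed by a rising and a falling inflexion are
spots, their centres the plateau midpoints.  Weak or absent spots leave gaps
that are filled by fitting an ideal 1D lattice (period = pitch_x, phase by
least squares) to the detections and inserting the unmatched lattice sites
flagged as missing.  Every spot finally receives a pitch-sized rectangular
area of interest ``S`` in which segmentation operates — the "cookie cutter"
of commercial microarray software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpotGeometry, validate_pixels
from .errors import CannotAnchorError, InvalidInputError
from .grid import DEFAULT_MIN_JUMP_FRAC, LineBand
from .profiles import ShockConfig, horizontal_profile, plateau_pairs, shock_filter_1d


@dataclass
class SpotRecord:
    """One spot of the grid: indices, geometry, masks and features.

    ``area`` is the half-open, 0-based rectangle ``(x0, y0, x1, y1)``
    confining the spot; masks (set by segmentation) are boolean arrays over
    that rectangle with ``fg & bg`` empty and ``fg | bg`` covering it.
    """

    line: int
    col: int
    parity: str
    center: tuple[float, float]  # (x, y)
    radii: tuple[float, float]  # (a, b)
    area: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    missing: bool = False
    fg_mask: np.ndarray | None = None
    bg_mask: np.ndarray | None = None
    fg_mean: float = float("nan")
    bg_mean: float = float("nan")
    intensity: float = float("nan")
    r2: float = float("nan")
    cv: float = float("nan")

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.area
        if not (x0 <= self.center[0] <= x1 and y0 <= self.center[1] <= y1):
            raise InvalidInputError("spot centre must lie inside its area S")


def locate_spots_in_line(
    subimage: np.ndarray,
    band: LineBand,
    shock_cfg: ShockConfig | None = None,
    min_jump_frac: float = DEFAULT_MIN_JUMP_FRAC,
) -> list[float]:
    """Spot x-centres along one line of a (parity) sub-image.

    Shock-filters the band strip's column-mean profile; each up-jump
    followed by a down-jump brackets one bright plateau whose midpoint is a
    spot centre.  A structureless strip yields an empty list (missing spots
    are recovered downstream by :func:`infer_missing`).
    """
    return [c for c, _ in locate_spots_with_amplitude(subimage, band, shock_cfg, min_jump_frac)]


def locate_spots_with_amplitude(
    subimage: np.ndarray,
    band: LineBand,
    shock_cfg: ShockConfig | None = None,
    min_jump_frac: float = DEFAULT_MIN_JUMP_FRAC,
) -> list[tuple[float, float]]:
    """Like :func:`locate_spots_in_line` but with plateau amplitudes.

    The amplitude (plateau peak minus its base level) lets downstream grid
    inference weigh detections: genuine spots dominate their line's median
    amplitude, while noise blobs that survived the morphological cleanup
    sit well below it.
    """
    arr = validate_pixels(subimage)
    top = max(0, band.top)
    bottom = min(arr.shape[0], band.bottom)
    if top >= bottom:
        raise InvalidInputError(f"band rows {band.top}:{band.bottom} outside sub-image")
    profile = horizontal_profile(arr[top:bottom])
    rng = float(profile.max() - profile.min())
    if rng == 0.0:
        return []
    filtered = shock_filter_1d(profile, shock_cfg or ShockConfig())
    frng = float(filtered.max() - filtered.min())
    if frng == 0.0:
        return []
    out = []
    for up, down in plateau_pairs(filtered, min_jump_frac * frng):
        # plateau spans up+1 .. down (inclusive); the centre is the midpoint
        # of its region above half height (FWHM midpoint), which stays on
        # the spot when a weaker artefact plateau merged into the same pair
        region = filtered[up + 1: down + 1]
        base = float(filtered[up])
        peak = float(region.max())
        top = np.flatnonzero(region >= base + 0.5 * (peak - base))
        center = up + 1 + (top[0] + top[-1]) / 2.0
        out.append((float(center), peak - base))
    return out


def infer_missing(
    centers: list[float],
    pitch_x: float,
    extent: tuple[float, float] | None,
    phase: float | None = None,
) -> list[tuple[float, bool]]:
    """Complete a line of detections against an ideal lattice.

    An ideal lattice ``phase + k * pitch_x`` is fitted to the detected
    centres by least squares (or anchored on a caller-supplied ``phase``,
    e.g. pooled over all lines of a parity family) and evaluated over
    ``extent``; the result has exactly one entry per lattice site: sites
    with a detection within ``pitch_x / 2`` keep the nearest detected
    centre verbatim, sites without one are inserted with the missing flag
    set.  Re-running on its own output is a no-op.
    """
    if pitch_x <= 0:
        raise InvalidInputError("pitch_x must be > 0")
    detected = np.sort(np.asarray(centers, dtype=np.float64))
    if detected.size == 0 and extent is None:
        raise CannotAnchorError("no detections and no extent to anchor the lattice")
    if phase is None:
        if detected.size == 0:
            phase = float(extent[0])
        else:
            phase = lattice_phase(detected, pitch_x)
    if extent is None:
        extent = (float(detected.min()), float(detected.max()))
    x_min, x_max = float(extent[0]), float(extent[1])
    k_lo = int(np.ceil((x_min - phase - pitch_x / 4) / pitch_x))
    k_hi = int(np.floor((x_max - phase + pitch_x / 4) / pitch_x))
    out: list[tuple[float, bool]] = []
    used = np.zeros(detected.size, dtype=bool)
    for k in range(k_lo, k_hi + 1):
        site = phase + k * pitch_x
        if detected.size:
            j = int(np.argmin(np.abs(detected - site)))
            if abs(detected[j] - site) <= pitch_x / 2 and not used[j]:
                used[j] = True
                out.append((float(detected[j]), False))
                continue
        out.append((float(site), True))
    out.sort(key=lambda t: t[0])
    return out


def lattice_phase(
    centers: np.ndarray, pitch_x: float, inlier_tol: float | None = None
) -> float:
    """Robust least-squares lattice phase of detections for a known pitch.

    Each detection's residual modulo the pitch proposes a phase; the
    proposal with the most detections within ``inlier_tol`` (default
    pitch/4) wins, and the phase is refined as the LSQ intercept of
    ``center ~ phase + k*pitch`` over those inliers.  This keeps stray
    detections (e.g. leakage from the opposite parity, offset by half a
    pitch) from biasing the grid.
    """
    detected = np.sort(np.asarray(centers, dtype=np.float64))
    if detected.size == 0:
        raise CannotAnchorError("no detections to fit a lattice phase")
    if inlier_tol is None:
        inlier_tol = pitch_x / 4.0
    res = detected % pitch_x
    # circular distance between residuals, counted per candidate phase
    diff = np.abs(res[:, None] - res[None, :])
    diff = np.minimum(diff, pitch_x - diff)
    counts = (diff <= inlier_tol).sum(axis=1)
    anchor = detected[int(np.argmax(counts))]
    k = np.round((detected - anchor) / pitch_x)
    resid = detected - k * pitch_x
    inliers = np.abs(resid - anchor) <= inlier_tol
    return float(np.mean(resid[inliers]))


def lattice_inliers(
    centers: np.ndarray, pitch_x: float, phase: float, tol: float | None = None
) -> np.ndarray:
    """Detections within ``tol`` (default pitch/4) of the ideal lattice."""
    detected = np.asarray(centers, dtype=np.float64)
    if tol is None:
        tol = pitch_x / 4.0
    res = np.abs((detected - phase + pitch_x / 2) % pitch_x - pitch_x / 2)
    return detected[res <= tol]


def build_spot_areas(
    line_centers: list[list[tuple[float, bool]]],
    bands: list[LineBand],
    geom: SpotGeometry,
    image_shape: tuple[int, int],
) -> list[SpotRecord]:
    """Assemble geometry-only spot records with pitch-sized areas S.

    ``line_centers[i]`` holds the completed (x, missing) list of
    ``bands[i]``; the y-centre is the band's line centre.  ``S`` is the
    axis-aligned rectangle of half-width ``round(pitch_x/2)`` and
    half-height ``round(pitch_y/2)`` around the rounded centre, clipped to
    the image.  Lines are numbered 1..n in band order, columns 1..alpha in
    x order.
    """
    if len(line_centers) != len(bands):
        raise InvalidInputError("one centre list per band required")
    M, N = image_shape
    half_w = int(round(geom.pitch_x / 2))
    half_h = int(round(geom.pitch_y / 2))
    records: list[SpotRecord] = []
    for line_no, (band, centers) in enumerate(zip(bands, line_centers), start=1):
        for col_no, (x, missing) in enumerate(centers, start=1):
            y = band.center
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(0, cx - half_w), min(N, cx + half_w)
            y0, y1 = max(0, cy - half_h), min(M, cy + half_h)
            records.append(
                SpotRecord(
                    line=line_no,
                    col=col_no,
                    parity=band.parity,
                    center=(float(x), float(y)),
                    radii=(geom.a, geom.b),
                    area=(x0, y0, x1, y1),
                    missing=bool(missing),
                )
            )
    return records
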
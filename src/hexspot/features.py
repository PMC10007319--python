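"""Spot segmentation inside the area of interest S and quality metrics.

Segmentation refines the rectangular S to the true spot shape: an Otsu
threshold on the S histogram proposes foreground, of which only the
connected component at (or nearest) the spot centre is kept; statistically
flat areas are declared missing.  Features are the background-subtracted
mean intensity, a model-fit coefficient of determination R², and the
coefficient of variation.  Accuracy and reproducibility metrics compare
detections with a reference annotation: mean Euclidean centre distance,
positioning accuracy, Pearson agreement of R² vectors, per-spot replicate
MAE and CV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .core import validate_pixels
from .errors import InvalidInputError, PairingError, UndefinedMetricError
from .localize import SpotRecord

#: flat-area guard: S is "missing" when its dynamic range is below this many
#: robust noise standard deviations
FLAT_RANGE_SIGMAS = 3.0


def _area_view(pixels: np.ndarray, rec: SpotRecord) -> np.ndarray:
    x0, y0, x1, y1 = rec.area
    view = pixels[y0:y1, x0:x1]
    if view.size == 0:
        raise InvalidInputError("spot area S is empty")
    return view


def robust_noise_sigma(values: np.ndarray) -> float:
    """Noise scale as 1.4826 x median absolute deviation."""
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def segment_spot(pixels: np.ndarray, rec: SpotRecord) -> SpotRecord:
    """Classify the pixels of S into foreground spot and local background.

    Mutates and returns ``rec``: sets ``fg_mask``/``bg_mask`` (a partition
    of S) and the missing flag.  The threshold is Otsu's on the S histogram;
    only the connected component containing — or, failing that, nearest to —
    the spot centre survives.  A statistically flat S (dynamic range under
    ``FLAT_RANGE_SIGMAS`` robust noise sigmas, or zero) has no detectable
    spot: empty foreground, ``missing=True``.  Conversely a lattice site
    inserted as missing upstream is un-flagged when a component is found,
    which is how weakly expressed spots dropped by profile localisation are
    recovered; an empty site under noise is then reported with its (near
    zero) background-subtracted intensity rather than a flag.
    """
    arr = validate_pixels(pixels)
    S = _area_view(arr, rec)
    x0, y0, _, _ = rec.area
    rng = float(S.max() - S.min())
    noise = robust_noise_sigma(S)
    if rng == 0.0 or rng < FLAT_RANGE_SIGMAS * noise:
        rec.fg_mask = np.zeros(S.shape, dtype=bool)
        rec.bg_mask = np.ones(S.shape, dtype=bool)
        rec.missing = True
        return rec
    thr = threshold_otsu(S)
    fg = S >= thr
    labels = label(fg, connectivity=2)
    cy = int(round(rec.center[1])) - y0
    cx = int(round(rec.center[0])) - x0
    cy = min(max(cy, 0), S.shape[0] - 1)
    cx = min(max(cx, 0), S.shape[1] - 1)
    target = labels[cy, cx]
    if target == 0:
        best, best_d = 0, np.inf
        for region in regionprops(labels):
            d = (region.centroid[0] - cy) ** 2 + (region.centroid[1] - cx) ** 2
            if d < best_d:
                best, best_d = region.label, d
        target = best
    keep = labels == target if target else np.zeros(S.shape, dtype=bool)
    rec.fg_mask = keep
    rec.bg_mask = ~keep
    rec.missing = not keep.any()
    return rec


def spot_intensity(pixels: np.ndarray, rec: SpotRecord) -> float:
    """Background-subtracted spot intensity: mean(fg) - mean(bg).

    May legitimately be <= 0 for artifacts; an empty foreground reports 0
    and flags the spot missing.
    """
    arr = validate_pixels(pixels)
    S = _area_view(arr, rec)
    if rec.fg_mask is None or rec.bg_mask is None:
        raise InvalidInputError("segment_spot must run before spot_intensity")
    if not rec.fg_mask.any():
        rec.missing = True
        rec.intensity = 0.0
        return 0.0
    rec.fg_mean = float(S[rec.fg_mask].mean())
    rec.bg_mean = float(S[rec.bg_mask].mean()) if rec.bg_mask.any() else 0.0
    rec.intensity = rec.fg_mean - rec.bg_mean
    return rec.intensity


def _gaussian_spot_model(coords, amplitude, cx, cy, sigma, offset):
    x, y = coords
    return amplitude * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma ** 2)) + offset


def spot_r2(pixels: np.ndarray, rec: SpotRecord) -> float:
    """Coefficient of determination of S against a fitted ideal spot model.

    The model is a radially symmetric Gaussian bump on a constant
    background, fitted by least squares over all S pixels; R² is the
    squared Pearson correlation between observed and fitted values,
    clipped to [0, 1].  Degenerate areas (zero variance, < 3 foreground
    pixels, failed fit) report 0 by convention.
    """
    arr = validate_pixels(pixels)
    S = _area_view(arr, rec)
    if rec.fg_mask is None or int(rec.fg_mask.sum()) < 3:
        rec.r2 = 0.0
        return 0.0
    if float(S.std()) == 0.0:
        rec.r2 = 0.0
        return 0.0
    yy, xx = np.mgrid[0: S.shape[0], 0: S.shape[1]]
    x0, y0, _, _ = rec.area
    p0 = (
        float(S.max() - S.min()),
        float(rec.center[0] - x0),
        float(rec.center[1] - y0),
        max(1.0, rec.radii[0] / 1.5),
        float(np.median(S)),
    )
    try:
        popt, _ = curve_fit(
            _gaussian_spot_model,
            (xx.ravel(), yy.ravel()),
            S.ravel(),
            p0=p0,
            maxfev=2000,
        )
        fitted = _gaussian_spot_model((xx.ravel(), yy.ravel()), *popt)
    except (RuntimeError, ValueError):
        rec.r2 = 0.0
        return 0.0
    if float(np.std(fitted)) == 0.0:
        rec.r2 = 0.0
        return 0.0
    r = float(np.corrcoef(S.ravel(), fitted)[0, 1])
    rec.r2 = float(np.clip(r ** 2, 0.0, 1.0))
    return rec.r2


def cv_spot(pixels: np.ndarray, rec: SpotRecord) -> float:
    """Coefficient of variation sigma/nu of background-subtracted fg pixels."""
    arr = validate_pixels(pixels)
    S = _area_view(arr, rec)
    if rec.fg_mask is None or not rec.fg_mask.any():
        raise InvalidInputError("foreground mask required for CV")
    bg_mean = float(S[rec.bg_mask].mean()) if rec.bg_mask is not None and rec.bg_mask.any() else 0.0
    vals = S[rec.fg_mask] - bg_mean
    nu = float(vals.mean())
    if nu == 0.0:
        raise UndefinedMetricError("CV undefined: mean background-subtracted intensity is 0")
    rec.cv = float(vals.std()) / nu
    return rec.cv


def center_distance_metrics(
    detected: np.ndarray, reference: np.ndarray, spot_diameter: float
) -> tuple[float, float, float]:
    """Accuracy of grid alignment against reference centres.

    ``detected``/``reference`` are (n, 2) arrays paired row-by-row (same
    grid index).  Returns the mean Euclidean distance mE, the standard
    deviation of the distances, and the percentage of spots positioned
    within half a spot diameter of the reference.
    """
    det = np.atleast_2d(np.asarray(detected, dtype=np.float64))
    ref = np.atleast_2d(np.asarray(reference, dtype=np.float64))
    if det.shape != ref.shape or det.shape[1] != 2:
        raise PairingError(f"cannot pair centres with shapes {det.shape} and {ref.shape}")
    if det.shape[0] == 0:
        raise PairingError("no centre pairs to compare")
    d = np.linalg.norm(det - ref, axis=1)
    accuracy = 100.0 * float(np.mean(d <= spot_diameter / 2.0))
    return float(d.mean()), float(d.std()), accuracy


def replicate_metrics(intensity_table: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-spot replicate MAE and its dataset average.

    ``intensity_table`` has one row per spot and one column per replicate
    (r >= 2).  Each spot's MAE is the mean absolute deviation of its
    replicate intensities from the spot's replicate mean — identical
    replicates give 0.
    """
    table = np.atleast_2d(np.asarray(intensity_table, dtype=np.float64))
    if table.shape[1] < 2:
        raise InvalidInputError("replicate metrics need r >= 2 replicates")
    mean = table.mean(axis=1, keepdims=True)
    mae = np.abs(table - mean).mean(axis=1)
    return mae, float(mae.mean())


def agreement_metrics(r2_a: np.ndarray, r2_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and mean absolute difference of two R² vectors."""
    a = np.asarray(r2_a, dtype=np.float64).ravel()
    b = np.asarray(r2_b, dtype=np.float64).ravel()
    if a.size != b.size or a.size < 2:
        raise PairingError("R² vectors must have equal length >= 2")
    if a.std() == 0.0 or b.std() == 0.0:
        raise UndefinedMetricError("Pearson correlation undefined for zero variance")
    r, _ = pearsonr(a, b)
    return float(r), float(np.abs(a - b).mean())


@dataclass
class QualityReport:
    """Accuracy/reproducibility summary of one evaluation run."""

    mE: float
    std: float
    accuracy: float
    pearson_r: float = float("nan")
    avgdiff: float = float("nan")
    mae_spot: float = float("nan")
    cv_spot: float = float("nan")
    n_spots: int = 0
    n_replicates: int = 1

    def to_dict(self) -> dict[str, float]:
        return {
            "mE": self.mE,
            "std": self.std,
            "accuracy": self.accuracy,
            "pearson_r": self.pearson_r,
            "avgdiff": self.avgdiff,
            "mae_spot": self.mae_spot,
            "cv_spot": self.cv_spot,
            "n_spots": self.n_spots,
            "n_replicates": self.n_replicates,
        }
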
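"""Spot detection, normalized-distance classification and molecule counting.

Pipeline: local-maximum candidates above a robust background threshold are
refined by 2D Gaussian fits to sub-pixel positions with background-
subtracted integrated intensities; each spot's normalized centroid
distance d (axial projection / cell half-length) assigns it to the
pole (CI reporter, d >= 0.6) or mid-cell (Cro reporter, d < 0.6) channel;
intensities are converted to molecule numbers against a single-molecule
intensity calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

D_THRESHOLD = 0.6
CHANNEL_POLE = "pole_ci"
CHANNEL_MID = "mid_cro"
CHANNEL_UNASSIGNED = "unassigned"


class CalibrationError(ValueError):
    """Single-molecule intensity sample unusable for calibration."""


@dataclass
class SpotRecord:
    position: tuple  # (x, y) pixels, sub-pixel
    intensity: float  # background-subtracted integrated intensity
    frame: int = 0
    cell_id: str = ""
    d: float | None = None
    channel: str = CHANNEL_UNASSIGNED
    flags: set = field(default_factory=set)

    def __post_init__(self):
        if self.intensity < 0:
            self.flags.add("negative_intensity")
            self.intensity = 0.0
        if self.d is not None and not (0.0 <= self.d <= 1.0):
            raise ValueError("d must lie in [0, 1]")


@dataclass
class CellGeometry:
    cell_id: str
    centroid: tuple  # (x, y) pixels
    axis: tuple  # long-axis unit vector
    half_length: float  # pixels
    mask: np.ndarray | None = None

    def __post_init__(self):
        norm = float(np.hypot(*self.axis))
        if norm <= 0:
            raise ValueError("axis vector must be non-zero")
        self.axis = (self.axis[0] / norm, self.axis[1] / norm)
        if self.half_length <= 0:
            raise ValueError("half_length must be > 0")


@dataclass
class IntensityCalibration:
    single_molecule_peak: float
    fit_sd: float
    n_samples: int

    def __post_init__(self):
        if self.single_molecule_peak <= 0:
            raise ValueError("peak must be > 0")


@dataclass
class DetectionParams:
    min_distance: int = 3
    threshold_sigma: float = 5.0  # candidates above background by this many robust SDs
    fit_window: int = 7  # odd window size for the Gaussian refinement
    saturation_level: float | None = None


def _gauss2d(coords, amp, x0, y0, sigma, offset):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma**2)) + offset
    ).ravel()


def detect_spots(image, params: DetectionParams | None = None) -> list[SpotRecord]:
    """Detect fluorescent spots in a 2D grayscale image.

    Deterministic for fixed parameters. Saturated fit windows are flagged
    ('saturated'), never silently dropped.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    p = params or DetectionParams()

    background = float(np.median(img))
    mad = float(np.median(np.abs(img - background)))
    robust_sd = max(1.4826 * mad, 1e-6)
    threshold = background + p.threshold_sigma * robust_sd

    peaks = peak_local_max(
        img, min_distance=p.min_distance, threshold_abs=threshold,
        exclude_border=False,
    )
    half = p.fit_window // 2
    ny, nx = img.shape
    records: list[SpotRecord] = []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(ny, r + half + 1)
        c0, c1 = max(0, c - half), min(nx, c + half + 1)
        win = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        amp0 = img[r, c] - background
        try:
            popt, _ = curve_fit(
                _gauss2d,
                (xx, yy),
                win.ravel(),
                p0=[amp0, c, r, 1.5, background],
                bounds=(
                    [0, c0 - 1, r0 - 1, 0.3, 0],
                    [np.inf, c1, r1, half + 2, np.inf],
                ),
                maxfev=2000,
            )
        except RuntimeError:
            continue
        amp, x0, y0, sigma, offset = popt
        integrated = float(2 * np.pi * amp * sigma**2)
        rec = SpotRecord(position=(float(x0), float(y0)), intensity=integrated)
        if p.saturation_level is not None and np.any(win >= p.saturation_level):
            rec.flags.add("saturated")
        records.append(rec)
    return records


def normalized_distance(position, geometry: CellGeometry) -> float:
    """Normalized axial centroid distance d in [0, 1].

    d = |projection of (spot - centroid) onto the long axis| / half_length,
    clipped to [0, 1]. Positions outside the cell mask are still assigned a
    d value; flagging is the caller's concern (see annotate_spots).
    """
    dx = position[0] - geometry.centroid[0]
    dy = position[1] - geometry.centroid[1]
    proj = abs(dx * geometry.axis[0] + dy * geometry.axis[1])
    return float(np.clip(proj / geometry.half_length, 0.0, 1.0))


def classify_spot(d: float, threshold: float = D_THRESHOLD) -> str:
    """Channel from normalized distance: d >= threshold is the pole/CI
    channel (boundary inclusive on the pole side), else mid/Cro."""
    if not (0.0 <= d <= 1.0):
        raise ValueError("d must lie in [0, 1]")
    return CHANNEL_POLE if d >= threshold else CHANNEL_MID


def annotate_spots(
    records: list[SpotRecord],
    geometry: CellGeometry,
    threshold: float = D_THRESHOLD,
) -> list[SpotRecord]:
    """Fill d and channel for every record in place; flags spots falling
    outside the cell mask (when a mask is provided)."""
    for rec in records:
        rec.d = normalized_distance(rec.position, geometry)
        rec.channel = classify_spot(rec.d, threshold)
        if geometry.mask is not None:
            x, y = int(round(rec.position[0])), int(round(rec.position[1]))
            inside = (
                0 <= y < geometry.mask.shape[0]
                and 0 <= x < geometry.mask.shape[1]
                and geometry.mask[y, x]
            )
            if not inside:
                rec.flags.add("outside_mask")
    return records


def calibrate_single_molecule_intensity(
    samples, floor: int = 30
) -> IntensityCalibration:
    """Gaussian fit to a single-molecule intensity sample.

    Returns the mode (= mean of the fitted Gaussian) and its sd. A sample
    whose fitted sd exceeds the peak indicates a multimodal/contaminated
    distribution and raises CalibrationError.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if len(arr) < floor:
        raise CalibrationError(
            f"need >= {floor} samples for calibration, got {len(arr)}"
        )
    peak = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if peak <= 0:
        raise CalibrationError("non-positive calibration peak")
    if sd > peak:
        raise CalibrationError(
            f"calibration sample too broad (sd {sd:.3g} > peak {peak:.3g}); "
            "likely multimodal"
        )
    return IntensityCalibration(
        single_molecule_peak=peak, fit_sd=sd, n_samples=len(arr)
    )


def intensity_to_molecules(
    integrated_intensity: float, calibration: IntensityCalibration
) -> int:
    """Molecule count = round(intensity / single-molecule peak), floored at
    0 (negative background-subtracted intensities count as 0)."""
    if integrated_intensity < 0:
        return 0
    return int(round(integrated_intensity / calibration.single_molecule_peak))


@dataclass
class CloudCount:
    count: int
    clipped: bool = False


def quantify_cloud(
    total_intensity: float,
    pole_spot_intensities,
    calibration: IntensityCalibration,
) -> CloudCount:
    """Delocalized (cloud) molecule count for high-expression regimes:
    (total cellular fluorescence - sum of pole-spot fluorescence) / peak,
    rounded, floored at 0. ``clipped`` is set when the pole sum exceeds
    the total."""
    if total_intensity < 0:
        raise ValueError("total intensity must be >= 0")
    pole_sum = float(np.sum(np.asarray(pole_spot_intensities, dtype=float)))
    residual = total_intensity - pole_sum
    if residual < 0:
        return CloudCount(count=0, clipped=True)
    return CloudCount(
        count=int(round(residual / calibration.single_molecule_peak)),
        clipped=False,
    )
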
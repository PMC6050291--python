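"""Synthetic fluorescence spot frames with known ground truth.

Renders a rod-shaped cell lying along the image x axis. Pole-targeted
spots are placed near the cell caps (axial fraction ~ N(0.85, 0.15),
mirrored to both poles), mid/quarter-targeted spots near the centroid and
quarter positions (mixture of N(0, 0.15) and N(0.45, 0.10) axial
fractions), each additionally jittered by the localization noise. Spots
are rendered as 2D Gaussian point-spread peaks over a constant background
with optional Poisson shot noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from switchkin.spot_quant import CellGeometry


@dataclass
class ImageParams:
    pixel_size_nm: float = 100.0
    shape: tuple = (48, 96)  # rows (y), cols (x)
    psf_sigma_nm: float = 120.0
    background: float = 100.0
    peak_intensity: float = 2000.0  # mean integrated counts per molecule
    intensity_cv: float = 0.15
    radial_sd_nm: float = 100.0
    shot_noise: bool = True
    saturation_level: float | None = None


@dataclass
class SpotFrame:
    image: np.ndarray
    truth: pd.DataFrame
    geometry: CellGeometry
    crowded: bool = False


# axial-position model (fractions of the cell half-length)
POLE_LOC, POLE_SD = 0.85, 0.15
MID_SD = 0.15
QUARTER_LOC, QUARTER_SD = 0.45, 0.10


def _axial_fractions(rng, n_pole, n_mid):
    pole = rng.normal(POLE_LOC, POLE_SD, size=n_pole)
    quarter = rng.random(n_mid) < 0.5
    mid = np.where(
        quarter,
        rng.normal(QUARTER_LOC, QUARTER_SD, size=n_mid),
        rng.normal(0.0, MID_SD, size=n_mid),
    )
    # mirror to both poles / both quarter positions
    pole = pole * rng.choice([-1.0, 1.0], size=n_pole)
    mid = mid * rng.choice([-1.0, 1.0], size=n_mid)
    return np.clip(pole, -1.05, 1.05), np.clip(mid, -1.05, 1.05)


def simulate_spot_frame(
    n_pole: int,
    n_mid: int,
    cell_length: float = 2500.0,
    localization_sd: float = 35.0,
    image_params: ImageParams | None = None,
    seed: int = 0,
    placement: str = "targeted",
) -> SpotFrame:
    """Render a synthetic frame with ``n_pole`` pole-targeted and ``n_mid``
    mid/quarter-targeted spots; returns image, ground-truth table and cell
    geometry. A crowding flag is raised when the expected PSF footprint of
    the spots exceeds ~40% of the cell area (detections become unreliable)."""
    if n_pole < 0 or n_mid < 0:
        raise ValueError("spot counts must be >= 0")
    p = image_params or ImageParams()
    rng = np.random.default_rng(seed)
    px = p.pixel_size_nm
    ny, nx = p.shape
    cx, cy = nx / 2.0, ny / 2.0
    half_len_px = (cell_length / 2.0) / px

    if placement == "targeted":
        pole_f, mid_f = _axial_fractions(rng, n_pole, n_mid)
    elif placement == "uniform":
        # detector-validation mode: spots spread over the whole cell so
        # that a resolvable field can be rendered at any count
        pole_f = rng.uniform(-1, 1, n_pole)
        mid_f = rng.uniform(-1, 1, n_mid)
    else:
        raise ValueError("placement must be 'targeted' or 'uniform'")
    frac = np.concatenate([pole_f, mid_f])
    cls = np.array(["pole"] * n_pole + ["mid"] * n_mid)

    x_nm = frac * (cell_length / 2.0) + rng.normal(0, localization_sd, len(frac))
    y_nm = rng.normal(0, p.radial_sd_nm, len(frac)) + rng.normal(
        0, localization_sd, len(frac)
    )
    x = cx + x_nm / px
    y = cy + y_nm / px
    inten = np.maximum(
        p.peak_intensity * (1 + p.intensity_cv * rng.standard_normal(len(frac))),
        0.1 * p.peak_intensity,
    ) if len(frac) else np.array([])

    sigma_px = p.psf_sigma_nm / px
    img = np.full((ny, nx), p.background, dtype=float)
    if len(frac):
        yy, xx = np.mgrid[0:ny, 0:nx]
        for xi, yi, ii in zip(x, y, inten):
            g = np.exp(
                -((xx - xi) ** 2 + (yy - yi) ** 2) / (2 * sigma_px**2)
            )
            img += ii / (2 * np.pi * sigma_px**2) * g
    if p.shot_noise:
        img = rng.poisson(np.maximum(img, 0)).astype(float)
    if p.saturation_level is not None:
        img = np.minimum(img, p.saturation_level)

    cell_area = cell_length * 2 * 4 * p.radial_sd_nm  # rough footprint
    spot_area = len(frac) * np.pi * (2 * p.psf_sigma_nm) ** 2
    crowded = cell_area > 0 and spot_area > 0.4 * cell_area

    truth = pd.DataFrame(
        {
            "x_px": x,
            "y_px": y,
            "class": cls,
            "intensity": inten,
            "axial_fraction": frac,
        }
    )
    geom = CellGeometry(
        cell_id="synthetic",
        centroid=(cx, cy),
        axis=(1.0, 0.0),
        half_length=half_len_px,
    )
    return SpotFrame(image=img, truth=truth, geometry=geom, crowded=crowded)


def write_spot_frame(frame: SpotFrame, out_dir, stem: str = "frame") -> None:
    """Persist a synthetic frame as a single-plane grayscale TIFF plus a
    TSV ground-truth table."""
    from pathlib import Path

    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}.tif", frame.image.astype(np.float32))
    frame.truth.to_csv(out / f"{stem}_truth.tsv", sep="\t", index=False)


def read_spot_image(path) -> np.ndarray:
    """Load a single-plane grayscale TIFF as float."""
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)
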
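"""Per-cell orientation and paired nuclear signaling intensity.

Orientation is the angle of the longest axis of the best-fit ellipse,
computed from the second-order area moments of the traced cell polygon
(the same ellipse standard raster toolchains fit), reported in
[-90, 90) and folded against the tissue axis into a [0, 90] deviation.
Nuclear intensity is read in a 6-pixel-diameter circle in the nucleus,
background-corrected by 4-pixel-diameter circles at five random
cytoplasmic positions, and normalized to DAPI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .config import RunConfig
from .types import CellOutline, PixelCalibration

logger = logging.getLogger(__name__)

__all__ = [
    "polygon_moments",
    "fit_orientation",
    "deviation_from_axis",
    "nuclear_signal",
    "depth_gate",
    "NEAR_ISOTROPIC_ASPECT",
]

#: Aspect ratios below this get the "near-isotropic" flag: the long-axis
#: angle of an almost-circular cell is numerically meaningless.
NEAR_ISOTROPIC_ASPECT = 1.05


def polygon_moments(vertices: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and central second-order moment matrix of a simple
    polygon (Green's-theorem closed forms)."""
    v = np.asarray(vertices, float)
    x, y = v[:, 0], v[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("zero-area polygon")
    cx = ((x + x1) * cross).sum() / (6 * area)
    cy = ((y + y1) * cross).sum() / (6 * area)
    # raw second moments about the origin
    ixx = ((y**2 + y * y1 + y1**2) * cross).sum() / 12
    iyy = ((x**2 + x * x1 + x1**2) * cross).sum() / 12
    ixy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24
    sign = np.sign(area)
    area = abs(area)
    # central, normalized by area
    mu_xx = sign * iyy / area - cx**2
    mu_yy = sign * ixx / area - cy**2
    mu_xy = sign * ixy / area - cx * cy
    cov = np.array([[mu_xx, mu_xy], [mu_xy, mu_yy]])
    return float(area), np.array([cx, cy]), cov


@dataclass
class OrientationFit:
    angle_deg: float
    aspect_ratio: float
    near_isotropic: bool
    area_um2: float


def fit_orientation(outline: CellOutline | np.ndarray) -> OrientationFit:
    """Best-fit-ellipse orientation of a cell outline.

    The ellipse shares the polygon's area moments; the returned angle is
    the major-axis direction in degrees, in [-90, 90) (image convention:
    positive angles rotate from +x toward +y).  Aspect ratios below
    :data:`NEAR_ISOTROPIC_ASPECT` are flagged near-isotropic.
    """
    verts = outline.vertices if isinstance(outline, CellOutline) else outline
    area, _, cov = polygon_moments(verts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate polygon: zero minor moment")
    major = evecs[:, 1]  # eigh sorts ascending
    angle = math.degrees(math.atan2(major[1], major[0]))
    angle = (angle + 90.0) % 180.0 - 90.0
    aspect = float(math.sqrt(evals[1] / evals[0]))
    near_iso = aspect < NEAR_ISOTROPIC_ASPECT
    if near_iso:
        logger.info("near-isotropic cell (aspect %.3f): orientation unreliable",
                    aspect)
    return OrientationFit(
        angle_deg=float(angle),
        aspect_ratio=aspect,
        near_isotropic=near_iso,
        area_um2=float(area),
    )


def deviation_from_axis(angle_deg: float, axis_angle_deg: float) -> float:
    """Deviation of a cell's long axis from the tissue axis, folded into
    [0, 90] (orientations are axial: 180° periodic)."""
    d = abs(float(angle_deg) - float(axis_angle_deg)) % 180.0
    return min(d, 180.0 - d)


def _circle_mean(image: np.ndarray, center_px: tuple[float, float],
                 diameter_px: float) -> float:
    """Mean intensity in a circle (diameter in px) on a 2D image; a pixel
    contributes when its center lies within the circle."""
    ny, nx = image.shape
    r = diameter_px / 2.0
    cx, cy = center_px
    x0, x1 = max(0, int(cx - r) - 1), min(nx, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(ny, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("circle outside image")
    gx, gy = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    sel = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
    if not sel.any():
        raise ValueError("circle contains no pixel centers")
    return float(image[y0:y1, x0:x1][sel].mean())


def nuclear_signal(
    outline: CellOutline,
    nucleus_center_um: tuple[float, float],
    signal_image: np.ndarray,
    dapi_image: np.ndarray,
    calibration: PixelCalibration,
    cytoplasm_spots_um: np.ndarray | None = None,
    config: RunConfig | None = None,
    n_spots: int = 5,
    rng: np.random.Generator | None = None,
) -> dict:
    """Background-corrected, DAPI-normalized nuclear signal of one cell.

    Signal and DAPI are averaged in a circle of
    ``config.nuclear_circle_diameter_px`` (default 6 px) at the nucleus
    center; the background is the mean signal over ``n_spots`` circles of
    ``config.cytoplasm_circle_diameter_px`` (default 4 px) at random
    cytoplasmic positions — inside the cell outline, outside the nuclear
    circle — drawn with ``rng`` when not supplied.  Corrected values are
    clamped at zero (with a warning) when the background exceeds the
    nuclear signal.
    """
    cfg = config or RunConfig()
    px = calibration.pixel_size_xy
    center_px = (nucleus_center_um[0] / px, nucleus_center_um[1] / px)
    nuc_d = cfg.nuclear_circle_diameter_px
    cyt_d = cfg.cytoplasm_circle_diameter_px

    raw = _circle_mean(signal_image, center_px, nuc_d)
    dapi = _circle_mean(dapi_image, center_px, nuc_d)

    if cytoplasm_spots_um is None:
        rng = rng or np.random.default_rng(cfg.seed)
        cytoplasm_spots_um = _draw_cytoplasm_spots(
            outline, nucleus_center_um, nuc_d * px / 2, cyt_d * px / 2, n_spots, rng
        )
    spots = np.atleast_2d(np.asarray(cytoplasm_spots_um, float))
    bg_means = [
        _circle_mean(signal_image, (sx / px, sy / px), cyt_d) for sx, sy in spots
    ]
    background = float(np.mean(bg_means))
    corrected = raw - background
    if corrected < 0:
        logger.warning(
            "background (%.2f) exceeds nuclear signal (%.2f); clamping to 0",
            background, raw,
        )
        corrected = 0.0
    if dapi <= 0:
        raise ValueError("non-positive DAPI mean in the nuclear circle")
    return {
        "raw": raw,
        "background": background,
        "corrected": corrected,
        "dapi": dapi,
        "ratio": corrected / dapi,
        "cytoplasm_spots_um": spots,
    }


def _draw_cytoplasm_spots(
    outline: CellOutline,
    nucleus_center_um,
    nucleus_radius_um: float,
    spot_radius_um: float,
    n_spots: int,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> np.ndarray:
    poly = Polygon(outline.vertices)
    inner = poly.buffer(-spot_radius_um)
    if inner.is_empty:
        raise ValueError("cytoplasm spots infeasible: outline too small")
    minx, miny, maxx, maxy = inner.bounds
    nx, nyc = nucleus_center_um
    spots = []
    for _ in range(max_tries):
        if len(spots) == n_spots:
            break
        p = rng.uniform((minx, miny), (maxx, maxy))
        if not shapely.contains_xy(inner, p[0], p[1]):
            continue
        if np.hypot(p[0] - nx, p[1] - nyc) <= nucleus_radius_um + spot_radius_um:
            continue
        spots.append(p)
    if len(spots) < n_spots:
        raise ValueError("cytoplasm spots infeasible within the outline")
    return np.array(spots)


def depth_gate(
    records: pd.DataFrame,
    mode: str = "explant",
    tissue_top_um: float = 0.0,
    depth_col: str = "depth",
) -> pd.DataFrame:
    """Depth gating of alignment/intensity records.

    Explant mode keeps plane depths in [45, 60] µm from the explant top;
    embryo mode keeps depths within 37.5 µm of the mesendoderm top
    (``tissue_top_um``).  Kept/dropped counts are logged.
    """
    if mode == "explant":
        keep = (records[depth_col] >= 45.0) & (records[depth_col] <= 60.0)
    elif mode == "embryo":
        rel = records[depth_col] - tissue_top_um
        keep = (rel >= 0.0) & (rel <= 37.5)
    else:
        raise ValueError("mode must be 'explant' or 'embryo'")
    logger.info("depth gate (%s): kept %d of %d records", mode,
                int(keep.sum()), len(records))
    return records[keep].reset_index(drop=True)


def measure_cells(
    outlines: list[CellOutline],
    axis_angle_deg: float,
    signal_image: np.ndarray | None = None,
    dapi_image: np.ndarray | None = None,
    calibration: PixelCalibration | None = None,
    config: RunConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Alignment (and optional intensity) records for a list of cells."""
    rows = []
    for cell in outlines:
        fit = fit_orientation(cell)
        row = {
            "cell_id": cell.cell_id,
            "angle_deg": fit.angle_deg,
            "deviation_deg": deviation_from_axis(fit.angle_deg, axis_angle_deg),
            "aspect_ratio": fit.aspect_ratio,
            "near_isotropic": fit.near_isotropic,
            "depth": cell.plane_z,
        }
        if signal_image is not None and cell.nucleus_center is not None:
            sig = nuclear_signal(
                cell, cell.nucleus_center, signal_image, dapi_image,
                calibration, config=config, rng=rng,
            )
            row.update(
                psmad5_corrected=sig["corrected"],
                dapi=sig["dapi"],
                psmad5_over_dapi=sig["ratio"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
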
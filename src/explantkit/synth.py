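"""Ground-truth-known synthetic fixtures for every input class of the pipeline.

Each generator emulates the statistical structure a downstream measurement
assumes — not the biology that produces it:

* :func:`make_explant_mask` — elongating explant silhouettes: a round body
  plus an optional narrower extension lobe joined at a concave neck.
* :func:`simulate_clone_flow` — clonal point clouds advected by an
  anisotropic affine flow with known axial/perpendicular endpoint scale
  factors (the quantity the dispersal statistic estimates).
* :func:`simulate_gradient_nuclei` — nucleus tables carrying a monotone
  signaling gradient plus a DAPI channel, additive background and a
  shared depth attenuation that DAPI normalization should cancel.
* :func:`simulate_cell_outlines` — polygonal cell outlines with
  orientations drawn from a wrapped distribution of known mean and
  concentration.
* :func:`render_channels` — Gaussian-blob raster rendering so detector
  and mask operations can be exercised on images.

All generators are deterministic under a fixed seed and return a
ground-truth record sufficient to replay the noise-free forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .types import (
    CellOutline,
    ExplantMask,
    NucleusTable,
    PixelCalibration,
    ReferenceAxis,
    ReferenceContour,
)

__all__ = [
    "FlowParams",
    "GradientParams",
    "OrientationParams",
    "make_explant_mask",
    "simulate_clone_flow",
    "simulate_gradient_nuclei",
    "simulate_cell_outlines",
    "render_channels",
    "wild_type_flow",
    "ectoderm_flow",
]


# --------------------------------------------------------------------------
# parameter records

@dataclass
class FlowParams:
    """Anisotropic affine clone flow.

    ``s_par``/``s_perp`` are the endpoint scale factors of pairwise
    separations along and perpendicular to the extension axis over the
    whole analysis window; intermediate frames interpolate exponentially
    in time (scale ``s**(k/(n_frames-1))`` at frame k), the simplest flow
    consistent with reported endpoint fold changes.
    """

    s_par: float = 2.02
    s_perp: float = 0.88
    n_cells: int = 40
    n_frames: int = 27
    frame_dt: float = 10.0  # minutes
    positional_noise_sd: float = 0.0  # µm
    axis_drift_sd: float = 0.0  # µm, anchor placement jitter
    blob_radius: float = 50.0  # µm, initial clone footprint radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s_par <= 0 or self.s_perp <= 0:
            raise ValueError("scale factors must be > 0")
        if self.n_cells < 2 or self.n_frames < 2:
            raise ValueError("need n_cells >= 2 and n_frames >= 2")
        if self.positional_noise_sd < 0 or self.axis_drift_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class GradientParams:
    """Nuclear signaling gradient along a normalized tissue axis.

    ``decay_length`` is in fractions of the axis; ``depth_attenuation``
    is the fractional intensity loss per 100 µm of imaging depth, applied
    multiplicatively to both the signal and DAPI channels.
    """

    profile_shape: str = "exponential"  # exponential | logistic | flat
    decay_length: float = 0.25
    amplitude: float = 200.0
    background_level: float = 20.0
    dapi_mean: float = 100.0
    dapi_cv: float = 0.0
    intensity_cv: float = 0.0
    n_nuclei: int = 800
    depth_attenuation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_shape not in ("exponential", "logistic", "flat"):
            raise ValueError("unknown profile shape")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        for cv in (self.dapi_cv, self.intensity_cv):
            if not 0 <= cv < 1:
                raise ValueError("cv must be in [0, 1)")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")


@dataclass
class OrientationParams:
    """Cell-orientation field with controllable alignment strength.

    ``concentration`` is the von Mises concentration of the axial (period
    180°) orientation distribution: 0 gives uniform orientations, large
    values lock all cells to ``mean_angle``.
    """

    mean_angle: float = 0.0  # degrees, in [-90, 90)
    concentration: float = 0.0
    n_cells: int = 100
    aspect_ratio_range: tuple[float, float] = (1.5, 2.5)
    major_axis_um: float = 15.0
    n_vertices: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not -90 <= self.mean_angle < 90:
            raise ValueError("mean_angle must be in [-90, 90)")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        lo, hi = self.aspect_ratio_range
        if lo < 1 or hi < lo:
            raise ValueError("aspect ratios must be >= 1 and ordered")


def wild_type_flow(**overrides) -> FlowParams:
    """Noise-free preset matching the measured wild-type mesendoderm
    deformation: 2.02-fold axial / 0.88-fold perpendicular dispersal
    change over a 260 min window."""
    params = dict(s_par=2.02, s_perp=0.88, n_cells=40, n_frames=27,
                  frame_dt=10.0, positional_noise_sd=0.0, axis_drift_sd=0.0)
    params.update(overrides)
    return FlowParams(**params)


def ectoderm_flow(**overrides) -> FlowParams:
    """Preset for the late-stage ectodermal regime (1.12 / 0.83 over 260 min)."""
    params = dict(s_par=1.12, s_perp=0.83, n_cells=40, n_frames=27,
                  frame_dt=10.0, positional_noise_sd=0.0, axis_drift_sd=0.0)
    params.update(overrides)
    return FlowParams(**params)


# --------------------------------------------------------------------------
# explant silhouettes

def explant_polygon(
    length_um: float,
    width_um: float,
    extension_fraction: float,
    indentation_depth: float,
) -> tuple[Polygon, dict]:
    """Silhouette polygon in µm: round body + narrower extension lobe.

    The back of the explant sits at x=0, the tip at ``x = length_um``.
    With ``extension_fraction`` > 0 the body is cut flat at the neck
    position ``x_neck = (1 - extension_fraction) * length_um`` and a
    round-tipped lobe of half-width ``width/2 - indentation_depth``
    continues to the tip, leaving a concave step of the requested depth
    on both sides of the neck.
    """
    if not 0 <= extension_fraction < 1:
        raise ValueError("extension_fraction must be in [0, 1)")
    r = width_um / 2.0
    cy = r  # centerline at y = r so the mask is y >= 0
    if extension_fraction == 0:
        body = Point(r, cy).buffer(r, quad_segs=64)
        truth = {
            "length_um": width_um,
            "extension_length_um": 0.0,
            "extension_length_norm": 0.0,
            "indentation_point_um": None,
            "area_um2": body.area,
        }
        return body, truth
    h = r - indentation_depth
    if h <= 0:
        raise ValueError("indentation_depth must be < width/2")
    x_neck = (1.0 - extension_fraction) * length_um
    if x_neck <= r:
        raise ValueError(
            "extension too long for the requested width: the neck falls "
            "inside the body cap"
        )
    lobe_len = length_um - x_neck
    if lobe_len <= h:
        raise ValueError("extension shorter than its tip radius")
    body = unary_union(
        [Point(r, cy).buffer(r, quad_segs=64), box(r, cy - r, x_neck, cy + r)]
    )
    lobe = unary_union(
        [
            box(x_neck, cy - h, length_um - h, cy + h),
            Point(length_um - h, cy).buffer(h, quad_segs=64),
        ]
    )
    poly = unary_union([body, lobe])
    truth = {
        "length_um": length_um,
        "extension_length_um": lobe_len,
        "extension_length_norm": extension_fraction,
        "indentation_point_um": (x_neck, cy),
        "indentation_depth_um": indentation_depth,
        "area_um2": poly.area,
    }
    return poly, truth


def rasterize_polygon(
    poly: Polygon, calibration: PixelCalibration, margin_px: int = 4
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize a polygon (µm) onto a pixel grid; returns (mask, origin_um).

    A pixel is foreground when its center lies inside the polygon.
    ``origin_um`` is the µm position of pixel (0, 0)'s center.
    """
    px = calibration.pixel_size_xy
    minx, miny, maxx, maxy = poly.bounds
    x0 = minx - margin_px * px
    y0 = miny - margin_px * px
    nx = int(math.ceil((maxx - x0) / px)) + margin_px
    ny = int(math.ceil((maxy - y0) / px)) + margin_px
    xs = x0 + np.arange(nx) * px
    ys = y0 + np.arange(ny) * px
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
    return inside, (float(x0), float(y0))


def make_explant_mask(
    length_um: float = 600.0,
    width_um: float = 300.0,
    extension_fraction: float = 0.4,
    indentation_depth: float = 40.0,
    calibration: PixelCalibration = PixelCalibration(2.0),
    seed: int = 0,
) -> tuple[ExplantMask, dict]:
    """Synthesize an explant silhouette mask with known ground truth.

    Returns the rasterized :class:`ExplantMask` (indentation point
    attached when the shape is extended) and a ground-truth dict with the
    true extension length (µm and normalized), indentation point, and
    polygon area.  ``seed`` is accepted for interface uniformity; the
    construction is deterministic.
    """
    poly, truth = explant_polygon(
        length_um, width_um, extension_fraction, indentation_depth
    )
    raster, origin = rasterize_polygon(poly, calibration)
    truth = dict(truth)
    truth["origin_um"] = origin
    pt = truth["indentation_point_um"]
    if pt is not None:
        pt = (pt[0] - origin[0], pt[1] - origin[1])
        truth["indentation_point_um"] = pt
    truth["seed"] = seed
    mask = ExplantMask(mask=raster, calibration=calibration, indentation_point=pt)
    return mask, truth


# --------------------------------------------------------------------------
# clone flow

def simulate_clone_flow(
    params: FlowParams,
) -> tuple[NucleusTable, ReferenceAxis, dict]:
    """Advect a compact clone by an anisotropic affine flow.

    Cells start uniformly in a disk of ``blob_radius``; at frame k the
    offsets from the clone center are scaled by ``s_par**(k/(K-1))``
    along the axis (+x before drift) and ``s_perp**(k/(K-1))``
    perpendicular, then Gaussian positional noise is added.  Tip anchors
    are emitted every 10 frames (plus the final frame) and track the
    stretching tissue; ``axis_drift_sd`` jitters anchor placement to
    mimic manual spotting.
    """
    rng = np.random.default_rng(params.seed)
    K = params.n_frames
    n = params.n_cells
    center = np.array([400.0, 300.0])
    # uniform disk sample for initial in-plane offsets
    u = rng.random(n)
    theta = rng.random(n) * 2 * np.pi
    rr = params.blob_radius * np.sqrt(u)
    offsets = np.stack([rr * np.cos(theta), rr * np.sin(theta)], axis=1)
    z0 = rng.uniform(20.0, 40.0, size=n)

    g = np.arange(K) / (K - 1)
    s_par_t = params.s_par**g
    s_perp_t = params.s_perp**g

    rows = []
    for k in range(K):
        t = k * params.frame_dt
        pos = center + np.stack(
            [offsets[:, 0] * s_par_t[k], offsets[:, 1] * s_perp_t[k]], axis=1
        )
        if params.positional_noise_sd > 0:
            pos = pos + rng.normal(0, params.positional_noise_sd, size=pos.shape)
        for i in range(n):
            rows.append(
                {
                    "id": i,
                    "t": t,
                    "x": pos[i, 0],
                    "y": pos[i, 1],
                    "z": z0[i],
                    "label": "mesendoderm",
                }
            )
    table = NucleusTable(pd.DataFrame(rows))

    back = np.array([center[0] - 200.0, center[1], 30.0])
    anchor_frames = sorted(set(range(0, K, 10)) | {K - 1})
    tips = []
    for k in anchor_frames:
        tip = np.array(
            [center[0] + 200.0 * s_par_t[k], center[1], 30.0]
        )
        if params.axis_drift_sd > 0:
            tip[:2] = tip[:2] + rng.normal(0, params.axis_drift_sd, size=2)
        tips.append([k * params.frame_dt, *tip])
    axis = ReferenceAxis(tip_anchors=np.array(tips), back=back)

    truth = {
        "s_par": params.s_par,
        "s_perp": params.s_perp,
        "scale_par_per_frame": s_par_t,
        "scale_perp_per_frame": s_perp_t,
        "axis_angle_deg": 0.0,
        "times": g * (K - 1) * params.frame_dt,
        "center": center,
        "initial_offsets": offsets,
        "seed": params.seed,
    }
    return table, axis, truth


# --------------------------------------------------------------------------
# gradient nuclei

def gradient_shape(shape: str, d: np.ndarray, decay: float) -> np.ndarray:
    """Normalized-distance response f(d): 1 at the high-intensity side."""
    d = np.asarray(d, float)
    if shape == "flat":
        return np.ones_like(d)
    if shape == "exponential":
        return np.exp(-d / decay)
    if shape == "logistic":
        return 1.0 / (1.0 + np.exp((d - 0.5) / decay))
    raise ValueError(f"unknown profile shape: {shape}")


def simulate_gradient_nuclei(
    params: GradientParams,
    axis_length_um: float = 500.0,
    width_um: float = 200.0,
    depth_range_um: tuple[float, float] = (10.0, 150.0),
) -> tuple[NucleusTable, ReferenceContour, dict]:
    """Place nuclei uniformly in a slab with a gradient along +x.

    Per nucleus: ``signal = amplitude * f(x/L) * A(depth) + background +
    noise`` and ``dapi = dapi_mean * A(depth) * (1 + cv noise)`` where
    ``A(depth) = (1 - depth_attenuation)**(depth/100)`` is shared by both
    channels, so background-subtracted DAPI-normalized ratios cancel it.
    The reference contour is a dense line of points along the x=0 (high
    intensity) edge.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_nuclei
    x = rng.uniform(0, axis_length_um, n)
    y = rng.uniform(0, width_um, n)
    depth = rng.uniform(*depth_range_um, n)
    d_norm = x / axis_length_um
    f = gradient_shape(params.profile_shape, d_norm, params.decay_length)
    atten = (1.0 - params.depth_attenuation) ** (depth / 100.0)
    signal_clean = params.amplitude * f * atten
    signal = signal_clean + params.background_level
    if params.intensity_cv > 0:
        signal = signal * (1.0 + params.intensity_cv * rng.standard_normal(n))
    dapi = params.dapi_mean * atten
    if params.dapi_cv > 0:
        dapi = dapi * (1.0 + params.dapi_cv * rng.standard_normal(n))
    signal = np.clip(signal, 0, None)
    dapi = np.clip(dapi, 1e-9, None)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "t": 0.0,
            "x": x,
            "y": y,
            "z": depth,
            "depth": depth,
            "dapi": dapi,
            "psmad5": signal,
            "sample": "synthetic",
            "condition": "control",
            "replicate": 1,
        }
    )
    contour_y = np.arange(0.0, width_um + 1e-9, 2.0)
    contour = ReferenceContour(
        np.stack(
            [np.zeros_like(contour_y), contour_y, np.full_like(contour_y, 30.0)],
            axis=1,
        )
    )
    truth = {
        "f_per_nucleus": f,
        "d_norm": d_norm,
        "background_level": params.background_level,
        "amplitude": params.amplitude,
        "decay_length": params.decay_length,
        "profile_shape": params.profile_shape,
        "axis_length_um": axis_length_um,
        "attenuation": atten,
        "seed": params.seed,
    }
    return NucleusTable(df), contour, truth


# --------------------------------------------------------------------------
# cell outlines

def sample_axial_angles(
    rng: np.random.Generator, mean_deg: float, concentration: float, n: int
) -> np.ndarray:
    """Draw axial orientations (degrees, folded to [-90, 90)).

    Orientations are axial data (period 180°): a von Mises draw on the
    doubled angle 2θ is halved, which makes ``concentration=0`` exactly
    uniform on [-90, 90).
    """
    if concentration <= 0:
        ang = rng.uniform(-90.0, 90.0, n)
    else:
        kappa = min(concentration, 1e6)
        dbl = rng.vonmises(np.deg2rad(2 * mean_deg), kappa, n)
        ang = np.rad2deg(dbl) / 2.0
    return (ang + 90.0) % 180.0 - 90.0


def simulate_cell_outlines(
    params: OrientationParams,
    axis_angle_deg: float = 0.0,
    field_um: tuple[float, float] = (400.0, 400.0),
    depth_range_um: tuple[float, float] = (40.0, 65.0),
) -> tuple[list[CellOutline], dict]:
    """Generate elliptical cell outlines with known orientations.

    Ground truth records each cell's drawn orientation (``None`` when the
    aspect ratio is 1: a circle has no defined long axis) and its
    deviation from ``axis_angle_deg`` folded into [0, 90].
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_cells
    angles = sample_axial_angles(rng, params.mean_angle, params.concentration, n)
    lo, hi = params.aspect_ratio_range
    aspects = rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))
    centers = rng.uniform(0, 1, size=(n, 2)) * np.array(field_um)
    depths = rng.uniform(*depth_range_um, n)
    tt = np.linspace(0, 2 * np.pi, params.n_vertices, endpoint=False)
    outlines: list[CellOutline] = []
    truth_angles: list[float | None] = []
    for i in range(n):
        a = params.major_axis_um / 2.0
        b = a / aspects[i]
        th = np.deg2rad(angles[i])
        ex = np.cos(tt) * a
        ey = np.sin(tt) * b
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        verts = (rot @ np.stack([ex, ey])).T + centers[i]
        outlines.append(
            CellOutline(
                vertices=verts,
                plane_z=float(depths[i]),
                nucleus_center=tuple(centers[i]),
                cell_id=i,
            )
        )
        truth_angles.append(None if aspects[i] == 1.0 else float(angles[i]))
    deviations = [
        None if a is None else _fold_deviation(a - axis_angle_deg)
        for a in truth_angles
    ]
    truth = {
        "angles_deg": truth_angles,
        "deviations_deg": deviations,
        "aspects": aspects,
        "axis_angle_deg": axis_angle_deg,
        "seed": params.seed,
    }
    return outlines, truth


def _fold_deviation(delta_deg: float) -> float:
    d = abs(delta_deg) % 180.0
    return min(d, 180.0 - d)


# --------------------------------------------------------------------------
# raster rendering

def render_channels(
    table: NucleusTable,
    calibration: PixelCalibration,
    shape_px: tuple[int, int, int],
    channels: tuple[str, ...] = ("dapi",),
    psf_sd_um: float = 2.0,
    snr: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render nuclei as 3D Gaussian blobs with Poisson-Gaussian noise.

    Returns a ``(n_channels, z, y, x)`` float stack.  Blob amplitude per
    channel is the nucleus' tabulated intensity (100 when the column is
    absent); noise is scaled so peak amplitude / noise sd ≈ ``snr``
    (``snr=inf`` disables noise).  Ground truth carries the rendered
    centers in pixel coordinates.
    """
    nz, ny, nx = shape_px
    px = calibration.pixel_size_xy
    pz = calibration.pixel_size_z or px
    df = table.data
    cx = df["x"].to_numpy(float) / px
    cy = df["y"].to_numpy(float) / px
    cz = df["z"].to_numpy(float) / pz
    if len(df) and (
        cx.max() >= nx or cy.max() >= ny or cz.max() >= nz
        or cx.min() < 0 or cy.min() < 0 or cz.min() < 0
    ):
        raise ValueError("canvas too small for the nucleus positions")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    sx = psf_sd_um / px
    sz = psf_sd_um / pz
    stack = np.zeros((len(channels),) + tuple(shape_px), dtype=float)
    for ci, ch in enumerate(channels):
        amps = (
            df[ch].to_numpy(float) if ch in df.columns else np.full(len(df), 100.0)
        )
        img = np.zeros(shape_px, dtype=float)
        for i in range(len(df)):
            img += amps[i] * np.exp(
                -(
                    (xx - cx[i]) ** 2 / (2 * sx**2)
                    + (yy - cy[i]) ** 2 / (2 * sx**2)
                    + (zz - cz[i]) ** 2 / (2 * sz**2)
                )
            )
        if np.isfinite(snr) and len(df):
            noise_sd = amps.max() / snr if len(amps) else 0.0
            shot = rng.poisson(np.clip(img, 0, None)) - img
            img = img + 0.25 * shot + rng.normal(0, noise_sd, size=img.shape)
            img = np.clip(img, 0, None)
        stack[ci] = img
    truth = {
        "centers_px": np.stack([cz, cy, cx], axis=1),
        "channels": channels,
        "seed": seed,
    }
    return stack, truth
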
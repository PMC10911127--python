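"""Nuclear pSmad5/pSmad2 signaling-gradient profiles.

Pipeline: detect or load per-nucleus positions and channel means → QC
filtering (flagged nuclei, depth window) → planar geometric distance to a
reference contour on the high-intensity side, normalized to each sample's
maximum → cytoplasmic background subtraction → DAPI normalization (which
cancels depth-dependent attenuation common to both channels) → fixed-width
binning of the normalized distances with edge-bin exclusion and control
referencing → summary statistics (top-decile position, domain extent,
graded/radial classification).

Order of operations matters: the background is subtracted from raw
channel means first, then the corrected value is divided by DAPI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

from .config import RunConfig
from .types import (
    QC_FLAG_COLUMNS,
    GradientProfile,
    NucleusTable,
    PixelCalibration,
    ReferenceContour,
)

logger = logging.getLogger(__name__)

__all__ = [
    "detect_nuclei",
    "qc_filter",
    "distance_to_reference",
    "background_subtract",
    "build_profile",
    "control_reference_value",
    "top_decile_position",
    "ratio_to_control",
    "domain_extent",
    "classify_profile",
]


def detect_nuclei(
    stacks: dict[str, np.ndarray] | np.ndarray,
    calibration: PixelCalibration,
    nucleus_diameter_um: float = 8.0,
    threshold_rel: float = 0.2,
) -> NucleusTable:
    """Difference-of-Gaussian nucleus detection on a 3D DAPI stack.

    ``stacks`` is either a single ``(z, y, x)`` DAPI array or a dict of
    channel name → stack sharing one geometry (detection always runs on
    ``'dapi'``).  Local maxima of the DoG response at the nuclear scale
    become detections; per detection, the mean intensity of every channel
    within a sphere of the nuclear radius is tabulated.  Positions are in
    µm; detections closer than the nuclear scale merge (resolution limit,
    logged).
    """
    if isinstance(stacks, np.ndarray):
        stacks = {"dapi": stacks}
    dapi = np.asarray(stacks["dapi"], float)
    if dapi.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) stack")
    px = calibration.pixel_size_xy
    pz = calibration.pixel_size_z or px
    if dapi.max() <= 0:
        return NucleusTable(pd.DataFrame(
            {c: [] for c in ("id", "t", "x", "y", "z", *stacks)}))
    sigma_lo = np.array([nucleus_diameter_um / 4 / pz,
                         nucleus_diameter_um / 4 / px,
                         nucleus_diameter_um / 4 / px])
    dog = ndi.gaussian_filter(dapi, sigma_lo) - ndi.gaussian_filter(
        dapi, sigma_lo * 1.6)
    min_dist = max(1, int(round(nucleus_diameter_um / 2 / px)))
    peaks = peak_local_max(
        dog,
        min_distance=min_dist,
        threshold_abs=threshold_rel * dog.max(),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return NucleusTable(pd.DataFrame(
            {c: [] for c in ("id", "t", "x", "y", "z", *stacks)}))

    # per-detection sphere means for every channel
    zz, yy, xx = np.meshgrid(
        *(np.arange(s) for s in dapi.shape), indexing="ij"
    )
    r_um = nucleus_diameter_um / 2
    rows = []
    for i, (pz_i, py_i, px_i) in enumerate(peaks):
        sphere = (
            ((zz - pz_i) * pz) ** 2
            + ((yy - py_i) * px) ** 2
            + ((xx - px_i) * px) ** 2
        ) <= r_um**2
        row = {
            "id": i,
            "t": 0.0,
            "x": px_i * px,
            "y": py_i * px,
            "z": pz_i * pz,
            "depth": pz_i * pz,
        }
        for ch, stack in stacks.items():
            row[ch] = float(np.asarray(stack, float)[sphere].mean())
        rows.append(row)
    logger.info("detected %d nuclei", len(rows))
    return NucleusTable(pd.DataFrame(rows))


def qc_filter(
    table: NucleusTable,
    mode: str = "explant",
    depth_limits: tuple[float, float] | None = None,
    depth_col: str = "depth",
) -> NucleusTable:
    """Remove flagged nuclei and those outside the analysis depth window.

    Flags (enveloping layer, yolk syncytial layer, inhomogeneous DAPI,
    dividing) reproduce the manual exclusions of the imaging workflow.
    Default depth windows: explants ≤ 180 µm from the top; embryos
    60–120 µm from the animal pole.  Removal counts are logged per reason.
    """
    if depth_limits is None:
        depth_limits = {"explant": (0.0, 180.0), "embryo": (60.0, 120.0)}[mode]
    df = table.data
    keep = np.ones(len(df), bool)
    removals: dict[str, int] = {}
    for flag in QC_FLAG_COLUMNS:
        if flag in df.columns:
            hit = df[flag].fillna(False).astype(bool).to_numpy()
            removals[flag] = int((hit & keep).sum())
            keep &= ~hit
    if depth_col in df.columns:
        depth = df[depth_col].to_numpy(float)
        out = (depth < depth_limits[0]) | (depth > depth_limits[1])
        removals["depth"] = int((out & keep).sum())
        keep &= ~out
    for reason, n in removals.items():
        if n:
            logger.info("qc_filter: removed %d nuclei (%s)", n, reason)
    return NucleusTable(df[keep].reset_index(drop=True))


def distance_to_reference(
    table: NucleusTable,
    contour: ReferenceContour,
    interpolate: bool = False,
) -> NucleusTable:
    """Planar distance of every nucleus to the reference contour.

    Nuclei and reference points are projected along z; the distance is
    the minimum Euclidean distance to any reference point (or, with
    ``interpolate=True``, to the polyline through them).  Distances are
    normalized to the maximum within the sample, so the normalized value
    is in [0, 1] and attains 1 at the farthest nucleus.  Adds columns
    ``dist_um`` and ``dist_norm``.
    """
    df = table.data.copy()
    if len(df) < 2:
        raise ValueError("need >= 2 nuclei to normalize distances")
    xy = df[["x", "y"]].to_numpy(float)
    ref = contour.xy
    if interpolate and len(ref) >= 2:
        from shapely.geometry import LineString, Point

        line = LineString(ref)
        dist = np.array([line.distance(Point(p)) for p in xy])
    else:
        dist = cdist(xy, ref).min(axis=1)
    dmax = dist.max()
    if dmax == 0:
        raise ValueError("all nuclei coincide with the reference contour")
    df["dist_um"] = dist
    df["dist_norm"] = dist / dmax
    return NucleusTable(df)


def background_subtract(
    table: NucleusTable,
    spot_means: dict[str, float | np.ndarray],
    min_spots: int = 1,
) -> NucleusTable:
    """Cytoplasmic background subtraction per channel.

    ``spot_means`` maps channel name → the mean intensities of the
    cytoplasmic background spots (12 by default in the protocol, placed
    on the low-intensity side at the bottom of the analysis volume).
    The channel background is the mean of the spot means; corrected
    values ``<channel>_corr = max(raw - background, 0)`` are added and
    the backgrounds logged.
    """
    df = table.data.copy()
    for ch, means in spot_means.items():
        arr = np.atleast_1d(np.asarray(means, float))
        if len(arr) < min_spots:
            raise ValueError(f"missing background spots for channel '{ch}'")
        if ch not in df.columns:
            raise ValueError(f"channel '{ch}' not in table")
        bg = float(arr.mean())
        corrected = df[ch].to_numpy(float) - bg
        n_clamped = int((corrected < 0).sum())
        if n_clamped:
            logger.warning(
                "background_subtract: clamped %d negative value(s) in '%s'",
                n_clamped, ch,
            )
        df[f"{ch}_corr"] = np.clip(corrected, 0, None)
        logger.info("background_subtract: channel %s background %.3f", ch, bg)
    return NucleusTable(df)


def _bin_index(d: np.ndarray, width: float, n_bins: int) -> np.ndarray:
    """Half-open bins [k·w, (k+1)·w), last bin closed at 1."""
    idx = np.floor(np.asarray(d, float) / width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def _n_edge_bins(bin_width: float, edge_fraction: float) -> int:
    return max(1, int(round(edge_fraction / bin_width)))


def control_reference_value(
    tables: list[NucleusTable],
    bin_width: float,
    signal_col: str = "psmad5_corr",
    dapi_col: str = "dapi",
    replicate_col: str = "replicate",
) -> float:
    """Reference value for control normalization.

    The mean DAPI-normalized corrected intensity in the bin closest to
    the high-intensity side (bin 0) of the control samples, computed per
    replicate and averaged across replicates.
    """
    per_replicate: dict = {}
    for table in tables:
        df = table.data
        rep_ids = (
            df[replicate_col] if replicate_col in df.columns
            else pd.Series(0, index=df.index)
        )
        for rep, grp in df.groupby(rep_ids):
            ratio = grp[signal_col].to_numpy(float) / grp[dapi_col].to_numpy(float)
            sel = grp["dist_norm"].to_numpy(float) < bin_width
            if sel.any():
                per_replicate.setdefault(rep, []).append(float(ratio[sel].mean()))
    if not per_replicate:
        raise ValueError("no control nuclei fall in the reference bin")
    rep_means = [float(np.mean(v)) for v in per_replicate.values()]
    return float(np.mean(rep_means))


def build_profile(
    table: NucleusTable,
    bin_width: float = 0.04,
    signal_col: str = "psmad5_corr",
    dapi_col: str = "dapi",
    control_reference: float | None = None,
    edge_fraction: float = 0.04,
) -> GradientProfile:
    """Bin DAPI-normalized intensities over normalized distance.

    Per nucleus, ratio = corrected signal / DAPI.  Nuclei fall into
    half-open bins ``[k·w, (k+1)·w)`` (last bin closed); bin 0 sits at
    the high-intensity (reference-contour) side.  The first and last
    ``edge_fraction`` of the axis is excluded from the reported curve
    (one bin per edge at w=0.04; two at w=0.02) because edge bins are
    sparsely populated by sample curvature.  All reported values are
    divided by ``control_reference`` (the control group's bin-0 mean,
    see :func:`control_reference_value`); without one the profile
    self-references on its own bin-0 mean (logged).
    """
    df = table.data
    for col in (signal_col, dapi_col, "dist_norm"):
        if col not in df.columns:
            raise ValueError(f"missing column '{col}'; run the upstream steps")
    n_bins = int(round(1.0 / bin_width))
    ratio = df[signal_col].to_numpy(float) / df[dapi_col].to_numpy(float)
    idx = _bin_index(df["dist_norm"].to_numpy(float), bin_width, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=ratio, minlength=n_bins)
    means = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)

    n_edge = _n_edge_bins(bin_width, edge_fraction)
    excluded = tuple(range(n_edge)) + tuple(range(n_bins - n_edge, n_bins))

    if control_reference is None:
        if not np.isfinite(means[0]) or means[0] <= 0:
            raise ValueError("zero control reference: empty high-side bin")
        control_reference = float(means[0])
        logger.info("build_profile: self-referencing on bin 0 (%.4f)",
                    control_reference)
    if control_reference <= 0:
        raise ValueError("zero control reference")

    values = means / control_reference
    for b in np.flatnonzero(counts == 0):
        if b not in excluded:
            logger.info("build_profile: interior bin %d is empty", int(b))
    values[list(excluded)] = np.nan
    centers = (np.arange(n_bins) + 0.5) * bin_width
    return GradientProfile(
        bin_centers=centers,
        values=values,
        counts=counts,
        bin_width=bin_width,
        reference_value=float(control_reference),
        excluded_bins=excluded,
    )


def top_decile_position(
    table: NucleusTable,
    signal_col: str = "psmad5_corr",
    dapi_col: str = "dapi",
    fraction: float = 0.10,
) -> float:
    """Mean normalized distance of the top-10% highest-intensity nuclei.

    Intensity is the DAPI-normalized corrected signal; k = ceil(0.10·n)
    nuclei are taken, and any nuclei tying with the k-th ranked intensity
    are included (deterministic tie rule, logged).
    """
    df = table.data
    n = len(df)
    if n < 10:
        raise ValueError("need >= 10 nuclei for a top-decile statistic")
    ratio = df[signal_col].to_numpy(float) / df[dapi_col].to_numpy(float)
    d = df["dist_norm"].to_numpy(float)
    k = math.ceil(fraction * n)
    order = np.argsort(-ratio, kind="stable")
    kth_value = ratio[order[k - 1]]
    sel = ratio >= kth_value
    if sel.sum() > k:
        logger.info(
            "top_decile_position: %d nuclei tie at the k-th intensity; "
            "including all", int(sel.sum()),
        )
    return float(d[sel].mean())


def ratio_to_control(positions, control_positions) -> float:
    """Mean top-decile position relative to the control-group mean."""
    p = float(np.mean(np.atleast_1d(positions)))
    c = float(np.mean(np.atleast_1d(control_positions)))
    if c == 0:
        raise ValueError("zero control position")
    return p / c


def domain_extent(
    table: NucleusTable,
    back_um: np.ndarray,
    tip_um: np.ndarray,
    kind: str = "psmad5",
    signal_col: str = "psmad5_corr",
    dapi_col: str = "dapi",
    threshold: float | None = None,
    background_quantile: float = 0.75,
    n_sd: float = 2.0,
    half_width_um: float | None = None,
) -> float:
    """Normalized extent of a signal-positive domain along the back→tip line.

    Nuclei (optionally restricted to a central strip of
    ``half_width_um``) are projected onto the back→tip line.  A nucleus
    is positive when its DAPI-normalized corrected ratio exceeds
    ``threshold``; by default the threshold is mean + ``n_sd``·sd of the
    ratios in the far (low-signal) part of the axis, beyond
    ``background_quantile`` of the projected positions.  For
    ``kind='psmad5'`` (a back-anchored domain) the extent is the farthest
    positive position; for ``kind='egfp'`` (a tip-anchored domain) it is
    the first positive position.  Both are divided by the back→tip
    length.  No positive nuclei → 0.0 with a warning.
    """
    if kind not in ("psmad5", "egfp"):
        raise ValueError("kind must be 'psmad5' or 'egfp'")
    back = np.asarray(back_um, float)[:2]
    tip = np.asarray(tip_um, float)[:2]
    axis = tip - back
    L = np.linalg.norm(axis)
    if L == 0:
        raise ValueError("degenerate back/tip landmarks")
    u = axis / L
    df = table.data
    xy = df[["x", "y"]].to_numpy(float)
    rel = xy - back
    s = rel @ u
    if half_width_um is not None:
        q = rel @ np.array([-u[1], u[0]])
        central = np.abs(q) <= half_width_um
        df, s = df[central], s[central]
    ratio = df[signal_col].to_numpy(float) / df[dapi_col].to_numpy(float)
    if threshold is None:
        far = s >= np.quantile(s, background_quantile)
        if not far.any():
            raise ValueError("no nuclei in the background region")
        threshold = float(ratio[far].mean() + n_sd * ratio[far].std())
    positive = ratio > threshold
    if not positive.any():
        logger.warning("domain_extent: no positive nuclei; extent 0")
        return 0.0
    if kind == "psmad5":
        return float(np.clip(s[positive].max() / L, 0, 1))
    return float(np.clip(s[positive].min() / L, 0, 1))


def fit_exponential_decay(
    profile: GradientProfile, min_value_frac: float = 0.05
) -> float:
    """Decay length (fraction of axis) of an exponential-looking profile.

    Ordinary least squares of log bin mean against the bin's left edge
    over the reported bins: for a binned exponential the bin mean is
    proportional to ``exp(-edge/λ)``, so the slope is exactly ``-1/λ``.
    Bins below ``min_value_frac`` of the maximum reported value are
    dropped — background clamping leaves a positive noise floor there
    that would otherwise flatten the fitted tail.
    """
    rep = profile.reported
    v = profile.values[rep]
    edges = profile.bin_centers[rep] - profile.bin_width / 2
    ok = np.isfinite(v) & (v > 0)
    if ok.any():
        ok &= v > min_value_frac * np.nanmax(v)
    if ok.sum() < 3:
        raise ValueError("too few positive bins to fit a decay length")
    slope = np.polyfit(edges[ok], np.log(v[ok]), 1)[0]
    if slope >= 0:
        raise ValueError("profile does not decay")
    return float(-1.0 / slope)


@dataclass
class ProfileClassification:
    label: str
    end_ratio: float
    spearman_rho: float
    ratio_threshold: float
    rho_threshold: float


def classify_profile(
    profile: GradientProfile,
    ratio_threshold: float = 2.0,
    rho_threshold: float = 0.5,
    window: int = 3,
) -> ProfileClassification:
    """Call a profile graded or radial.

    Graded when the high-end mean (first ``window`` reported bins) is at
    least ``ratio_threshold`` times the low-end mean (last ``window``)
    AND the Spearman trend of bin means versus position is negative with
    |ρ| ≥ ``rho_threshold``; otherwise radial (uniformly elevated).  Both
    statistics are returned alongside the call.  NaN bins inside an end
    window expand it outward (logged).
    """
    rep = profile.reported
    vals = profile.values[rep]
    pos = profile.bin_centers[rep]
    if len(vals) < 5:
        raise ValueError("need >= 5 reported bins to classify")
    finite = np.isfinite(vals)
    if not finite.all():
        logger.info("classify_profile: expanding end windows over NaN bins")
        vals, pos = vals[finite], pos[finite]
    high = float(np.mean(vals[:window]))
    low = float(np.mean(vals[-window:]))
    if low <= 0:
        end_ratio = math.inf
    else:
        end_ratio = high / low
    if np.ptp(vals) == 0:  # perfectly flat profile: no trend
        rho = 0.0
    else:
        rho, _ = sps.spearmanr(pos, vals)
    graded = end_ratio >= ratio_threshold and rho < 0 and abs(rho) >= rho_threshold
    return ProfileClassification(
        label="graded" if graded else "radial",
        end_ratio=end_ratio,
        spearman_rho=float(rho),
        ratio_threshold=ratio_threshold,
        rho_threshold=rho_threshold,
    )
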
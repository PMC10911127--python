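"""Within-clone dispersal statistics on a time-varying extension axis.

The dispersal statistic: at each time point all positions are projected
along the imaging (z) axis onto the plane; for every cell the mean
absolute separation from all other clone cells is taken along the
extension axis and perpendicular to it; these per-cell means are averaged
over the clone and each series is reported relative to the initial
analysis time point.  The axis itself is defined by a stable back anchor
and sparse tip anchors that are linearly interpolated in time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import DispersalCurves, ExplantMask, NucleusTable, ReferenceAxis

logger = logging.getLogger(__name__)

__all__ = [
    "build_reference_axis",
    "axis_direction_at",
    "prepare_tracks",
    "dispersal_curves",
    "fold_change",
    "position_correlation",
    "categorize_clone",
]


def axis_direction_at(axis: ReferenceAxis, t: float) -> np.ndarray:
    """In-plane unit axis direction (back → interpolated tip) at time t."""
    tip = axis.tip_at(t)[:2]
    back = axis.back[:2]
    v = tip - back
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate axis at t={t}: tip and back coincide "
                         "after z-projection")
    return v / n


def build_reference_axis(axis: ReferenceAxis, times) -> np.ndarray:
    """Per-frame unit axis directions, shape (len(times), 2).

    Tip positions are linearly interpolated between anchors and held
    constant beyond the anchored range; directions are computed after
    dropping z (projection along the imaging axis).
    """
    return np.stack([axis_direction_at(axis, t) for t in np.asarray(times)])


def prepare_tracks(table: NucleusTable, max_gap: int = 1) -> NucleusTable:
    """Enforce full-window coverage, filling single-frame gaps.

    Tracks covering every analysis frame are kept as is; tracks with gaps
    of at most ``max_gap`` frames are completed by linear interpolation;
    tracks that start late, end early or have longer gaps are excluded
    (mirroring the manual track curation of the imaging workflow).
    """
    df = table.data
    frames = np.unique(df["t"].to_numpy(float))
    keep_rows = []
    n_excluded = 0
    for cid, grp in df.groupby("id"):
        ts = grp["t"].to_numpy(float)
        present = np.isin(frames, ts)
        if present.all():
            keep_rows.append(grp)
            continue
        if not (present[0] and present[-1]):
            n_excluded += 1
            continue
        # gap lengths between observed frames
        idx = np.flatnonzero(present)
        gaps = np.diff(idx) - 1
        if gaps.max() > max_gap:
            n_excluded += 1
            continue
        grp = grp.sort_values("t")
        filled = {"id": cid, "t": frames}
        out = pd.DataFrame(filled)
        for col in ("x", "y", "z"):
            out[col] = np.interp(frames, grp["t"], grp[col])
        for col in grp.columns:
            if col not in out.columns:
                out[col] = grp[col].iloc[0]
        keep_rows.append(out)
    if n_excluded:
        logger.info("excluded %d track(s) not covering the analysis window",
                    n_excluded)
    if not keep_rows:
        raise ValueError("no complete tracks remain")
    return NucleusTable(pd.concat(keep_rows, ignore_index=True))


def _mean_pairwise_abs(values: np.ndarray) -> float:
    """Mean over cells of the mean absolute separation to all other cells."""
    v = np.asarray(values, float)
    n = len(v)
    diffs = np.abs(v[:, None] - v[None, :])
    return float(diffs.sum() / (n * (n - 1)))


def dispersal_curves(
    clone: NucleusTable,
    axis: ReferenceAxis,
    t0: float | None = None,
    normalization: str = "ratio",
) -> DispersalCurves:
    """Per-time within-clone mean pairwise distances, axial and perpendicular.

    Positions are projected onto the plane (z dropped); separations are
    decomposed on the per-frame axis direction.  ``normalization='ratio'``
    divides each series by its value at ``t0`` (the reported fold-change
    convention); ``'difference'`` subtracts it instead (sensitivity mode).
    """
    if normalization not in ("ratio", "difference"):
        raise ValueError("normalization must be 'ratio' or 'difference'")
    df = clone.data
    frames = np.unique(df["t"].to_numpy(float))
    if t0 is None:
        t0 = float(frames[0])
    if t0 not in frames:
        raise ValueError(f"t0={t0} is not an analysis frame")
    par = np.empty(len(frames))
    perp = np.empty(len(frames))
    ncells = np.empty(len(frames), int)
    for k, t in enumerate(frames):
        sub = df[df["t"] == t]
        if len(sub) < 2:
            raise ValueError(f"fewer than 2 cells at frame t={t}")
        u = axis_direction_at(axis, t)
        v = np.array([-u[1], u[0]])
        xy = sub[["x", "y"]].to_numpy(float)
        par[k] = _mean_pairwise_abs(xy @ u)
        perp[k] = _mean_pairwise_abs(xy @ v)
        ncells[k] = len(sub)
    i0 = int(np.flatnonzero(frames == t0)[0])
    if normalization == "ratio":
        def _ratio(series):
            if series[i0] == 0:
                logger.warning("zero dispersal at t0; normalized series "
                               "undefined (NaN)")
                return np.full_like(series, np.nan)
            return series / series[i0]

        par_n = _ratio(par)
        perp_n = _ratio(perp)
    else:
        par_n = par - par[i0]
        perp_n = perp - perp[i0]
    return DispersalCurves(
        times=frames,
        parallel_um=par,
        perpendicular_um=perp,
        parallel_norm=par_n,
        perpendicular_norm=perp_n,
        n_cells=ncells,
    )


def fold_change(curves: DispersalCurves, t_end: float) -> tuple[float, float]:
    """Normalized dispersal at ``t_end`` (linearly interpolated between
    frames): the axial and perpendicular fold changes."""
    t = curves.times
    if not (t[0] <= t_end <= t[-1]):
        raise ValueError(f"t_end={t_end} outside curve support [{t[0]}, {t[-1]}]")
    return (
        float(np.interp(t_end, t, curves.parallel_norm)),
        float(np.interp(t_end, t, curves.perpendicular_norm)),
    )


def position_correlation(
    clone: NucleusTable, axis: ReferenceAxis, t0: float, t1: float
) -> float:
    """R² of relative tip distances at the onset versus the end.

    Per cell, the planar Euclidean distance to the interpolated tip,
    normalized by the back-to-tip axis length at that time; returns the
    squared Pearson correlation of the paired values at ``t0`` and ``t1``.
    """
    df = clone.data

    def _rel_dist(t):
        sub = df[df["t"] == t].sort_values("id")
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 cells at t={t}")
        tip = axis.tip_at(t)[:2]
        L = np.linalg.norm(tip - axis.back[:2])
        if L == 0:
            raise ValueError("degenerate axis")
        xy = sub[["x", "y"]].to_numpy(float)
        return sub["id"].to_numpy(), np.hypot(*(xy - tip).T) / L

    ids0, d0 = _rel_dist(t0)
    ids1, d1 = _rel_dist(t1)
    common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
    if len(common) < 3:
        raise ValueError("fewer than 3 cells present at both time points")
    r, _ = sps.pearsonr(d0[i0], d1[i1])
    return float(r**2)


def categorize_clone(
    positions_um: np.ndarray, domain: ExplantMask, threshold: float = 0.25
) -> str:
    """Clone category from its overlap with the reporter-positive domain.

    ``mostly_mesendodermal`` if < 25% of the clone lies outside the
    domain, ``mostly_ectodermal`` if < 25% lies inside, else ``mixed``.
    """
    pos = np.atleast_2d(np.asarray(positions_um, float))[:, :2]
    if len(pos) < 1:
        raise ValueError("empty clone")
    m = domain.domain if domain.domain is not None else domain.mask
    px = domain.calibration.pixel_size_xy
    cols = np.round(pos[:, 0] / px).astype(int)
    rows = np.round(pos[:, 1] / px).astype(int)
    ny, nx = m.shape
    inside = (
        (rows >= 0) & (rows < ny) & (cols >= 0) & (cols < nx)
    )
    in_domain = np.zeros(len(pos), bool)
    in_domain[inside] = m[rows[inside], cols[inside]]
    frac_out = 1.0 - in_domain.mean()
    if frac_out < threshold:
        return "mostly_mesendodermal"
    if in_domain.mean() < threshold:
        return "mostly_ectodermal"
    return "mixed"
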
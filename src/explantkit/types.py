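"""Core data containers shared across the pipeline.

Geometry convention: image coordinates, ``x`` rightward, ``y`` downward,
``z`` into the stack; pixel indices are 0-based and a pixel's position is
its center.  All geometry leaving the I/O layer is in micrometres (µm);
parameters that the protocols specify in pixels (box widths, circle
diameters) are kept in pixels and converted with a
:class:`PixelCalibration` at the point of use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PixelCalibration",
    "ExplantMask",
    "NucleusTable",
    "ReferenceAxis",
    "ReferenceContour",
    "CellOutline",
    "GradientProfile",
    "DispersalCurves",
    "MorphometricsRecord",
    "REQUIRED_NUCLEUS_COLUMNS",
    "QC_FLAG_COLUMNS",
]

#: Columns every nucleus table must carry (positions in µm after loading).
REQUIRED_NUCLEUS_COLUMNS = ("id", "t", "x", "y", "z")

#: Boolean quality-control flags; any true flag excludes the nucleus.
QC_FLAG_COLUMNS = ("enveloping_layer", "ysl", "inhomogeneous_dapi", "dividing")


@dataclass(frozen=True)
class PixelCalibration:
    """Physical size of a pixel/voxel.

    Parameters
    ----------
    pixel_size_xy : float
        Lateral pixel size in µm/pixel (> 0).
    pixel_size_z : float, optional
        Axial plane spacing in µm/plane (> 0); ``None`` for 2D rasters.
    """

    pixel_size_xy: float
    pixel_size_z: float | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size_xy > 0:
            raise ValueError("pixel_size_xy must be > 0")
        if self.pixel_size_z is not None and not self.pixel_size_z > 0:
            raise ValueError("pixel_size_z must be > 0")


@dataclass
class ExplantMask:
    """2D binary silhouette of an explant with its calibration.

    ``mask`` is indexed ``[row, col]`` = ``[y, x]``.  The optional
    ``indentation_point`` (µm) marks the neck between the round body and
    the extension; ``domain`` is a submask of equal shape (e.g. the
    reporter-positive mesendoderm domain); ``reference_box`` is the central
    axis box used for geodesic shape profiling, stored as two centerline
    endpoints in µm plus a width in pixels.
    """

    mask: np.ndarray
    calibration: PixelCalibration
    indentation_point: tuple[float, float] | None = None
    domain: np.ndarray | None = None
    reference_box: tuple[tuple[float, float], tuple[float, float], int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("empty mask")
        if self.domain is not None:
            self.domain = np.asarray(self.domain).astype(bool)
            if self.domain.shape != self.mask.shape:
                raise ValueError("domain submask shape mismatch")

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.calibration.pixel_size_xy**2


@dataclass
class NucleusTable:
    """Per-nucleus records: position (µm), time, channel intensities, flags.

    Thin wrapper around a :class:`pandas.DataFrame` that enforces the
    required schema.  Optional columns: channel means (``dapi``,
    ``psmad5``, ``psmad2``), ``depth`` (µm from the sample top), QC flags,
    ``sample``, ``condition``, ``replicate``, ``label``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_NUCLEUS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"nucleus table missing required column(s): {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def positions(self, frame: float | None = None) -> np.ndarray:
        """(n, 3) array of x, y, z positions, optionally for one frame."""
        df = self.data if frame is None else self.data[self.data["t"] == frame]
        return df[["x", "y", "z"]].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return np.unique(self.data["t"].to_numpy(float))


@dataclass
class ReferenceAxis:
    """Extension axis defined by sparse tip anchors and one stable back anchor.

    ``tip_anchors`` is an (k, 4) array of ``(t, x, y, z)`` rows; ``back``
    is a single ``(x, y, z)`` point at the round part of the explant.
    Tip positions at intermediate times are linearly interpolated; beyond
    the anchored range the nearest anchor is held constant.
    """

    tip_anchors: np.ndarray
    back: np.ndarray

    def __post_init__(self) -> None:
        self.tip_anchors = np.atleast_2d(np.asarray(self.tip_anchors, float))
        self.back = np.asarray(self.back, float)
        if self.tip_anchors.shape[1] != 4:
            raise ValueError("tip_anchors must be (k, 4) rows of (t, x, y, z)")
        if self.tip_anchors.shape[0] < 1:
            raise ValueError("need at least one tip anchor")
        if self.back.shape != (3,):
            raise ValueError("back anchor must be a 3-vector")
        order = np.argsort(self.tip_anchors[:, 0])
        self.tip_anchors = self.tip_anchors[order]

    def tip_at(self, t: float | np.ndarray) -> np.ndarray:
        """Tip position (x, y, z) at time ``t`` (linear interp, clamped)."""
        t = np.asarray(t, float)
        ts = self.tip_anchors[:, 0]
        out = np.stack(
            [np.interp(t, ts, self.tip_anchors[:, i]) for i in (1, 2, 3)], axis=-1
        )
        return out


@dataclass
class ReferenceContour:
    """Ordered reference points (µm) along the high-intensity side."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, float))
        if self.points.shape[0] < 1 or self.points.shape[1] not in (2, 3):
            raise ValueError("contour needs >= 1 point of dim 2 or 3")

    @property
    def xy(self) -> np.ndarray:
        """Points projected along z onto the imaging plane."""
        return self.points[:, :2]


@dataclass
class CellOutline:
    """Planar polygon of one cell body traced on a single z-plane."""

    vertices: np.ndarray  # (n, 2) in µm
    plane_z: float = 0.0
    nucleus_center: tuple[float, float] | None = None
    cell_id: int | str = 0
    sample: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be (n, 2)")
        if self.vertices.shape[0] < 6:
            raise ValueError("outline needs >= 6 vertices")


@dataclass
class GradientProfile:
    """Binned, normalized intensity-vs-normalized-distance curve.

    ``bin_centers`` tile [0, 1] at ``bin_width``; bin 0 sits at the
    high-intensity (reference-contour) side.  ``values`` are per-bin mean
    DAPI-normalized intensities divided by ``reference_value``; excluded
    edge bins and empty bins carry NaN but keep their ``counts``.
    """

    bin_centers: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    bin_width: float
    reference_value: float
    excluded_bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, float)
        self.values = np.asarray(self.values, float)
        self.counts = np.asarray(self.counts, int)
        if not (len(self.bin_centers) == len(self.values) == len(self.counts)):
            raise ValueError("bin arrays must have equal length")
        if not self.reference_value > 0:
            raise ValueError("reference value must be > 0")

    @property
    def reported(self) -> np.ndarray:
        """Boolean mask of bins that enter the reported curve."""
        mask = np.isfinite(self.values)
        mask[list(self.excluded_bins)] = False
        return mask


@dataclass
class DispersalCurves:
    """Within-clone mean pairwise distances over time, decomposed on the axis.

    ``parallel_um``/``perpendicular_um`` are the mean-of-per-cell-mean
    absolute separations (µm); the ``*_norm`` series are the same divided
    by their value at the initial analysis time point.
    """

    times: np.ndarray
    parallel_um: np.ndarray
    perpendicular_um: np.ndarray
    parallel_norm: np.ndarray
    perpendicular_norm: np.ndarray
    n_cells: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in (
            "parallel_um",
            "perpendicular_um",
            "parallel_norm",
            "perpendicular_norm",
            "n_cells",
        ):
            arr = np.asarray(getattr(self, name), float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        self.times = np.asarray(self.times, float)


@dataclass
class MorphometricsRecord:
    """One explant's shape measurements (all fractions dimensionless)."""

    circularity: float | None = None
    extended: bool | None = None
    extension_length_norm: float | None = None
    length_width_ratio: float | None = None
    area_fraction: float | None = None
    domain_area_norm: float | None = None
    axis_length_ratio: float | None = None
    sample: str = ""

    def as_dict(self) -> dict:
        return {
            "sample": self.sample,
            "circularity": self.circularity,
            "extended": self.extended,
            "extension_length_norm": self.extension_length_norm,
            "length_width_ratio": self.length_width_ratio,
            "area_fraction": self.area_fraction,
            "domain_area_norm": self.domain_area_norm,
            "axis_length_ratio": self.axis_length_ratio,
        }
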
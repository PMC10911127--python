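"""Readers and writers for the tabular and raster formats the pipeline touches.

Tables are comma-separated UTF-8 text with a header and "." decimals.
Rasters are TIFF (multi-plane/multi-channel) or PNG (2D masks).  Every
result written by :func:`write_results` gets a JSON sidecar recording the
run configuration, seed and software version so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .types import (
    QC_FLAG_COLUMNS,
    REQUIRED_NUCLEUS_COLUMNS,
    DispersalCurves,
    ExplantMask,
    GradientProfile,
    MorphometricsRecord,
    NucleusTable,
    PixelCalibration,
    ReferenceAxis,
    ReferenceContour,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_nucleus_table",
    "write_nucleus_table",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "read_reference_axis",
    "write_reference_axis",
    "read_contour",
    "write_results",
    "read_dispersal_curves",
    "read_profile",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


def read_nucleus_table(
    path: str | Path, calibration: PixelCalibration | None = None
) -> NucleusTable:
    """Load a per-nucleus CSV, converting coordinates to µm.

    With a :class:`PixelCalibration`, ``x``/``y`` are multiplied by the
    lateral pixel size and ``z`` by the plane spacing; with
    ``calibration=None`` coordinates are taken to be in µm already.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_NUCLEUS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"nucleus table {path}: missing column(s) {missing}")
    for col in ("t", "x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"nucleus table {path}: non-numeric value in column '{col}' "
                f"at row {int(bad.idxmax())}"
            )
        df[col] = coerced
    if calibration is not None:
        df["x"] = df["x"] * calibration.pixel_size_xy
        df["y"] = df["y"] * calibration.pixel_size_xy
        dz = calibration.pixel_size_z or calibration.pixel_size_xy
        df["z"] = df["z"] * dz
    for flag in QC_FLAG_COLUMNS:
        if flag in df.columns:
            df[flag] = df[flag].fillna(False).astype(bool)
    return NucleusTable(df)


def write_nucleus_table(table: NucleusTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return np.asarray(iio.imread(path))


def write_image(image: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        kw = {"photometric": "minisblack"} if image.ndim >= 3 else {}
        tifffile.imwrite(path, image, **kw)
    else:
        iio.imwrite(path, image)


def read_mask(path: str | Path, calibration: PixelCalibration) -> ExplantMask:
    """Load a single-channel raster as a binary mask (nonzero = foreground).

    Explant analyses expect one connected component; extra components are
    kept but logged as a warning.  An all-background image is an error.
    """
    img = read_image(path)
    if img.ndim == 3 and img.shape[-1] in (3, 4):  # RGB(A) PNG
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError(f"mask {path}: expected a 2D single-channel raster")
    binary = img > 0
    if not binary.any():
        raise ValueError(f"empty mask: {path}")
    from skimage.measure import label

    n = int(label(binary).max())
    if n > 1:
        logger.warning("mask %s has %d connected components (expected 1)", path, n)
    return ExplantMask(mask=binary, calibration=calibration)


def write_mask(mask: ExplantMask, path: str | Path) -> None:
    write_image(mask.mask.astype(np.uint8) * 255, path)


def read_reference_axis(path: str | Path) -> ReferenceAxis:
    """Axis CSV: rows ``kind,t,x,y,z`` with kind in {tip, back} (µm)."""
    df = pd.read_csv(path)
    tips = df[df["kind"] == "tip"][["t", "x", "y", "z"]].to_numpy(float)
    back = df[df["kind"] == "back"][["x", "y", "z"]].to_numpy(float)
    if len(back) != 1:
        raise SchemaError(f"axis table {path}: expected exactly one back anchor")
    return ReferenceAxis(tip_anchors=tips, back=back[0])


def write_reference_axis(axis: ReferenceAxis, path: str | Path) -> None:
    rows = [
        {"kind": "tip", "t": t, "x": x, "y": y, "z": z}
        for t, x, y, z in axis.tip_anchors
    ]
    rows.append(
        {"kind": "back", "t": np.nan, "x": axis.back[0], "y": axis.back[1],
         "z": axis.back[2]}
    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contour(path: str | Path) -> ReferenceContour:
    """Contour CSV: ``point_index,x,y,z`` in µm."""
    df = pd.read_csv(path).sort_values("point_index")
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    return ReferenceContour(df[cols].to_numpy(float))


def _to_frame(artifact) -> pd.DataFrame:
    if isinstance(artifact, pd.DataFrame):
        return artifact
    if isinstance(artifact, NucleusTable):
        return artifact.data
    if isinstance(artifact, GradientProfile):
        return pd.DataFrame(
            {
                "bin_center": artifact.bin_centers,
                "value": artifact.values,
                "count": artifact.counts,
                "excluded": [
                    i in artifact.excluded_bins for i in range(len(artifact.counts))
                ],
            }
        )
    if isinstance(artifact, DispersalCurves):
        return pd.DataFrame(
            {
                "t": artifact.times,
                "parallel_um": artifact.parallel_um,
                "perpendicular_um": artifact.perpendicular_um,
                "parallel_norm": artifact.parallel_norm,
                "perpendicular_norm": artifact.perpendicular_norm,
                "n_cells": artifact.n_cells,
            }
        )
    if isinstance(artifact, MorphometricsRecord):
        return pd.DataFrame([artifact.as_dict()])
    if isinstance(artifact, dict):
        return pd.DataFrame([artifact])
    raise TypeError(f"cannot serialize artifact of type {type(artifact).__name__}")


def write_results(
    artifact,
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra_metadata: dict | None = None,
) -> None:
    """Write a result table plus a ``<path>.meta.json`` sidecar.

    The sidecar records the run configuration, seed and package version;
    profile-specific metadata (bin width, reference value) is included
    automatically.
    """
    path = Path(path)
    frame = _to_frame(artifact)
    frame.to_csv(path, index=False)
    meta: dict = {"software": "explantkit", "version": __version__}
    if config is not None:
        meta["config"] = dataclasses.asdict(config)
    if seed is not None:
        meta["seed"] = int(seed)
    if isinstance(artifact, GradientProfile):
        meta["bin_width"] = artifact.bin_width
        meta["reference_value"] = artifact.reference_value
    if extra_metadata:
        meta.update(extra_metadata)
    with open(path.with_name(path.name + ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_dispersal_curves(path: str | Path) -> DispersalCurves:
    df = pd.read_csv(path)
    return DispersalCurves(
        times=df["t"].to_numpy(float),
        parallel_um=df["parallel_um"].to_numpy(float),
        perpendicular_um=df["perpendicular_um"].to_numpy(float),
        parallel_norm=df["parallel_norm"].to_numpy(float),
        perpendicular_norm=df["perpendicular_norm"].to_numpy(float),
        n_cells=df["n_cells"].to_numpy(float),
    )


def read_profile(path: str | Path) -> GradientProfile:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_name(path.name + ".meta.json")
    bin_width = None
    reference_value = 1.0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        bin_width = meta.get("bin_width")
        reference_value = meta.get("reference_value", 1.0)
    if bin_width is None:
        bin_width = float(np.diff(df["bin_center"]).mean()) if len(df) > 1 else 1.0
    excluded = tuple(int(i) for i in np.flatnonzero(df["excluded"].to_numpy(bool)))
    return GradientProfile(
        bin_centers=df["bin_center"].to_numpy(float),
        values=df["value"].to_numpy(float),
        counts=df["count"].to_numpy(int),
        bin_width=float(bin_width),
        reference_value=float(reference_value),
        excluded_bins=excluded,
    )
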
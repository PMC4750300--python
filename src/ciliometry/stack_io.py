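"""Calibrated Z-stack and annotation I/O.

This module owns all coordinate conventions used in the package:

* Voxels are indexed ``(z, y, x)``.  In-plane sampling is isotropic with
  pixel size ``dxy`` (µm/pixel); the axial step is ``dz`` (µm/slice).
* ``(x, y)`` coordinates are continuous, 0-based and measured at pixel
  centers (sub-pixel positions are meaningful); ``z`` indices are integers.
* A cilium's slice span is inclusive: a cilium visible from ``z_first`` to
  ``z_last`` appears in ``z_last - z_first + 1`` slices.

Stacks are 8-bit single-channel multi-page TIFF / OME-TIFF files.  Voxel
calibration comes from an explicit override first, then OME metadata;
reading fails rather than guessing, because lengths in µm are meaningless
without calibration.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CalibrationError",
    "ZStack",
    "CiliumAnnotation",
    "read_stack",
    "write_stack",
    "read_annotations",
    "write_annotations",
    "read_measurements",
    "write_measurements",
]

#: Column order of the annotation CSV format.
ANNOTATION_COLUMNS = ["cilium_id", "point_index", "x", "y", "z_first", "z_last"]

#: Column order of the measurement CSV format.
MEASUREMENT_COLUMNS = ["cilium_id", "method", "replicate", "length_um", "classification"]


class CalibrationError(ValueError):
    """Raised when a stack's voxel size cannot be determined."""


@dataclass(frozen=True)
class ZStack:
    """A calibrated 3D fluorescence volume.

    Parameters
    ----------
    voxels
        Intensity array indexed ``(z, y, x)``, values in ``[0, 255]``.
    dxy
        In-plane pixel size, µm/pixel (isotropic in x and y).
    dz
        Axial step between consecutive slices, µm.
    """

    voxels: np.ndarray
    dxy: float
    dz: float

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim == 2:
            vox = vox[np.newaxis]
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x); got ndim={vox.ndim}")
        if vox.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if vox.size and (vox.min() < 0 or vox.max() > 255):
            raise ValueError("intensities must lie in [0, 255]")
        if not (self.dxy > 0 and self.dz > 0):
            raise ValueError("dxy and dz must be positive")
        object.__setattr__(self, "voxels", vox)

    @property
    def nz(self) -> int:
        return self.voxels.shape[0]

    @property
    def ny(self) -> int:
        return self.voxels.shape[1]

    @property
    def nx(self) -> int:
        return self.voxels.shape[2]

    @property
    def z_range_um(self) -> float:
        """Axial distance between the first and last slice, µm."""
        return (self.nz - 1) * self.dz


@dataclass(frozen=True)
class CiliumAnnotation:
    """Operator (or generator) annotation for one cilium.

    ``points_xy`` is an ordered polyline of sub-pixel ``(x, y)`` positions on
    the projection, in pixel units; ``z_first``/``z_last`` are the inclusive
    slice indices where the cilium's signal appears.
    """

    cilium_id: str
    points_xy: np.ndarray
    z_first: int
    z_last: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points_xy, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points_xy must have shape (n, 2)")
        if pts.shape[0] < 2:
            raise ValueError("an annotation needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points_xy must be finite")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive annotation points must be distinct")
        zf, zl = int(self.z_first), int(self.z_last)
        if zf < 0 or zl < zf:
            raise ValueError(f"need 0 <= z_first <= z_last; got ({zf}, {zl})")
        object.__setattr__(self, "points_xy", pts)
        object.__setattr__(self, "z_first", zf)
        object.__setattr__(self, "z_last", zl)

    @property
    def span_slices(self) -> int:
        """Number of slices the cilium appears in (inclusive count)."""
        return self.z_last - self.z_first + 1


def _parse_ome_calibration(ome_xml: str) -> tuple[float | None, float | None, int | None]:
    """Extract (PhysicalSizeX, PhysicalSizeZ, SizeC) from OME-XML."""
    root = ET.fromstring(ome_xml)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None, None, None

    def _get(attr: str) -> float | None:
        v = pixels.get(attr)
        return float(v) if v is not None else None

    size_c = pixels.get("SizeC")
    return _get("PhysicalSizeX"), _get("PhysicalSizeZ"), int(size_c) if size_c else None


def read_stack(path: str | os.PathLike, dxy: float | None = None, dz: float | None = None) -> ZStack:
    """Read a single-channel 8-bit TIFF / OME-TIFF Z-stack.

    Calibration precedence is explicit override > OME metadata; if neither
    supplies a value a :class:`CalibrationError` is raised.

    Parameters
    ----------
    path
        Multi-page TIFF or OME-TIFF file.
    dxy, dz
        Optional µm calibration overrides; an override always wins over
        file metadata.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        ome_dxy = ome_dz = None
        if tf.ome_metadata:
            ome_dxy, ome_dz, size_c = _parse_ome_calibration(tf.ome_metadata)
            if size_c is not None and size_c > 1:
                raise ValueError(f"multi-channel stack not supported (SizeC={size_c})")
    if "C" in axes or "S" in axes:
        c_dim = data.shape[axes.index("C" if "C" in axes else "S")]
        if c_dim > 1:
            raise ValueError("multi-channel stack not supported")
        data = np.squeeze(data, axis=axes.index("C" if "C" in axes else "S"))
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2D/3D single-channel image, got shape {data.shape}")

    dxy = dxy if dxy is not None else ome_dxy
    dz = dz if dz is not None else ome_dz
    if dxy is None:
        raise CalibrationError(f"{path}: no in-plane pixel size (dxy) in metadata or arguments")
    if dz is None:
        if data.shape[0] == 1:
            dz = 1.0  # single slice: the axial step never enters any length
        else:
            raise CalibrationError(f"{path}: no Z-step (dz) in metadata or arguments")
    return ZStack(voxels=data, dxy=float(dxy), dz=float(dz))


def write_stack(stack: ZStack, path: str | os.PathLike) -> None:
    """Write a stack as OME-TIFF with voxel-size metadata embedded."""
    data = np.ascontiguousarray(stack.voxels.astype(np.uint8))
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.dxy,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.dxy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.dz,
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_annotations(path: str | os.PathLike) -> list[CiliumAnnotation]:
    """Read per-cilium polyline annotations from CSV.

    The CSV must carry the columns ``cilium_id, point_index, x, y, z_first,
    z_last`` with one row per polyline point; rows of one cilium may be
    interleaved with others and are re-grouped and ordered by
    ``point_index``.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    for col in ("point_index", "x", "y", "z_first", "z_last"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be numeric")
    annotations = []
    for cid, grp in df.groupby("cilium_id", sort=False):
        grp = grp.sort_values("point_index")
        zf = grp["z_first"].unique()
        zl = grp["z_last"].unique()
        if len(zf) != 1 or len(zl) != 1:
            raise ValueError(f"{path}: inconsistent z span for cilium {cid!r}")
        annotations.append(
            CiliumAnnotation(
                cilium_id=str(cid),
                points_xy=grp[["x", "y"]].to_numpy(float),
                z_first=int(zf[0]),
                z_last=int(zl[0]),
            )
        )
    return annotations


def write_annotations(annotations: Iterable[CiliumAnnotation], path: str | os.PathLike,
                      header_lines: Sequence[str] = ()) -> None:
    """Write annotations in the CSV format read by :func:`read_annotations`."""
    rows = []
    for ann in annotations:
        for i, (x, y) in enumerate(ann.points_xy):
            rows.append((ann.cilium_id, i, x, y, ann.z_first, ann.z_last))
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    _write_csv(df, path, header_lines, float_cols=("x", "y"))


def read_measurements(path: str | os.PathLike) -> pd.DataFrame:
    """Read a measurement table written by :func:`write_measurements`."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing measurement columns {missing}")
    df["cilium_id"] = df["cilium_id"].astype(str)
    return df


def write_measurements(records, path: str | os.PathLike, header_lines: Sequence[str] = ()) -> None:
    """Write measurement records as CSV.

    ``records`` is a DataFrame or an iterable of objects/mappings with
    fields ``cilium_id, method, replicate, length_um, classification``.
    Lengths are serialized with enough digits to round-trip losslessly at
    µm scale.
    """
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, MEASUREMENT_COLUMNS].copy()
    else:
        rows = []
        for r in records:
            if isinstance(r, dict):
                rows.append({c: r[c] for c in MEASUREMENT_COLUMNS})
            else:
                rows.append({c: getattr(r, c) for c in MEASUREMENT_COLUMNS})
        df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    _write_csv(df, path, header_lines, float_cols=("length_um",))


def _write_csv(df: pd.DataFrame, path, header_lines: Sequence[str], float_cols=()) -> None:
    df = df.copy()
    for col in float_cols:
        df[col] = df[col].map(lambda v: format(float(v), ".9g"))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
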
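"""Voxel-volume containers and file I/O.

Volumes are stacks of z-slices on an (nz, ny, nx) grid with per-axis voxel
spacing in micrometres, ordered (sz, sy, sx) to match the array axes.
Coordinates are 0-based voxel indices; the physical position of a voxel
centre is ``origin + index * spacing`` (voxel-centre convention).

Supported formats: multi-page 3D TIFF (one page per z-slice) with a JSON
sidecar carrying spacing, and NRRD (raw encoding) with spacing in the header.
Tabular per-spicule results travel as CSV with a fixed column schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelVolume",
    "RECORD_COLUMNS",
    "read_volume",
    "write_volume",
    "convert_to_16bit",
    "crop_to_foreground",
    "read_records",
    "write_records",
]

Kind = Literal["grayscale", "binary", "labels"]

#: Column schema for per-spicule morphometric records.
RECORD_COLUMNS = [
    "spicule_id",
    "condition",
    "timepoint_hpf",
    "volume_um3",
    "surface_area_um2",
    "total_length_um",
    "mean_thickness_um",
    "n_tips",
    "n_junctions",
]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Scalar per voxel. Binary volumes contain only {0, 1}.
    spacing : tuple of float
        Voxel spacing (sz, sy, sx) in µm; all entries > 0.
    kind : {"grayscale", "binary", "labels"}
    origin : tuple of float
        Physical position (µm) of voxel (0, 0, 0); defaults to the origin.
    meta : dict
        Free-form provenance (thresholds used, source path, ...).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    kind: Kind = "grayscale"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"non-3D data: expected a 3D (nz, ny, nx) array, got ndim={self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)  # type: ignore[assignment]
        if self.kind == "binary":
            vals = np.unique(self.values)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary volume must contain only {0, 1}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    def with_values(self, values: np.ndarray, kind: Kind | None = None) -> "VoxelVolume":
        return replace(self, values=values, kind=kind or self.kind, meta=dict(self.meta))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as 3D TIFF (+ JSON sidecar) or NRRD by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(volume.values), compression="deflate")
        sidecar = {
            "spacing_um": list(volume.spacing),
            "origin_um": list(volume.origin),
            "kind": volume.kind,
        }
        _sidecar_path(path).write_text(json.dumps(sidecar))
    elif path.suffix.lower() == ".nrrd":
        _write_nrrd(volume, path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")


def read_volume(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    kind: Kind | None = None,
) -> VoxelVolume:
    """Read a 3D TIFF or NRRD volume.

    Spacing is taken from (in order) the ``spacing`` argument, the NRRD
    header, or the TIFF JSON sidecar; a volume with no spacing source raises
    a "missing spacing" error rather than silently assuming 1 µm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"unreadable file: {path}")
    origin = (0.0, 0.0, 0.0)
    meta: dict = {"source": str(path)}
    if path.suffix.lower() in (".tif", ".tiff"):
        values = tifffile.imread(path)
        file_kind = None
        sc = _sidecar_path(path)
        if sc.exists():
            side = json.loads(sc.read_text())
            if spacing is None:
                spacing = side.get("spacing_um")
            origin = tuple(side.get("origin_um", origin))
            file_kind = side.get("kind")
    elif path.suffix.lower() == ".nrrd":
        values, hdr_spacing = _read_nrrd(path)
        file_kind = None
        if spacing is None:
            spacing = hdr_spacing
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    if values.ndim != 3:
        raise ValueError(f"non-3D data in {path}: ndim={values.ndim}")
    if spacing is None:
        raise ValueError(
            f"missing spacing for {path}: supply spacing=, a JSON sidecar, or an NRRD header"
        )
    return VoxelVolume(
        values=values,
        spacing=tuple(spacing),  # type: ignore[arg-type]
        kind=kind or file_kind or "grayscale",
        origin=origin,
        meta=meta,
    )


# -- minimal NRRD (raw encoding, little-endian) ------------------------------

_NRRD_TYPES = {
    np.dtype("uint8"): "uint8",
    np.dtype("uint16"): "uint16",
    np.dtype("int16"): "int16",
    np.dtype("int32"): "int32",
    np.dtype("float32"): "float",
    np.dtype("float64"): "double",
}


def _write_nrrd(volume: VoxelVolume, path: Path) -> None:
    arr = np.ascontiguousarray(volume.values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    if arr.dtype.newbyteorder("<") != arr.dtype:
        arr = arr.astype(arr.dtype.newbyteorder("<"))
    if arr.dtype not in _NRRD_TYPES:
        raise ValueError(f"unsupported dtype for NRRD: {arr.dtype}")
    nz, ny, nx = arr.shape
    # NRRD sizes are fastest-axis first; our memory layout is x fastest.
    header = (
        "NRRD0004\n"
        f"type: {_NRRD_TYPES[arr.dtype]}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"spacings: {volume.spacing[2]} {volume.spacing[1]} {volume.spacing[0]}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.tobytes())


def _read_nrrd(path: Path) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if end < 0 or not raw.startswith(b"NRRD"):
        raise ValueError(f"not a supported NRRD file: {path}")
    fields: dict[str, str] = {}
    for line in raw[:end].decode("ascii").splitlines()[1:]:
        if ":" in line and not line.startswith("#"):
            k, v = line.split(":", 1)
            fields[k.strip().lower()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"non-3D data in {path}")
    type_map = {v: k for k, v in _NRRD_TYPES.items()}
    dtype = type_map[fields["type"]].newbyteorder("<")
    nx, ny, nz = (int(t) for t in fields["sizes"].split())
    values = np.frombuffer(raw[end + 2 :], dtype=dtype, count=nx * ny * nz).reshape(nz, ny, nx)
    spacing = None
    if "spacings" in fields:
        sx, sy, sz = (float(t) for t in fields["spacings"].split())
        spacing = (sz, sy, sx)
    return values.copy(), spacing


# -- pre-processing -----------------------------------------------------------


def convert_to_16bit(volume: VoxelVolume) -> VoxelVolume:
    """Linearly rescale a grayscale volume to the full 16-bit range.

    [min, max] maps to [0, 65535] with round-half-up; a constant volume maps
    to all zeros (there is no contrast to preserve).
    """
    vals = np.asarray(volume.values, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values cannot be converted to 16-bit")
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out = np.zeros(vals.shape, dtype=np.uint16)
    else:
        scaled = (vals - lo) / (hi - lo) * 65535.0
        out = np.floor(scaled + 0.5).astype(np.uint16)
    res = volume.with_values(out, kind="grayscale")
    res.meta["converted_16bit_from"] = (float(lo), float(hi))
    return res


def crop_to_foreground(
    volume: VoxelVolume,
    threshold_or_mask: float | np.ndarray,
    pad_voxels: int = 0,
) -> VoxelVolume:
    """Crop to the tight bounding box of foreground, expanded by a margin.

    Foreground is ``values > threshold`` for a scalar, or the nonzero voxels
    of a same-shaped mask. The margin is clipped at the grid edge; spacing is
    preserved and the origin shifted so physical coordinates are unchanged.
    """
    if pad_voxels < 0:
        raise ValueError("pad_voxels must be >= 0")
    if isinstance(threshold_or_mask, np.ndarray):
        fg = threshold_or_mask != 0
        if fg.shape != volume.shape:
            raise ValueError("mask shape does not match volume")
    else:
        fg = volume.values > threshold_or_mask
    if not fg.any():
        raise ValueError("empty foreground: nothing to crop to")
    slices = []
    new_origin = []
    for ax in range(3):
        proj = np.any(fg, axis=tuple(a for a in range(3) if a != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - pad_voxels, 0)
        hi = min(int(idx[-1]) + pad_voxels + 1, volume.shape[ax])
        slices.append(slice(lo, hi))
        new_origin.append(volume.origin[ax] + lo * volume.spacing[ax])
    out = replace(
        volume,
        values=volume.values[tuple(slices)].copy(),
        origin=tuple(new_origin),
        meta=dict(volume.meta),
    )
    out.meta["crop_slices"] = [(s.start, s.stop) for s in slices]
    return out


# -- tabular records ----------------------------------------------------------


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a morphometric record table as CSV (schema-checked)."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    records.to_csv(path, index=False)  # default float repr round-trips exactly


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a morphometric record CSV, checking the column schema."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file {path} missing required columns: {missing}")
    return df
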
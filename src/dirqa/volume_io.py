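"""Image, vector-field, landmark and mask containers plus file I/O.

Conventions used throughout the package:

* Voxel arrays are indexed ``(z, y, x)``, 0-based (the NumPy view of a
  medical image as returned by SimpleITK).
* ``spacing`` and ``origin`` are 3-vectors in **world (x, y, z) order**,
  in millimetres. The world position of voxel ``(k, j, i)`` is
  ``origin + (i, j, k) * spacing`` — i.e. the origin is the centre of the
  first voxel.
* Displacement vectors carry components in ``(x, y, z)`` order, in mm.
* Only axis-aligned (identity direction cosine) volumes are accepted;
  anything else is rejected rather than silently resampled, because a
  silent flip would corrupt the sign of displacement components.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "VectorField",
    "LandmarkSet",
    "StructureMask",
    "read_volume",
    "write_volume",
    "read_vector_field",
    "write_vector_field",
    "read_landmarks",
    "write_landmarks",
    "read_mask",
    "voxel_to_world",
    "world_to_voxel",
]

_DIRECTION_TOL = 1e-6
_SLICE_GAP_TOL = 1e-3  # mm


def _as_vec3(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class ImageVolume:
    """A scalar 3D image in Hounsfield units on a regular axis-aligned grid.

    Parameters
    ----------
    voxels:
        3D array indexed ``(z, y, x)``.
    spacing:
        Voxel size ``(sx, sy, sz)`` in mm; all components positive.
    origin:
        World position ``(x, y, z)`` in mm of the centre of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # (nz, ny, nx)


@dataclass
class VectorField:
    """Per-voxel 3D displacements in mm with a declared mapping direction.

    ``vectors`` has shape ``(nz, ny, nx, 3)`` with components in (x, y, z)
    order. ``direction_tag`` is a free-form ``"FROM->TO"`` label stating
    which image's points the field maps from and to; comparisons refuse
    fields whose target images differ instead of silently flipping signs.
    """

    vectors: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction_tag: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(
                f"vectors must have shape (nz, ny, nx, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("vector components must be finite")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @property
    def target(self) -> str:
        """The TO part of the direction tag ('' when untagged)."""
        if "->" in self.direction_tag:
            return self.direction_tag.split("->", 1)[1].strip()
        return ""


@dataclass
class LandmarkSet:
    """World-coordinate points (mm) with optional string labels."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) == 0:
            raise ValueError("points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise ValueError("labels length must match number of points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StructureMask:
    """Binary mask on the grid of a reference volume/field."""

    voxels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError("mask must be 3D")
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.voxels = vox.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


# ---------------------------------------------------------------------------
# coordinate transforms


def voxel_to_world(
    index_zyx: np.ndarray, spacing: np.ndarray, origin: np.ndarray
) -> np.ndarray:
    """Map (possibly fractional) ``(z, y, x)`` indices to world (x, y, z) mm."""
    idx = np.atleast_2d(np.asarray(index_zyx, dtype=float))
    world = origin[None, :] + idx[:, ::-1] * spacing[None, :]
    return world.reshape(np.shape(index_zyx))


def world_to_voxel(
    points_xyz: np.ndarray, spacing: np.ndarray, origin: np.ndarray
) -> np.ndarray:
    """Map world (x, y, z) mm points to fractional ``(z, y, x)`` indices."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    idx = ((pts - origin[None, :]) / spacing[None, :])[:, ::-1]
    return idx.reshape(np.shape(points_xyz))


# ---------------------------------------------------------------------------
# SimpleITK bridging


def _check_direction(img: sitk.Image, path: str) -> None:
    d = np.asarray(img.GetDirection())
    n = int(round(np.sqrt(d.size)))
    if not np.allclose(d.reshape(n, n), np.eye(n), atol=_DIRECTION_TOL):
        raise ValueError(
            f"{path}: non-identity direction matrix; this toolkit only accepts "
            "axis-aligned volumes (resample externally first)"
        )


def _from_sitk(img: sitk.Image, path: str) -> ImageVolume:
    _check_direction(img, path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError(f"{path}: expected scalar pixel data")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    if arr.ndim == 2:
        arr = arr[None]
    return ImageVolume(
        voxels=arr.astype(float),
        spacing=np.asarray(img.GetSpacing(), dtype=float),
        origin=np.asarray(img.GetOrigin(), dtype=float),
    )


def _dicom_series_files(path: str) -> list[str]:
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(path)
    if not files:
        raise FileNotFoundError(f"no DICOM series found under {path}")
    return list(files)


def _check_slice_spacing(files: list[str]) -> None:
    """Reject series whose inter-slice gaps are not uniform."""
    import pydicom

    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            return  # cannot check; let SimpleITK decide
        zs.append(float(ipp[2]))
    zs = np.sort(np.asarray(zs))
    if len(zs) >= 3:
        gaps = np.diff(zs)
        if np.ptp(gaps) > _SLICE_GAP_TOL:
            raise ValueError(
                f"inconsistent DICOM slice spacing: gaps range "
                f"{gaps.min():.4f}–{gaps.max():.4f} mm"
            )


def read_volume(
    path: str | os.PathLike,
    format: Literal["dicom_series", "metaimage", "nifti", "auto"] = "auto",
) -> ImageVolume:
    """Read a scalar volume from a DICOM series directory, .mhd/.mha or NIfTI.

    Values are returned in HU: the format's rescale slope/intercept is
    applied (SimpleITK does this for DICOM) and nothing else.
    """
    path = str(path)
    if format == "auto":
        if os.path.isdir(path):
            format = "dicom_series"
        elif path.endswith((".mhd", ".mha")):
            format = "metaimage"
        elif path.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer format of {path}")
    if format == "dicom_series":
        files = _dicom_series_files(path)
        _check_slice_spacing(files)
        reader = sitk.ImageSeriesReader()
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        img = sitk.ReadImage(path)
    return _from_sitk(img, path)


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> None:
    """Write a scalar volume as MetaImage (.mhd/.mha) or NIfTI (.nii[.gz])."""
    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def read_vector_field(
    path: str | os.PathLike,
    direction_tag: str = "",
    layout: Literal["auto", "interleaved", "planar"] = "auto",
) -> VectorField:
    """Read a 3-component displacement volume (MetaImage or NIfTI), mm-valued.

    ``layout='interleaved'`` expects a native 3-vector image;
    ``'planar'`` expects a 4D scalar image whose last dimension holds the
    x, y, z component planes. ``'auto'`` accepts either.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = sitk.ReadImage(path)
    ncomp = img.GetNumberOfComponentsPerPixel()
    if ncomp == 3:
        _check_direction(img, path)
        arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3) components (x, y, z)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
    elif ncomp == 1 and img.GetDimension() == 4 and layout in ("auto", "planar"):
        arr4 = sitk.GetArrayFromImage(img)  # (c, z, y, x) — sitk reverses axes
        if arr4.shape[0] != 3:
            raise ValueError(
                f"{path}: planar displacement volume must have 3 component "
                f"planes, got {arr4.shape[0]}"
            )
        arr = np.moveaxis(arr4, 0, -1)
        spacing = np.asarray(img.GetSpacing()[:3], dtype=float)
        origin = np.asarray(img.GetOrigin()[:3], dtype=float)
    else:
        raise ValueError(
            f"{path}: expected a 3-component displacement volume, "
            f"got {ncomp} component(s)"
        )
    return VectorField(
        vectors=arr.astype(float),
        spacing=spacing,
        origin=origin,
        direction_tag=direction_tag,
    )


def write_vector_field(fld: VectorField, path: str | os.PathLike) -> None:
    """Write a displacement field as a 3-component MetaImage/NIfTI volume."""
    img = sitk.GetImageFromArray(fld.vectors, isVector=True)
    img.SetSpacing(tuple(fld.spacing))
    img.SetOrigin(tuple(fld.origin))
    sitk.WriteImage(img, str(path))


def read_mask(path: str | os.PathLike, name: str = "") -> StructureMask:
    """Read a 0/1 volume as a structure mask."""
    vol = read_volume(path)
    return StructureMask(voxels=np.rint(vol.voxels).astype(int), name=name or Path(str(path)).stem)


def read_landmarks(
    path: str | os.PathLike,
    units: Literal["mm", "voxel"] = "mm",
    reference: ImageVolume | VectorField | None = None,
) -> LandmarkSet:
    """Read whitespace-delimited landmark points, one ``x y z`` triple per line.

    With ``units='voxel'`` the coordinates are voxel indices in (x, y, z)
    order and are converted to world mm using ``reference``'s spacing and
    origin (public landmark sets ship in both conventions, so the choice
    is a flag, not a guess).
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            toks = stripped.split()
            if len(toks) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(toks)}"
                )
            try:
                rows.append([float(t) for t in toks])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token") from exc
    if not rows:
        raise ValueError(f"{path}: no landmark points found")
    pts = np.asarray(rows, dtype=float)
    if units == "voxel":
        if reference is None:
            raise ValueError("voxel-index landmarks require a reference volume")
        pts = reference.origin[None, :] + pts * reference.spacing[None, :]
    return LandmarkSet(points=pts)


def write_landmarks(landmarks: LandmarkSet, path: str | os.PathLike) -> None:
    """Write landmarks as plain ``x y z`` lines (world mm)."""
    with open(path, "w") as fh:
        for p in landmarks.points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
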
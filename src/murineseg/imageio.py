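"""Volumetric image containers and NRRD/NIfTI input-output.

All volumes are held in ``(z, y, x)`` index order with ``z`` the axial
(cranio-caudal) axis; readers convert from the on-disk order.  Spacing and
origin are kept in millimetres, and the world position of voxel ``(k, j, i)``
is ``origin + (k, j, i) * spacing`` (0-based indices, voxel centres).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GridMismatchError

__all__ = [
    "Volume",
    "Mask",
    "read_volume",
    "read_mask",
    "write_volume",
    "resample_isotropic",
]

#: intensity semantics a Volume may carry
INTENSITY_KINDS = ("HU", "normalized", "probability", "difference")


@dataclass
class Volume:
    """A 3D scalar grid with physical geometry.

    Parameters
    ----------
    data:
        3D array indexed ``(z, y, x)``.
    spacing:
        Per-axis voxel size ``(sz, sy, sx)`` in mm; all strictly positive.
    origin:
        World position of voxel ``(0, 0, 0)`` in mm, ``(oz, oy, ox)``.
    intensity_kind:
        One of ``HU`` (calibrated attenuation), ``normalized`` (min-max scaled
        to [0, 1]), ``probability`` (per-voxel lung probability in [0, 1]) or
        ``difference`` (signed mask difference).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3 (z, y, x)")
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive and finite, got {self.spacing}")
        if self.intensity_kind not in INTENSITY_KINDS:
            raise ValueError(f"intensity_kind must be one of {INTENSITY_KINDS}")
        if self.intensity_kind in ("normalized", "probability") and self.data.size:
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"{self.intensity_kind} volume must lie in [0, 1], got [{lo}, {hi}]"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Grid extent per axis in mm (shape * spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World positions (mm) of an ``(n, 3)`` array of voxel indices."""
        return np.asarray(indices, dtype=float) * np.array(self.spacing) + np.array(self.origin)

    def same_grid(self, other: "Volume | Mask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray, intensity_kind: str | None = None) -> "Volume":
        return Volume(
            data,
            self.spacing,
            self.origin,
            self.intensity_kind if intensity_kind is None else intensity_kind,
        )


@dataclass
class Mask:
    """A binary lung-label grid aligned voxel-for-voxel with a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, got {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if not all(math.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive and finite, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def num_voxels(self) -> int:
        return int(self.data.sum())

    def bool(self) -> np.ndarray:
        return self.data.astype(bool)

    same_grid = Volume.same_grid
    world_coords = Volume.world_coords
    physical_extent = Volume.physical_extent

    def with_data(self, data: np.ndarray) -> "Mask":
        return Mask(data, self.spacing, self.origin)


# ---------------------------------------------------------------------------
# SimpleITK bridging.  SimpleITK orders axes (x, y, z); arrays from
# GetArrayFromImage come back (z, y, x), which is our internal order already.
# ---------------------------------------------------------------------------

def to_sitk(obj: Volume | Mask) -> sitk.Image:
    img = sitk.GetImageFromArray(obj.data)
    img.SetSpacing(tuple(obj.spacing[::-1]))
    img.SetOrigin(tuple(obj.origin[::-1]))
    return img


def from_sitk(img: sitk.Image, intensity_kind: str = "HU") -> Volume:
    data = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing()[::-1])
    origin = tuple(img.GetOrigin()[::-1])
    return Volume(data, spacing, origin, intensity_kind)


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    name = path.name.lower()
    if name.endswith(".nrrd") or name.endswith(".nhdr"):
        return "nrrd"
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    raise FormatError(f"cannot infer format from extension of {path}")


def _check_nrrd_spacing_fields(path: Path) -> None:
    """NRRD headers are plain text even for gzip-encoded data; demand an
    explicit voxel-size field rather than silently defaulting to 1 mm."""
    with open(path, "rb") as fh:
        header = fh.read(4096).split(b"\n\n")[0].decode("ascii", errors="replace")
    fields = [line.split(":")[0].strip().lower() for line in header.splitlines() if ":" in line]
    if "space directions" not in fields and "spacings" not in fields:
        raise FormatError(f"{path}: NRRD header lacks 'space directions' (or 'spacings') field")


def read_volume(path: str | os.PathLike, format: str = "auto", intensity_kind: str = "HU") -> Volume:
    """Read a 3D volume from NRRD or NIfTI, preserving spacing and origin.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    FormatError
        If the file cannot be parsed as the named format or lacks voxel-size
        metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "nrrd":
        _check_nrrd_spacing_fields(path)
        reader_name = "NrrdImageIO"
    elif fmt == "nifti":
        reader_name = "NiftiImageIO"
    else:
        raise FormatError(f"unknown format {fmt!r}; expected 'nrrd', 'nifti' or 'auto'")
    try:
        img = sitk.ReadImage(str(path), imageIO=reader_name)
    except RuntimeError as exc:  # sitk wraps parse failures in RuntimeError
        raise FormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    vol = from_sitk(img, intensity_kind)
    if not all(math.isfinite(s) and s > 0 for s in vol.spacing):
        raise FormatError(f"{path}: invalid spacing metadata {vol.spacing}")
    return vol


def read_mask(path: str | os.PathLike, format: str = "auto") -> Mask:
    v = read_volume(path, format)
    return Mask(np.rint(v.data).astype(np.uint8), v.spacing, v.origin)


def write_volume(v: Volume | Mask, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a volume or mask to NRRD/NIfTI; re-reading yields identical
    data, spacing and origin (lossless for integer and float grids)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt not in ("nrrd", "nifti"):
        raise FormatError(f"unknown format {fmt!r}")
    if not path.parent.exists():
        raise IOError(f"parent directory {path.parent} does not exist")
    sitk.WriteImage(to_sitk(v), str(path), useCompression=path.name.endswith(".gz"))


def resample_isotropic(
    obj: Volume | Mask,
    target_spacing_mm: float,
    mode: str | None = None,
) -> Volume | Mask:
    """Resample onto an isotropic grid of the requested spacing.

    The output grid size is ``round(shape * spacing / target)`` per axis, which
    preserves the physical extent to within half a voxel per axis.  Intensities
    use linear interpolation, masks nearest-neighbour (so binarity survives);
    pass ``mode`` explicitly to override.
    """
    t = float(target_spacing_mm)
    if not (t > 0 and math.isfinite(t)):
        raise ValueError(f"target_spacing_mm must be positive, got {target_spacing_mm}")
    is_mask = isinstance(obj, Mask)
    if mode is None:
        mode = "nearest" if is_mask else "linear"
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")

    new_shape = tuple(max(1, round(n * s / t)) for n, s in zip(obj.shape, obj.spacing))
    img = to_sitk(obj)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((t, t, t))
    res.SetSize(tuple(int(n) for n in new_shape[::-1]))
    res.SetOutputOrigin(img.GetOrigin())
    res.SetOutputDirection(img.GetDirection())
    res.SetInterpolator(sitk.sitkNearestNeighbor if mode == "nearest" else sitk.sitkLinear)
    res.SetDefaultPixelValue(float(np.min(obj.data)))
    out = res.Execute(img)
    if is_mask:
        return Mask(sitk.GetArrayFromImage(out), (t, t, t), obj.origin)
    vol = from_sitk(out, obj.intensity_kind)
    if obj.intensity_kind in ("normalized", "probability"):
        vol = replace(vol, data=np.clip(vol.data, 0.0, 1.0))
    return vol
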
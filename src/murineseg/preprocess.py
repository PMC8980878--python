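"""Turn multi-mouse bed scans into normalized per-mouse axial slice stacks.

The preparation sequence mirrors standard practice for 2D segmentation
networks: crop each animal out of the bed using its reference lung mask,
resample to an isotropic target, min-max normalize to [0, 1], then extract
axial sections padded to a size the encoder's pooling ladder accepts.
Every step is exactly invertible given the recorded bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, EmptyMaskError, GridMismatchError
from .imageio import Mask, Volume

__all__ = [
    "BoundingBox",
    "SliceStack",
    "lung_bbox",
    "crop_mice",
    "normalize_intensity",
    "extract_axial_slices",
    "restack",
]


@dataclass(frozen=True)
class BoundingBox:
    """Closed (inclusive) 0-based index ranges per axis."""

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self):
        if self.z0 > self.z1 or self.y0 > self.y1 or self.x0 > self.x1:
            raise ValueError(f"degenerate bounding box {self}")

    def expand(self, margin: int, shape: tuple[int, int, int]) -> "BoundingBox":
        """Grow by ``margin`` voxels per side, clamped to the grid."""
        return BoundingBox(
            max(self.z0 - margin, 0), min(self.z1 + margin, shape[0] - 1),
            max(self.y0 - margin, 0), min(self.y1 + margin, shape[1] - 1),
            max(self.x0 - margin, 0), min(self.x1 + margin, shape[2] - 1),
        )

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1 + 1), slice(self.y0, self.y1 + 1), slice(self.x0, self.x1 + 1))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.z1 - self.z0 + 1, self.y1 - self.y0 + 1, self.x1 - self.x0 + 1)


@dataclass
class SliceStack:
    """Axial sections of one normalized volume, zero-padded for the network.

    ``slices`` is ``(n_slices, H, W)`` in source z order; ``pad`` records the
    symmetric zero padding ``((y_before, y_after), (x_before, x_after))`` so
    :func:`restack` can invert the extraction exactly.
    """

    slices: np.ndarray
    pad: tuple[tuple[int, int], tuple[int, int]]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    norm_min: float | None = None
    norm_max: float | None = None

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def lung_bbox(m: Mask) -> BoundingBox:
    """Tightest box containing all mask voxels (the 'lung edge' coordinates)."""
    idx = np.argwhere(m.data)
    if idx.size == 0:
        raise EmptyMaskError("cannot take the bounding box of an empty mask")
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    return BoundingBox(lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])


def crop_mice(
    bed: Volume, masks: list[Mask], margin_voxels: int = 10
) -> list[tuple[Volume, Mask]]:
    """Cut one sub-volume per animal out of a multi-mouse bed scan.

    Boxes are the per-mask lung bounding boxes expanded by ``margin_voxels``
    and clamped to the grid; origins are shifted so world coordinates of every
    voxel are preserved.
    """
    if margin_voxels < 0:
        raise ValueError("margin_voxels must be nonnegative")
    for m in masks:
        if not bed.same_grid(m):
            raise GridMismatchError("mask grid differs from bed grid")
    if len(masks) > 1:
        total = sum(m.data.astype(np.int32) for m in masks)
        if total.max() > 1:
            raise ValueError("reference masks overlap; each animal needs a disjoint mask")
    out = []
    for m in masks:
        box = lung_bbox(m).expand(margin_voxels, bed.shape)
        sl = box.slices()
        new_origin = tuple(
            o + lo * s for o, lo, s in zip(bed.origin, (box.z0, box.y0, box.x0), bed.spacing)
        )
        sub_v = Volume(bed.data[sl].copy(), bed.spacing, new_origin, bed.intensity_kind)
        sub_m = Mask(m.data[sl].copy(), bed.spacing, new_origin)
        out.append((sub_v, sub_m))
    return out


def normalize_intensity(v: Volume, return_record: bool = False):
    """Affine min-max scaling of a volume to [0, 1].

    Monotone and idempotent (a volume already spanning [0, 1] is returned
    unchanged up to floating error).  Raises on constant input, where the
    scaling is undefined.
    """
    lo = float(v.data.min())
    hi = float(v.data.max())
    if hi <= lo:
        raise DegenerateInputError("cannot normalize a constant volume")
    data = (v.data.astype(np.float64) - lo) / (hi - lo)
    out = Volume(data, v.spacing, v.origin, "normalized")
    if return_record:
        return out, (lo, hi)
    return out


def extract_axial_slices(v: Volume, pad_multiple: int = 16) -> SliceStack:
    """Extract one 2D section per z index, zero-padded so height and width are
    multiples of ``pad_multiple`` (the network's pooling-ladder constraint).
    Padding is symmetric (extra voxel goes after) and recorded for inversion.
    """
    if v.intensity_kind not in ("normalized", "probability"):
        raise ValueError("extract_axial_slices expects a normalized volume")
    if pad_multiple < 1:
        raise ValueError("pad_multiple must be >= 1")
    nz, ny, nx = v.shape
    H = int(np.ceil(ny / pad_multiple)) * pad_multiple
    W = int(np.ceil(nx / pad_multiple)) * pad_multiple
    py, px = H - ny, W - nx
    pad = ((py // 2, py - py // 2), (px // 2, px - px // 2))
    slices = np.pad(v.data, ((0, 0), pad[0], pad[1]))
    return SliceStack(slices, pad, v.spacing, v.origin)


def extract_mask_slices(m: Mask, pad_multiple: int = 16) -> SliceStack:
    """Same extraction for a paired binary mask (zero padding keeps binarity)."""
    as_vol = Volume(m.data.astype(np.float64), m.spacing, m.origin, "normalized")
    return extract_axial_slices(as_vol, pad_multiple)


def restack(stack: SliceStack, intensity_kind: str = "normalized") -> Volume:
    """Invert :func:`extract_axial_slices` exactly using the recorded padding."""
    (py0, py1), (px0, px1) = stack.pad
    _, H, W = stack.slices.shape
    data = stack.slices[:, py0 : H - py1, px0 : W - px1]
    return Volume(data, stack.spacing, stack.origin, intensity_kind)
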
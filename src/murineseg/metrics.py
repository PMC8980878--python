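"""Segmentation accuracy and mask-interchangeability metrics.

Accuracy is quantified by the Dice score coefficient (DSC) and the 95th
percentile of the surface Hausdorff distance in millimetres (HD95), with
median / interquartile-range cohort summaries.  Interchangeability of two
segmentation approaches is assessed the way fibrosis studies use the masks:
lung HU histograms (cohort mean with standard error) and a fibrosis-index
surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyMaskError, GridMismatchError, UndefinedMetricError
from .imageio import Mask, Volume

__all__ = [
    "dice",
    "hd95",
    "surface_voxels",
    "MetricReport",
    "summarize",
    "lung_histogram",
    "cohort_mean_sem",
    "fibrosis_index",
]


def _check_grids(a: Mask, b: Mask) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"masks are not on a common grid: {a.shape}@{a.spacing} vs {b.shape}@{b.spacing}"
        )


def dice(a: Mask, b: Mask) -> float:
    """Dice score coefficient ``2|A n B| / (|A| + |B|)``.

    Symmetric, in [0, 1].  Two empty masks agree perfectly on an all-negative
    grid, so that case returns 1.0 (with a warning).
    """
    _check_grids(a, b)
    na, nb = a.num_voxels(), b.num_voxels()
    if na == 0 and nb == 0:
        warnings.warn("dice of two empty masks defined as 1.0", stacklevel=2)
        return 1.0
    inter = int((a.bool() & b.bool()).sum())
    return 2.0 * inter / (na + nb)


def surface_voxels(m: Mask) -> np.ndarray:
    """Indices (n, 3) of mask voxels with >= 1 face-adjacent background
    neighbour (the grid boundary counts as background)."""
    fg = m.bool()
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(fg, structure=struct, border_value=0)
    return np.argwhere(fg & ~interior)


def hd95(
    a: Mask,
    b: Mask,
    spacing: tuple[float, float, float] | None = None,
    variant: str = "pooled",
) -> float:
    """95th percentile of surface-to-surface distances, in mm.

    The default ``pooled`` convention (as in common medical-image libraries)
    pools the distances from every surface voxel of A to the surface of B
    with those from B to A and takes one 95th percentile (linear
    interpolation).  ``variant='max_directed'`` instead returns the maximum
    of the two directed 95th percentiles.  Distances are between voxel
    centres in world coordinates.
    """
    _check_grids(a, b)
    if a.num_voxels() == 0 or b.num_voxels() == 0:
        raise UndefinedMetricError("hd95 is undefined for an empty mask")
    sp = np.asarray(spacing if spacing is not None else a.spacing, dtype=float)
    pa = surface_voxels(a) * sp
    pb = surface_voxels(b) * sp
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    if variant == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    if variant == "max_directed":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    raise ValueError(f"variant must be 'pooled' or 'max_directed', got {variant!r}")


@dataclass
class MetricReport:
    """Per-subject metric records plus median / IQR cohort summary."""

    per_subject: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        combined = self.per_subject.copy()
        combined.to_csv(path, index=False)
        with open(path, "a") as fh:
            fh.write("\n")
            self.summary.to_csv(fh)


def summarize(records: list[dict] | pd.DataFrame) -> MetricReport:
    """Cohort summary: median and interquartile range per metric column.

    Percentiles use linear interpolation (type-7), the numpy default.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValueError("summarize needs at least one record")
    metric_cols = [c for c in df.columns if df[c].dtype.kind in "fi" and c != "subject"]
    rows = {}
    for c in metric_cols:
        vals = df[c].dropna().to_numpy(dtype=float)
        rows[c] = {
            "median": float(np.percentile(vals, 50)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
        }
    return MetricReport(df, pd.DataFrame(rows).T[["median", "q25", "q75"]])


def lung_histogram(
    v: Volume, m: Mask, bin_edges: np.ndarray, density: bool = False
) -> np.ndarray:
    """Histogram of HU values inside the mask."""
    if v.intensity_kind != "HU":
        raise ValueError("lung_histogram expects an HU volume")
    if not v.same_grid(m):
        raise GridMismatchError("volume and mask grids differ")
    if m.num_voxels() == 0:
        raise EmptyMaskError("lung_histogram needs a nonempty mask")
    hist, _ = np.histogram(v.data[m.bool()], bins=bin_edges, density=density)
    return hist


def cohort_mean_sem(histograms: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Across-subject mean curve and standard error of the mean per bin."""
    H = np.stack([np.asarray(h, dtype=float) for h in histograms])
    mean = H.mean(axis=0)
    n = H.shape[0]
    sem = H.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem


def fibrosis_index(v: Volume, m: Mask, cutoff_hu: float = -500.0) -> float:
    """Fraction of in-mask voxels with HU strictly above ``cutoff_hu``.

    This is a surrogate severity score — fibrotic consolidation raises lung
    attenuation, so the high-attenuation fraction grows monotonically with
    lesion burden.  It is *not* the published fibrosis-index formula (which
    lives in the fibrosis-quantification literature this package does not
    reimplement); use it for relative comparisons between masks, not as an
    absolute clinical quantity.
    """
    if v.intensity_kind != "HU":
        raise ValueError("fibrosis_index expects an HU volume")
    if not v.same_grid(m):
        raise GridMismatchError("volume and mask grids differ")
    if m.num_voxels() == 0:
        raise EmptyMaskError("fibrosis_index needs a nonempty mask")
    inside = v.data[m.bool()]
    return float((inside > cutoff_hu).mean())
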
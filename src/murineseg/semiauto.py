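"""HU-window reference segmentation with automated cleanup.

The reference ("ground truth") lung masks come from attenuation windowing:
voxels between -900 and -100 HU are provisionally lung.  The window also
captures the trachea and primary bronchi; in the original semiautomatic
protocol those voxels were removed by hand.  Here :func:`clean_mask` is an
automated surrogate for that curation — morphological opening-by-
reconstruction to delete tube-like airway structures, then retention of the
largest connected components.  It is a surrogate, not a reproduction of
human editing, and is flagged as such in the documentation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError
from .imageio import Mask, Volume

__all__ = ["threshold_lung", "clean_mask"]

#: 26-connectivity structuring element for 3D foreground components
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def threshold_lung(
    v: Volume, lo_hu: float = -900.0, hi_hu: float = -100.0, closed: bool = True
) -> Mask:
    """Approximate lung segmentation by HU windowing.

    The interval is closed on both ends by default (``lo_hu <= HU <= hi_hu``);
    ``closed=False`` gives the strict-inequality reading.  Monotone: widening
    the window never removes voxels.
    """
    if lo_hu >= hi_hu:
        raise ValueError(f"lo_hu must be < hi_hu, got [{lo_hu}, {hi_hu}]")
    if v.intensity_kind != "HU":
        raise ValueError("threshold_lung expects a volume in Hounsfield units")
    if closed:
        sel = (v.data >= lo_hu) & (v.data <= hi_hu)
    else:
        sel = (v.data > lo_hu) & (v.data < hi_hu)
    return Mask(sel.astype(np.uint8), v.spacing, v.origin)


def _ellipsoid_se(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ball of the given physical radius, expressed on an anisotropic grid."""
    r_vox = [max(radius_mm / s, 0.0) for s in spacing]
    ri = [int(np.floor(r)) for r in r_vox]
    zz, yy, xx = np.mgrid[-ri[0] : ri[0] + 1, -ri[1] : ri[1] + 1, -ri[2] : ri[2] + 1]
    se = (
        (zz / max(r_vox[0], 1e-9)) ** 2
        + (yy / max(r_vox[1], 1e-9)) ** 2
        + (xx / max(r_vox[2], 1e-9)) ** 2
    ) <= 1.0
    return se


def clean_mask(
    m: Mask,
    keep_components: int = 2,
    airway_radius_mm: float = 0.9,
    connectivity: int = 26,
) -> Mask:
    """Automated cleanup of a thresholded lung mask.

    Tube-like structures of radius <= ``airway_radius_mm`` (trachea, primary
    bronchi) are removed by morphological opening with a ball of that radius
    followed by reconstruction, which restores every component thick enough
    to survive the opening while discarding thin ones entirely.  The
    ``keep_components`` largest surviving 26-connected components (the two
    lungs, by default) are kept.  Never adds voxels; idempotent.
    """
    if m.num_voxels() == 0:
        raise EmptyMaskError("clean_mask needs a nonempty mask")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])

    fg = m.bool()
    if airway_radius_mm > 0:
        se = _ellipsoid_se(airway_radius_mm, m.spacing)
        opened = ndimage.binary_opening(fg, structure=se)
        # reconstruction under the original mask: keep whole components that
        # intersect the opening, drop components erased by it
        labels, n = ndimage.label(fg, structure=struct)
        surviving = np.unique(labels[opened & fg])
        fg = np.isin(labels, surviving[surviving > 0])
    if not fg.any():
        return Mask(fg.astype(np.uint8), m.spacing, m.origin)

    labels, n = ndimage.label(fg, structure=struct)
    if n > keep_components:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        keep = np.argsort(sizes)[::-1][:keep_components] + 1
        fg = np.isin(labels, keep)
    return Mask(fg.astype(np.uint8), m.spacing, m.origin)
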
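"""Synthetic multi-mouse thorax CT phantoms with paired ground-truth lung masks.

The generator emulates the geometry the segmentation pipeline cares about —
a soft-tissue body, two air-filled lung lobes indented medially by a heart,
a thin airway that an HU-window segmentation wrongly picks up, and optional
fibrotic lesions that raise lung attenuation — so the whole pipeline can be
exercised and graded without animal data.  It makes no attempt at physical CT
realism (no beam hardening, scatter or reconstruction texture).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError
from .imageio import Mask, Volume

__all__ = ["PhantomSpec", "generate_mouse", "generate_bed"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic mouse thorax.

    HU defaults follow the usual CT scale: background air -1000, lung
    parenchyma -750 (within the -900..-100 HU window used for reference
    segmentation), soft tissue +20, fibrotic lesions -300.  ``noise_sd_hu``
    defaults to 20 HU, a typical noise magnitude for low-dose small-animal
    protocols; set it to 0 for the noiseless constructions used by exact
    oracles.
    """

    n_mice: int = 4
    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing_mm: tuple[float, float, float] = (0.35, 0.35, 0.35)
    body_hu: float = 20.0
    lung_hu: float = -750.0
    background_hu: float = -1000.0
    fibrosis_fraction: float = 0.0
    fibrosis_hu: float = -300.0
    noise_sd_hu: float = 20.0
    seed: int = 0
    emphysema: bool = False
    emphysema_hu: float = -950.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_mice <= 6:
            raise ValueError(f"n_mice must be in [1, 6], got {self.n_mice}")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise ValueError("fibrosis_fraction must be in [0, 1]")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be nonnegative")
        if self.fibrosis_fraction == 0 and not (-900 < self.lung_hu < -100):
            raise ValueError(
                "lung_hu must lie inside (-900, -100) HU so the HU-window "
                f"reference segmentation can succeed, got {self.lung_hu}"
            )


def _ellipsoid(shape, center, semi):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _grow_fibrosis(lung: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    """Spherical blobs grown from random in-lung seeds until exactly
    ``target`` lung voxels are lesioned."""
    fib = np.zeros_like(lung, dtype=bool)
    coords = np.argwhere(lung)
    remaining = target
    guard = 0
    while remaining > 0 and guard < 10_000:
        guard += 1
        cz, cy, cx = coords[rng.integers(len(coords))]
        r = float(rng.uniform(2.0, 4.5))
        ri = int(np.ceil(r))
        z0, z1 = max(cz - ri, 0), min(cz + ri + 1, lung.shape[0])
        y0, y1 = max(cy - ri, 0), min(cy + ri + 1, lung.shape[1])
        x0, x1 = max(cx - ri, 0), min(cx + ri + 1, lung.shape[2])
        zz, yy, xx = np.mgrid[z0:z1, y0:y1, x0:x1]
        d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        blob = (d2 <= r * r) & lung[z0:z1, y0:y1, x0:x1] & ~fib[z0:z1, y0:y1, x0:x1]
        n_new = int(blob.sum())
        if n_new == 0:
            continue
        if n_new > remaining:
            # trim the blob to the voxels nearest its seed to land exactly
            idx = np.argwhere(blob)
            order = np.argsort(d2[blob], kind="stable")[:remaining]
            blob = np.zeros_like(blob)
            blob[tuple(idx[order].T)] = True
            n_new = remaining
        sub = fib[z0:z1, y0:y1, x0:x1]
        sub |= blob
        remaining -= n_new
    if remaining > 0:
        raise GeometryError("could not place requested fibrosis fraction")
    return fib


def generate_mouse(
    spec: PhantomSpec, seed: int | None = None, parts: bool = False
) -> tuple[Volume, Mask] | tuple[Volume, Mask, dict[str, np.ndarray]]:
    """Build one synthetic mouse thorax.

    Returns an HU :class:`Volume` and the ground-truth lung :class:`Mask`
    (two ellipsoidal lobes, heart indentation carved out, airway excluded).
    Deterministic given ``(spec, seed)``; ``seed`` defaults to ``spec.seed``.
    With ``parts=True`` a third dict of boolean region masks (body, lungs,
    heart, airway, fibrosis) is returned for diagnostics.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    nz, ny, nx = spec.grid_shape

    # mild per-animal anatomical variability: ~3% size jitter and sub-2-voxel
    # positional shifts, so no two phantoms are voxel-identical
    jit = rng.uniform(0.97, 1.03, size=6)
    dz, dy, dx = rng.uniform(-1.5, 1.5, size=3)

    body = _ellipsoid(
        spec.grid_shape,
        (nz * 0.5 + dz, ny * 0.52 + dy, nx * 0.5 + dx),
        (nz * 0.48 * jit[0], ny * 0.38 * jit[1], nx * 0.42 * jit[2]),
    )
    lobe_semi = (nz * 0.26 * jit[3], ny * 0.20 * jit[4], nx * 0.13 * jit[5])
    lcenter_z, lcenter_y = nz * 0.52 + dz, ny * 0.48 + dy
    left = _ellipsoid(spec.grid_shape, (lcenter_z, lcenter_y, nx * 0.32 + dx), lobe_semi)
    right = _ellipsoid(spec.grid_shape, (lcenter_z, lcenter_y, nx * 0.68 + dx), lobe_semi)
    lungs = left | right
    if (lungs & ~body).any():
        raise GeometryError("lung lobes do not fit inside the body ellipsoid on this grid")

    # heart: soft-tissue ellipsoid between/under the lobes; indents their
    # medial surfaces, giving the mismatch module its hot-spot anatomy
    heart = _ellipsoid(
        spec.grid_shape,
        (nz * 0.60 + dz, ny * 0.56 + dy, nx * 0.50 + dx),
        (nz * 0.17, ny * 0.15, nx * 0.15),
    )
    lungs &= ~heart

    # thin airway above the lungs: air-like HU inside the window, excluded
    # from the ground truth, so HU thresholding acquires a surplus to clean
    airway = np.zeros(spec.grid_shape, dtype=bool)
    z_top = int(lcenter_z - lobe_semi[0]) - 2
    z_lo = max(2, int(nz * 0.5 - nz * 0.48) + 2)
    if z_lo < z_top:
        yy, xx = np.ogrid[:ny, :nx]
        tube = ((yy - lcenter_y) ** 2 + (xx - nx * 0.5 - dx) ** 2) <= 1.3**2
        airway[z_lo:z_top] = tube
    airway &= body & ~lungs

    fib = np.zeros(spec.grid_shape, dtype=bool)
    if spec.fibrosis_fraction > 0:
        target = int(round(spec.fibrosis_fraction * lungs.sum()))
        fib = _grow_fibrosis(lungs, target, rng)

    emph = np.zeros(spec.grid_shape, dtype=bool)
    if spec.emphysema:
        emph = _grow_fibrosis(lungs & ~fib, int(round(0.1 * lungs.sum())), rng)

    data = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    data[body] = spec.body_hu
    data[lungs] = spec.lung_hu
    data[airway] = spec.lung_hu
    data[fib] = spec.fibrosis_hu
    data[emph] = spec.emphysema_hu
    if spec.noise_sd_hu > 0:
        data += rng.normal(0.0, spec.noise_sd_hu, size=data.shape)

    vol = Volume(data, spec.spacing_mm, (0.0, 0.0, 0.0), "HU")
    mask = Mask(lungs.astype(np.uint8), spec.spacing_mm, (0.0, 0.0, 0.0))
    if parts:
        return vol, mask, {"body": body, "lungs": lungs, "heart": heart, "airway": airway, "fibrosis": fib}
    return vol, mask


def generate_bed(spec: PhantomSpec) -> tuple[Volume, list[Mask]]:
    """Lay ``spec.n_mice`` phantoms on one scanner bed.

    Mice are tiled on a 1x n or 2x n grid (up to 2 rows of 3), each inside
    its own tile so bodies — and a fortiori lung masks — are pairwise
    disjoint.  Per-mouse anatomy uses seeds ``spec.seed + i``; bed-wide noise
    is added once at the end.
    """
    n = spec.n_mice
    rows = 1 if n <= 3 else 2
    cols = int(np.ceil(n / rows))
    nz, ny, nx = spec.grid_shape
    bed_shape = (nz, rows * ny, cols * nx)
    bed = np.full(bed_shape, spec.background_hu, dtype=np.float64)
    masks: list[Mask] = []
    quiet = replace(spec, noise_sd_hu=0.0)
    for i in range(n):
        r, c = divmod(i, cols)
        vol, mask = generate_mouse(quiet, seed=spec.seed + i)
        sl = (slice(None), slice(r * ny, (r + 1) * ny), slice(c * nx, (c + 1) * nx))
        bed[sl] = vol.data
        full = np.zeros(bed_shape, dtype=np.uint8)
        full[sl] = mask.data
        masks.append(Mask(full, spec.spacing_mm, (0.0, 0.0, 0.0)))
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        bed += rng.normal(0.0, spec.noise_sd_hu, size=bed.shape)
    return Volume(bed, spec.spacing_mm, (0.0, 0.0, 0.0), "HU"), masks
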
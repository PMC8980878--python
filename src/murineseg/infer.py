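"""Per-slice inference, fold-ensemble median fusion and binarization.

Inference mirrors training geometry: each axial section of a normalized
volume is padded, pushed through the network, un-padded and restacked into a
probability map on the input grid.  The five per-fold maps are fused
voxelwise by the median, and the fused map is binarized either at a hard 0.5
or with an Otsu threshold computed over the whole volume.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError
from .imageio import Mask, Volume
from .model import FoldEnsemble, UNetConfig
from .preprocess import SliceStack, extract_axial_slices, restack

__all__ = [
    "predict_volume",
    "predict_ensemble",
    "ensemble_median",
    "otsu_threshold",
    "binarize",
]


def predict_volume(
    weights: dict[str, np.ndarray], v: Volume, uc: UNetConfig, batch_size: int = 32
) -> Volume:
    """Run one weight set over every axial section of a normalized volume.

    Returns a probability map on exactly the input grid (padding applied for
    the forward pass is stripped again).
    """
    if v.data.min() < -1e-6 or v.data.max() > 1 + 1e-6:
        raise ValueError("predict_volume expects a volume normalized to [0, 1]")
    net = uc.build()
    net.check_params(weights)
    stack = extract_axial_slices(
        Volume(v.data, v.spacing, v.origin, "normalized"), pad_multiple=uc.pad_multiple
    )
    prob = net.predict_proba(weights, stack.slices[:, None].astype(np.float32), batch_size)[:, 0]
    out = restack(
        SliceStack(np.clip(prob.astype(np.float64), 0.0, 1.0), stack.pad, v.spacing, v.origin),
        intensity_kind="probability",
    )
    return out


def ensemble_median(maps: list[Volume]) -> Volume:
    """Voxelwise median across probability maps (the fold-fusion rule).

    For an even number of maps the arithmetic mean of the two central values
    is used.  Idempotent on identical maps and invariant to map order.
    """
    if not maps:
        raise ValueError("ensemble_median needs at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise GridMismatchError("probability maps are not on a common grid")
    med = np.median(np.stack([m.data for m in maps]), axis=0)
    return Volume(med, first.spacing, first.origin, "probability")


def predict_ensemble(ens: FoldEnsemble, v: Volume, batch_size: int = 32) -> Volume:
    """Median-fused probability map from every fold of an ensemble."""
    maps = [predict_volume(w, v, ens.unet_config, batch_size) for w in ens.weights]
    return ensemble_median(maps)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold over an ``n_bins`` histogram of [0, 1].

    Returns the interior bin edge maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2``; ties break toward the lower edge.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0 or values.min() == values.max():
        raise DegenerateInputError("otsu_threshold needs at least two distinct values")
    if values.min() < 0 or values.max() > 1:
        raise ValueError("otsu_threshold expects values in [0, 1]")
    hist, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)[:-1]                       # class weights at each interior edge
    w1 = 1.0 - w0
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_tot = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu[:-1] / w0
        mu1 = (mu_tot - mu[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=0.0)
    k = int(np.argmax(sigma_b))                  # first maximum = lowest edge
    return float(edges[k + 1])


def binarize(
    p: Volume,
    method: str = "otsu",
    hard_value: float = 0.5,
    n_bins: int = 256,
    largest_component: bool = False,
) -> Mask:
    """Turn a probability map into a binary lung mask.

    ``method='otsu'`` computes the threshold per volume over all voxels;
    ``method='hard'`` uses ``hard_value``.  The comparison is ``>=`` at the
    threshold.  Optional largest-component filtering is off by default.
    """
    if p.intensity_kind != "probability":
        raise ValueError("binarize expects a probability map")
    if method == "otsu":
        thr = otsu_threshold(p.data, n_bins)
    elif method == "hard":
        thr = float(hard_value)
    else:
        raise ValueError(f"method must be 'otsu' or 'hard', got {method!r}")
    sel = p.data >= thr
    if largest_component and sel.any():
        labels, n = ndimage.label(sel, structure=np.ones((3, 3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(sel, labels, index=np.arange(1, n + 1))
            sel = labels == (int(np.argmax(sizes)) + 1)
    return Mask(sel.astype(np.uint8), p.spacing, p.origin)
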
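"""Composite training objective with edge supervision.

The total loss is a weighted sum of three terms,

    L_total = α·L_BCE(G, P) + β·L_Dice(G, P) + γ·L_Ohem(G_edge, P_edge),

with weights defaulting to α=0.5, β=0.3, γ=0.2.  The segmentation terms are
pixel-mean binary cross-entropy and the soft Dice loss
``1 − (2·Σyp + ε) / (Σy + Σp + ε)``; the edge term supervises a Canny-derived
boundary map and keeps only the hardest fraction of pixels (online hard
example mining), countering the extreme foreground/background imbalance of
thin edge bands.

All losses accept either NumPy arrays or autodiff tensors and return a
scalar :class:`~axunet.autodiff.Tensor`, so they serve both as training
objectives and as plain evaluation functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossWeights",
    "LossConfig",
    "bce_loss",
    "dice_loss",
    "canny_edge_mask",
    "ohem_bce",
    "total_loss",
]

_P_FLOOR = 1e-7


@dataclass
class LossWeights:
    alpha: float = 0.5   # binary cross-entropy on the segmentation map
    beta: float = 0.3    # Dice loss on the segmentation map
    gamma: float = 0.2   # hard-example-mined BCE on the edge map

    def __post_init__(self):
        for v in (self.alpha, self.beta, self.gamma):
            if not np.isfinite(v) or v < 0:
                raise ValueError("loss weights must be finite and nonnegative")


@dataclass
class LossConfig:
    dice_epsilon: float = 1.0
    dice_as_printed: bool = False   # drop the factor 2 in the Dice numerator
    reduction: str = "mean"          # "mean" or "sum" over pixels
    ohem_keep_fraction: float = 0.25
    ohem_min_kept: int = 256
    canny_low: float = 10.0          # hysteresis thresholds on a 0–255 scale
    canny_high: float = 100.0
    canny_sigma: float = 1.5         # pre-smoothing width, px
    edge_dilation: int = 1           # px of edge-band thickening

    def __post_init__(self):
        if not (0.0 < self.ohem_keep_fraction <= 1.0):
            raise ValueError("ohem_keep_fraction must lie in (0, 1]")
        if self.canny_low >= self.canny_high:
            raise ValueError("canny_low must be below canny_high")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")


def _check_shapes(p, y):
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: prediction {p.shape} vs target {y.shape}")


def _pixel_bce(p: Tensor, y: Tensor) -> Tensor:
    p = ad.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return -(y * p.log() + (1.0 - y) * (1.0 - p).log())


def bce_loss(p, y, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy between probabilities ``p`` and binary ``y``."""
    p, y = ad.astensor(p), ad.astensor(y)
    _check_shapes(p, y)
    per_pixel = _pixel_bce(p, y)
    return per_pixel.mean() if reduction == "mean" else per_pixel.sum()


def dice_loss(p, y, eps: float = 1.0, as_printed: bool = False) -> Tensor:
    """Soft Dice loss, 0 at a perfect prediction (``as_printed`` drops the
    factor 2 from the numerator, in which case perfection scores 0.5)."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    p, y = ad.astensor(p), ad.astensor(y)
    _check_shapes(p, y)
    inter = (p * y).sum()
    total = p.sum() + y.sum()
    num = inter + eps if as_printed else inter * 2.0 + eps
    return 1.0 - num / (total + eps)


def canny_edge_mask(mask: np.ndarray, cfg: LossConfig | None = None) -> np.ndarray:
    """Binary edge band derived from a binary mask by Canny detection.

    The mask is scaled to 0–255 before hysteresis thresholding; the
    resulting contour is thickened by ``cfg.edge_dilation`` so the
    supervision band has body.  The smoothing width ``canny_sigma`` is set
    so the contour of a filled shape stays one pixel wide (its pixel count
    tracks the true perimeter).
    """
    cfg = cfg or LossConfig()
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("edge extraction expects a binary {0,1} mask")
    edges = feature.canny(
        mask.astype(np.float64) * 255.0,
        sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low,
        high_threshold=cfg.canny_high,
    )
    if cfg.edge_dilation > 0:
        edges = ndimage.binary_dilation(edges, iterations=cfg.edge_dilation)
    return edges.astype(np.uint8)


def ohem_bce(p_edge, g_edge, cfg: LossConfig | None = None) -> Tensor:
    """BCE over the hardest pixels only (online hard example mining).

    Per image, pixels are ranked by their BCE value and the top
    ``max(ohem_min_kept, ceil(keep_fraction · n))`` are averaged.  Ties at
    the cutoff are broken by pixel index (stable sort), so the result is
    deterministic.
    """
    cfg = cfg or LossConfig()
    p_edge, g_edge = ad.astensor(p_edge), ad.astensor(g_edge)
    _check_shapes(p_edge, g_edge)
    if p_edge.data.size == 0:
        raise ValueError("empty input")
    # flatten to [images, pixels]; a bare 2-D map counts as one image
    if p_edge.ndim <= 2:
        shape = (1, p_edge.data.size)
    else:
        shape = (p_edge.shape[0], int(np.prod(p_edge.shape[1:])))
    per_pixel = _pixel_bce(p_edge, g_edge).reshape(shape)
    n = shape[1]
    keep = min(n, max(int(cfg.ohem_min_kept), int(np.ceil(cfg.ohem_keep_fraction * n))))
    # selection is data-dependent bookkeeping: rank on detached values
    order = np.argsort(-per_pixel.data, axis=1, kind="stable")[:, :keep]
    rows = np.repeat(np.arange(shape[0])[:, None], keep, axis=1)
    return per_pixel[rows, order].mean()


def total_loss(seg_p, seg_y, edge_p, edge_y,
               weights: LossWeights | None = None,
               cfg: LossConfig | None = None) -> tuple[Tensor, dict]:
    """Weighted objective; returns (total, per-term breakdown)."""
    weights = weights or LossWeights()
    cfg = cfg or LossConfig()
    bce = bce_loss(seg_p, seg_y, reduction=cfg.reduction)
    dice = dice_loss(seg_p, seg_y, eps=cfg.dice_epsilon,
                     as_printed=cfg.dice_as_printed)
    ohem = ohem_bce(edge_p, edge_y, cfg)
    total = weights.alpha * bce + weights.beta * dice + weights.gamma * ohem
    parts = {"bce": bce.item(), "dice": dice.item(), "ohem": ohem.item(),
             "total": total.item()}
    return total, parts
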
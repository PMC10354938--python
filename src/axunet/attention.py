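"""Axial self-attention with a distance weight mask, and transformer blocks.

The encoder's attention deviates from dense multi-head self-attention in two
ways.  First, queries and keys are computed from *axial profiles*: the token
grid is mean-pooled along the width axis to give one profile per row, and
along the height axis to give one per column, so the Q·K correlation stage
costs O((H² + W²)·C) instead of O((H·W)²·C).  Second, each axial correlation
matrix is multiplied elementwise by a distance weight mask that suppresses
short-range token pairs — those are already well modelled by the parallel
convolutional branch — while leaving the diagonal and long-range pairs at
weight 1:

    mask[i, j] = 1                      if i == j
               = k·|i−j|² − k·a² + 1    if 0 < |i−j| < a
               = 1                      if |i−j| ≥ a

with curvature ``k`` (default 0.5) and cutoff ``a`` (default half the axis
length).  The two masked axial correlation matrices are recombined into a
joint logit for every token pair — logit[(i,j),(i′,j′)] is the product of
the row-pair and column-pair entries — before the usual softmax over keys
and multiplication with V, where V is a linear map of the full (unpooled)
token sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "AttentionConfig",
    "build_distance_mask",
    "axial_profiles",
    "axial_correlations",
    "assemble_masked_logits",
    "MaskedAxialAttention",
    "MultiHeadSelfAttention",
    "TransformerBlock",
]


@dataclass
class AttentionConfig:
    """Hyperparameters of one attention/transformer block.

    embed_dim       channels per token; must be divisible by ``heads``
    heads           number of attention heads
    mlp_ratio       hidden width of the MLP as a multiple of embed_dim
    mask_k          curvature of the distance mask
    mask_a_fraction cutoff distance as a fraction of the axis length
    clamp_mask      clamp mask values at 0 (guards the sign flip when a
                    correlation entry is negative); off by default
    """

    embed_dim: int = 64
    heads: int = 4
    mlp_ratio: float = 4.0
    mask_k: float = 0.5
    mask_a_fraction: float = 0.5
    clamp_mask: bool = False

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")


def build_distance_mask(n: int, k: float = 0.5, a: float | None = None,
                        clamp: bool = False) -> np.ndarray:
    """Distance weight mask for one axis of length ``n``.

    ``a`` defaults to half the axis length (rounded up).  Entries depend only
    on the index distance d = |i−j|: 1 on the diagonal and beyond the cutoff,
    and the parabola ``k·d² − k·a² + 1`` in between, which dips below 1 near
    the diagonal and rises back to 1 at d = a.
    """
    if n < 1:
        raise ValueError("mask size must be positive")
    if a is None:
        a = int(np.ceil(0.5 * n))
    if a < 0:
        raise ValueError("cutoff distance must be nonnegative")
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(np.float32)
    mask = k * d**2 - k * float(a) ** 2 + 1.0
    mask = np.where((d == 0) | (d >= a), 1.0, mask).astype(np.float32)
    if clamp:
        mask = np.maximum(mask, 0.0)
    return mask


def axial_profiles(tokens: Tensor) -> tuple[Tensor, Tensor]:
    """Mean-pool a [B,C,H,W] token grid into per-row and per-column profiles.

    Returns ``f_H`` [B,H,C] (mean over the width axis) and ``f_W`` [B,W,C]
    (mean over the height axis).
    """
    tokens = ad.astensor(tokens)
    if tokens.ndim != 4:
        raise ValueError("token grid must be [B,C,H,W]")
    f_h = tokens.mean(axis=3).transpose((0, 2, 1))  # [B,H,C]
    f_w = tokens.mean(axis=2).transpose((0, 2, 1))  # [B,W,C]
    return f_h, f_w


def _split_heads(x: Tensor, heads: int) -> Tensor:
    """[B,N,C] -> [B,heads,N,C/heads]."""
    B, N, C = x.shape
    return x.reshape((B, N, heads, C // heads)).transpose((0, 2, 1, 3))


def axial_correlations(f_h: Tensor, f_w: Tensor, heads: int,
                       q_proj: nn.Linear, k_proj: nn.Linear) -> tuple[Tensor, Tensor]:
    """Per-head Q·Kᵀ correlation matrices along each axis.

    The same learned query/key maps are applied to both axial profiles;
    returns ``corr_H`` [B,heads,H,H] and ``corr_W`` [B,heads,W,W].
    """
    if f_h.shape[-1] != q_proj.weight.shape[0]:
        raise ValueError("profile channels do not match projection width")
    corrs = []
    for f in (f_h, f_w):
        q = _split_heads(q_proj(f), heads)
        k = _split_heads(k_proj(f), heads)
        corrs.append(ad.matmul(q, k.transpose((0, 1, 3, 2))))
    return corrs[0], corrs[1]


def assemble_masked_logits(corr_h: Tensor, corr_w: Tensor,
                           mask_h: np.ndarray, mask_w: np.ndarray) -> Tensor:
    """Recombine masked axial correlations into joint token-pair logits.

    The logit between tokens (i, j) and (i′, j′) is the product
    ``(mask_h ∘ corr_h)[i, i′] · (mask_w ∘ corr_w)[j, j′]`` (elementwise
    mask multiplication); tokens are flattened row-major, so the result is
    [B, heads, H·W, H·W].
    """
    B, h, H, H2 = corr_h.shape
    _, _, W, W2 = corr_w.shape
    if mask_h.shape != (H, H2) or mask_w.shape != (W, W2):
        raise ValueError("mask extents do not match correlation matrices")
    mc_h = corr_h * Tensor(mask_h.astype(corr_h.dtype))
    mc_w = corr_w * Tensor(mask_w.astype(corr_w.dtype))
    # outer (Kronecker) combination over the two axes
    joint = mc_h.reshape((B, h, H, 1, H, 1)) * mc_w.reshape((B, h, 1, W, 1, W))
    return joint.reshape((B, h, H * W, H * W))


class MaskedAxialAttention(nn.Module):
    """Multi-head attention with axial Q/K pooling and the distance mask.

    V is computed from the full token sequence so the output keeps full
    spatial rank; only the Q/K path is pooled.
    """

    def __init__(self, cfg: AttentionConfig):
        super().__init__()
        C = cfg.embed_dim
        self.cfg = cfg
        self.q_proj = nn.Linear(C, C)
        self.k_proj = nn.Linear(C, C)
        self.v_proj = nn.Linear(C, C)
        self.out_proj = nn.Linear(C, C)

    def forward(self, tokens: Tensor) -> Tensor:
        cfg = self.cfg
        B, C, H, W = tokens.shape
        if C != cfg.embed_dim:
            raise ValueError(f"expected {cfg.embed_dim} channels, got {C}")
        a_h = int(np.ceil(cfg.mask_a_fraction * H))
        a_w = int(np.ceil(cfg.mask_a_fraction * W))
        mask_h = build_distance_mask(H, cfg.mask_k, a_h, clamp=cfg.clamp_mask)
        mask_w = build_distance_mask(W, cfg.mask_k, a_w, clamp=cfg.clamp_mask)

        f_h, f_w = axial_profiles(tokens)
        corr_h, corr_w = axial_correlations(f_h, f_w, cfg.heads,
                                            self.q_proj, self.k_proj)
        logits = assemble_masked_logits(corr_h, corr_w, mask_h, mask_w)

        head_dim = C // cfg.heads
        weights = ad.softmax(logits * (1.0 / np.sqrt(head_dim)), axis=-1)

        seq = tokens.reshape((B, C, H * W)).transpose((0, 2, 1))  # [B,N,C]
        v = _split_heads(self.v_proj(seq), cfg.heads)  # [B,h,N,dh]
        out = ad.matmul(weights, v)  # [B,h,N,dh]
        out = out.transpose((0, 2, 1, 3)).reshape((B, H * W, C))
        out = self.out_proj(out)
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite activations in masked axial attention")
        return out.transpose((0, 2, 1)).reshape((B, C, H, W))


class MultiHeadSelfAttention(nn.Module):
    """Dense multi-head self-attention over a [B,N,C] token sequence."""

    def __init__(self, embed_dim: int, heads: int):
        super().__init__()
        if embed_dim % heads:
            raise ValueError("embed_dim must be divisible by heads")
        self.heads = heads
        self.q_proj = nn.Linear(embed_dim, embed_dim)
        self.k_proj = nn.Linear(embed_dim, embed_dim)
        self.v_proj = nn.Linear(embed_dim, embed_dim)
        self.out_proj = nn.Linear(embed_dim, embed_dim)

    def forward(self, seq: Tensor) -> Tensor:
        B, N, C = seq.shape
        q = _split_heads(self.q_proj(seq), self.heads)
        k = _split_heads(self.k_proj(seq), self.heads)
        v = _split_heads(self.v_proj(seq), self.heads)
        logits = ad.matmul(q, k.transpose((0, 1, 3, 2)))
        weights = ad.softmax(logits * (1.0 / np.sqrt(C // self.heads)), axis=-1)
        out = ad.matmul(weights, v).transpose((0, 2, 1, 3)).reshape((B, N, C))
        return self.out_proj(out)


class _Mlp(nn.Module):
    def __init__(self, dim: int, ratio: float):
        super().__init__()
        hidden = max(1, int(round(dim * ratio)))
        self.fc1 = nn.Linear(dim, hidden)
        self.fc2 = nn.Linear(hidden, dim)

    def forward(self, x):
        return self.fc2(ad.gelu(self.fc1(x)))


class TransformerBlock(nn.Module):
    """Pre-norm transformer block: z′ = MSA(LN(z)) + z; z″ = MLP(LN(z′)) + z′.

    ``attention_kind`` selects dense attention over the flattened token
    sequence (``"standard"``) or the masked axial variant (``"masked_axial"``).
    Operates on [B,C,H,W] token grids; layer norm runs over the channel axis
    of each token.
    """

    def __init__(self, cfg: AttentionConfig, attention_kind: str = "standard"):
        super().__init__()
        if attention_kind not in ("standard", "masked_axial"):
            raise ValueError(f"unknown attention_kind {attention_kind!r}")
        self.kind = attention_kind
        self.cfg = cfg
        self.norm1 = nn.LayerNorm(cfg.embed_dim)
        self.norm2 = nn.LayerNorm(cfg.embed_dim)
        if attention_kind == "standard":
            self.attn = MultiHeadSelfAttention(cfg.embed_dim, cfg.heads)
        else:
            self.attn = MaskedAxialAttention(cfg)
        self.mlp = _Mlp(cfg.embed_dim, cfg.mlp_ratio)

    def forward(self, tokens: Tensor) -> Tensor:
        B, C, H, W = tokens.shape
        seq = tokens.reshape((B, C, H * W)).transpose((0, 2, 1))  # [B,N,C]
        h = self.norm1(seq)
        if self.kind == "standard":
            attn_out = self.attn(h)
        else:
            grid = h.transpose((0, 2, 1)).reshape((B, C, H, W))
            attn_out = self.attn(grid).reshape((B, C, H * W)).transpose((0, 2, 1))
        seq = attn_out + seq
        seq = self.mlp(self.norm2(seq)) + seq
        return seq.transpose((0, 2, 1)).reshape((B, C, H, W))
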
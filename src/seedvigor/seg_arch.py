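"""Cost accounting and forward contracts for lightweight detector blocks.

Three building blocks commonly used to slim down and strengthen a
convolutional instance-segmentation backbone are provided at the level that
is verifiable without any training:

* **Ghost convolution** — exact multiply/parameter accounting.  A standard
  convolution mapping C input channels to M output channels with a k x k
  kernel costs ``M * C * k^2`` multiplies per output position.  A ghost
  module computes only ``M' = M / s`` intrinsic maps by standard
  convolution and expands each into ``s`` maps with cheap depthwise d x d
  operations, costing ``M' * C * k^2 + M' * (s - 1) * d^2`` — roughly 1/s
  of the standard cost.  Bias terms are excluded throughout (the parameter
  count per position then equals the multiply count).
* **Squeeze-and-Excitation** — channel attention: global average pooling
  (squeeze), a two-layer bottleneck with ReLU then sigmoid (excitation),
  and per-channel rescaling (scale).
* **Windowed multi-head self-attention and patch merging** — attention
  computed independently inside non-overlapping windows (the shifted
  variant offsets the window grid by half a window via a cyclic shift);
  patch merging concatenates each 2x2 patch neighborhood (losing no
  values) and linearly projects 4C channels down to 2C.

Blocks are standalone NumPy forward passes with explicit weights; they are
contracts for shapes and behavior, not a trainable network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, NamedTuple, Optional, Tuple

import numpy as np


@dataclass(frozen=True)
class ConvCostSpec:
    """Channel/kernel/ghost parameters for the cost formulas."""

    C: int  # input channels
    M: int  # output channels
    k: int  # kernel size
    s: int = 2  # ghost feature multiplier
    d: int = 3  # cheap-operation kernel size

    def __post_init__(self) -> None:
        for name in ("C", "M", "k", "s", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.M % self.s:
            raise ValueError(f"ghost multiplier s={self.s} must divide M={self.M}")


class GhostCost(NamedTuple):
    intrinsic: int
    cheap: int
    total: int


def conv_cost(spec: ConvCostSpec) -> int:
    """Multiplies per output position of a standard convolution: M*C*k^2."""
    return spec.M * spec.C * spec.k**2


def ghost_cost(spec: ConvCostSpec) -> GhostCost:
    """Ghost-module multiplies: intrinsic (M/s)*C*k^2 plus cheap (M/s)*(s-1)*d^2."""
    m_prime = spec.M // spec.s
    intrinsic = m_prime * spec.C * spec.k**2
    cheap = m_prime * (spec.s - 1) * spec.d**2
    return GhostCost(intrinsic=intrinsic, cheap=cheap, total=intrinsic + cheap)


def reduction_percent(spec: ConvCostSpec) -> float:
    """Percentage reduction of the ghost module vs the standard convolution."""
    return 100.0 * (1.0 - ghost_cost(spec).total / conv_cost(spec))


def conv_params(spec: ConvCostSpec) -> int:
    """Weight count of the standard convolution (no bias)."""
    return spec.M * spec.C * spec.k**2


def ghost_params(spec: ConvCostSpec) -> int:
    """Weight count of the ghost module (no bias): intrinsic kernels plus one
    depthwise d x d kernel per cheap map."""
    m_prime = spec.M // spec.s
    return m_prime * spec.C * spec.k**2 + m_prime * (spec.s - 1) * spec.d**2


def cost_report(spec: ConvCostSpec) -> dict:
    """Side-by-side conv vs ghost accounting for one layer."""
    g = ghost_cost(spec)
    return {
        "spec": {"C": spec.C, "M": spec.M, "k": spec.k, "s": spec.s, "d": spec.d},
        "conv_multiplies": conv_cost(spec),
        "ghost_intrinsic": g.intrinsic,
        "ghost_cheap": g.cheap,
        "ghost_multiplies": g.total,
        "conv_params": conv_params(spec),
        "ghost_params": ghost_params(spec),
        "reduction_percent": reduction_percent(spec),
    }


def format_cost_report(report: dict) -> str:
    s = report["spec"]
    lines = [
        f"layer: C={s['C']} M={s['M']} k={s['k']} | ghost s={s['s']} d={s['d']}",
        f"{'':24s}{'multiplies/pos':>16s}{'weights':>12s}",
        f"{'standard conv':24s}{report['conv_multiplies']:>16,}{report['conv_params']:>12,}",
        f"{'ghost intrinsic':24s}{report['ghost_intrinsic']:>16,}",
        f"{'ghost cheap (depthwise)':24s}{report['ghost_cheap']:>16,}",
        f"{'ghost total':24s}{report['ghost_multiplies']:>16,}{report['ghost_params']:>12,}",
        f"reduction: {report['reduction_percent']:.1f}% (bias and norm parameters excluded)",
    ]
    return "\n".join(lines)


# ---- SE block ----------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def se_forward(
    x: np.ndarray,
    reduction: int = 4,
    w1: Optional[np.ndarray] = None,
    w2: Optional[np.ndarray] = None,
    return_weights: bool = False,
):
    """Squeeze-and-Excitation forward pass on an (H, W, C) feature block.

    squeeze: per-channel global average pool; excitation:
    ``sigmoid(relu(z @ w1) @ w2)`` (bias-free bottleneck of width
    C/reduction); scale: per-channel multiply.  Output shape equals input
    shape and channel weights lie in (0, 1).  Weights default to a fixed
    seeded Gaussian initialization.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected an (H, W, C) feature block")
    c = x.shape[2]
    if reduction < 1 or reduction > c:
        raise ValueError(f"reduction ratio {reduction} must be in [1, C={c}]")
    if c % reduction:
        raise ValueError(f"C={c} must be divisible by reduction={reduction}")
    hidden = c // reduction
    rng = np.random.default_rng(0)
    if w1 is None:
        w1 = rng.normal(0.0, 1.0 / np.sqrt(c), size=(c, hidden))
    if w2 is None:
        w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, c))
    z = x.mean(axis=(0, 1))  # squeeze
    weights = _sigmoid(np.maximum(z @ w1, 0.0) @ w2)  # excitation
    out = se_scale(x, weights)
    if return_weights:
        return out, weights
    return out


def se_scale(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scale step: per-channel reweighting (identity when weights are all 1)."""
    return np.asarray(x, dtype=float) * np.asarray(weights, dtype=float)[None, None, :]


# ---- windowed attention and patch merging ------------------------------------


def _softmax(a: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(a - a.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def window_attention_forward(
    x: np.ndarray,
    window: int,
    shifted: bool = False,
    wq: Optional[np.ndarray] = None,
    wk: Optional[np.ndarray] = None,
    wv: Optional[np.ndarray] = None,
    return_attention: bool = False,
):
    """Single-head self-attention computed independently in each window.

    The (H, W, C) block is zero-padded to a multiple of ``window``,
    partitioned into non-overlapping windows, and each window's tokens
    attend only to each other: ``softmax(Q K^T / sqrt(C)) V``.  Projection
    matrices default to the identity, so a 1x1 window returns the value
    projection of the input unchanged.  ``shifted`` offsets the window grid
    by half a window through a cyclic shift (wrapped tokens attend
    together; no attention masking is applied).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("expected an (H, W, C) feature block")
    h, w, c = x.shape
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > h or window > w:
        raise ValueError(f"window {window} larger than the {h}x{w} feature map")
    pad_h = (-h) % window
    pad_w = (-w) % window
    eye = np.eye(c)
    wq = eye if wq is None else np.asarray(wq, dtype=float)
    wk = eye if wk is None else np.asarray(wk, dtype=float)
    wv = eye if wv is None else np.asarray(wv, dtype=float)

    shift = window // 2 if shifted else 0
    xp = np.roll(x, (-shift, -shift), axis=(0, 1)) if shift else x
    xp = np.pad(xp, ((0, pad_h), (0, pad_w), (0, 0)))
    hp, wp = xp.shape[:2]

    out = np.empty_like(xp)
    attentions: List[np.ndarray] = []
    scale = 1.0 / np.sqrt(c)
    for r0 in range(0, hp, window):
        for c0 in range(0, wp, window):
            tokens = xp[r0 : r0 + window, c0 : c0 + window].reshape(-1, c)
            q, k_, v = tokens @ wq, tokens @ wk, tokens @ wv
            attn = _softmax(q @ k_.T * scale, axis=-1)
            attentions.append(attn)
            out[r0 : r0 + window, c0 : c0 + window] = (attn @ v).reshape(
                window, window, c
            )
    out = out[:h, :w]
    if shift:
        out = np.roll(out, (shift, shift), axis=(0, 1))
    if return_attention:
        return out, attentions
    return out


def merge_patches(x: np.ndarray) -> np.ndarray:
    """Rearrange (H, W, C) into (H/2, W/2, 4C) by concatenating each 2x2
    neighborhood's channels — a pure reshuffle that loses no values."""
    x = np.asarray(x, dtype=float)
    h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("patch merging requires even H and W")
    return np.concatenate(
        [x[0::2, 0::2], x[0::2, 1::2], x[1::2, 0::2], x[1::2, 1::2]], axis=-1
    )


def patch_merge(x: np.ndarray, weight: Optional[np.ndarray] = None) -> np.ndarray:
    """Patch merging: halve spatial resolution, double channels.

    Concatenates 2x2 neighborhoods to 4C channels then applies a linear
    projection to 2C (default: fixed seeded Gaussian weight).
    """
    merged = merge_patches(x)
    c4 = merged.shape[-1]
    if weight is None:
        weight = np.random.default_rng(0).normal(0.0, 1.0 / np.sqrt(c4), size=(c4, c4 // 2))
    weight = np.asarray(weight, dtype=float)
    if weight.shape != (c4, c4 // 2):
        raise ValueError(f"projection weight must be {(c4, c4 // 2)}, got {weight.shape}")
    return merged @ weight
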
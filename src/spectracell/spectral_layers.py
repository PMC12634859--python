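"""LSBDU downsampling and depthwise separable convolution, functionally.

Feature maps here follow the (H, W, C) convention, with an optional leading
batch axis; the training engine's layers in :mod:`spectracell._nn` operate
on the same math in NCHW layout.

The LSBDU replaces pooling: per channel c the map is convolved with a
learnable low-pass kernel φ_c and a high-pass kernel ψ_c (same padding,
edge-mirrored so constants pass the low branch exactly and vanish in the
high branch), both decimated by stride 2 keeping even-indexed rows/columns,
and fused as

    Y_c = σ(a_c) · L̂_c + σ(b_c) · Ĥ_c

with per-channel trainable scalars a_c, b_c squashed through a sigmoid so
the fusion weights stay strictly inside (0, 1). Kernels are initialized
from the Bior2.2 taps and a = b = 0, making both gates 0.5 at the start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import filterbank
from ._nn import LSBDULayer, sigmoid, _dw_conv3x3

__all__ = ["LSBDUParams", "DSCParams", "lsbdu_forward", "lsbdu_attention",
           "dsc_forward", "init_lsbdu"]


@dataclass
class LSBDUParams:
    """Per-channel spectral filter pairs plus raw fusion scalars.

    ``phi``/``psi`` have shape (C, 3, 3); ``a``/``b`` are length-C vectors of
    unconstrained reals whose sigmoids are the fusion weights α, β.
    """

    phi: np.ndarray
    psi: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.psi = np.asarray(self.psi, dtype=np.float64)
        self.a = np.atleast_1d(np.asarray(self.a, dtype=np.float64))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        c = self.phi.shape[0]
        if self.phi.shape != (c, 3, 3) or self.psi.shape != (c, 3, 3):
            raise ValueError("phi/psi must have shape (C, 3, 3)")
        if self.a.shape != (c,) or self.b.shape != (c,):
            raise ValueError("a/b must be length-C vectors")

    @property
    def channels(self) -> int:
        return self.phi.shape[0]

    @property
    def alpha(self) -> np.ndarray:
        return sigmoid(self.a)

    @property
    def beta(self) -> np.ndarray:
        return sigmoid(self.b)


@dataclass
class DSCParams:
    """Depthwise separable convolution parameters.

    ``depthwise``: (M, DK, DK) per-input-channel spatial kernels;
    ``pointwise``: (M, N) 1×1 mixing weights; optional length-N ``bias``.
    """

    depthwise: np.ndarray
    pointwise: np.ndarray
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depthwise = np.asarray(self.depthwise, dtype=np.float64)
        self.pointwise = np.asarray(self.pointwise, dtype=np.float64)
        if self.depthwise.ndim != 3 or self.depthwise.shape[1] != self.depthwise.shape[2]:
            raise ValueError("depthwise must be (M, DK, DK)")
        if self.pointwise.ndim != 2 or self.pointwise.shape[0] != self.depthwise.shape[0]:
            raise ValueError("pointwise input dim must equal depthwise channel count")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.pointwise.shape[1],):
                raise ValueError("bias length must equal output channel count")


def _to_nchw(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 3:
        return x.transpose(2, 0, 1)[None], True
    if x.ndim == 4:
        return x.transpose(0, 3, 1, 2), False
    raise ValueError("feature map must be (H, W, C) or (N, H, W, C)")


def _from_nchw(x: np.ndarray, squeeze: bool) -> np.ndarray:
    out = x.transpose(0, 2, 3, 1)
    return out[0] if squeeze else out


def _layer_from(p: LSBDUParams) -> LSBDULayer:
    layer = LSBDULayer(p.channels, p.phi[0], p.psi[0])
    layer.params["phi"] = p.phi.astype(np.float64)
    layer.params["psi"] = p.psi.astype(np.float64)
    layer.params["a"] = p.a.astype(np.float64)
    layer.params["b"] = p.b.astype(np.float64)
    return layer


def lsbdu_forward(x: np.ndarray, p: LSBDUParams) -> np.ndarray:
    """Spectral downsampling: output shape (⌈H/2⌉, ⌈W/2⌉, C).

    Raises on channel mismatch or spatial dims < 2.
    """
    xn, squeeze = _to_nchw(x)
    if xn.shape[1] != p.channels:
        raise ValueError(f"input has {xn.shape[1]} channels, params expect {p.channels}")
    layer = _layer_from(p)
    return _from_nchw(layer.forward(xn, train=False), squeeze)


def lsbdu_attention(x: np.ndarray, p: LSBDUParams) -> np.ndarray:
    """Spectral attention: channel-mean |β_c·Ĥ_c| rescaled to [0, 1].

    A constant input is annihilated by the zero-sum high-pass and returns an
    all-zero map. Output shape (⌈H/2⌉, ⌈W/2⌉) (batched if input is batched).
    """
    xn, squeeze = _to_nchw(x)
    if xn.shape[1] != p.channels:
        raise ValueError(f"input has {xn.shape[1]} channels, params expect {p.channels}")
    if xn.shape[2] < 2 or xn.shape[3] < 2:
        raise ValueError("spatial dims must be >= 2 for downsampling")
    att = _layer_from(p).attention(xn)
    return att[0] if squeeze else att


def dsc_forward(x: np.ndarray, p: DSCParams) -> np.ndarray:
    """Depthwise spatial filtering then 1×1 pointwise mixing, stride 1, same padding."""
    xn, squeeze = _to_nchw(x)
    m, dk, _ = p.depthwise.shape
    if xn.shape[1] != m:
        raise ValueError(f"input has {xn.shape[1]} channels, params expect {m}")
    if dk == 3:
        mid, _ = _dw_conv3x3(xn, p.depthwise, stride=1)
    else:
        mid = _dw_conv_any(xn, p.depthwise)
    out = np.einsum("mn,bmhw->bnhw", p.pointwise, mid, optimize=True)
    if p.bias is not None:
        out += p.bias[None, :, None, None]
    return _from_nchw(out, squeeze)


def _dw_conv_any(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Depthwise cross-correlation for odd kernel sizes other than 3."""
    m, dk, _ = w.shape
    pad = dk // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="symmetric")
    n, c, h, wd = x.shape
    out = np.zeros_like(x)
    for i in range(dk):
        for j in range(dk):
            out += w[:, i, j][None, :, None, None] * xp[:, :, i:i + h, j:j + wd]
    return out


def init_lsbdu(channels: int) -> LSBDUParams:
    """Bior2.2-seeded parameters: identical φ/ψ per channel, a = b = 0."""
    if channels < 1:
        raise ValueError("channel count must be positive")
    kern = filterbank.make_kernels(filterbank.bior22_taps())
    phi = np.broadcast_to(kern.phi, (channels, 3, 3)).copy()
    psi = np.broadcast_to(kern.psi, (channels, 3, 3)).copy()
    return LSBDUParams(phi=phi, psi=psi, a=np.zeros(channels), b=np.zeros(channels))
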
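"""Compact NumPy neural-network engine used by the spectral-aware CNN.

Layers operate on NCHW float32 tensors and implement analytic forward and
backward passes; the model class chains them, caches activations, and can
return the gradient at any named layer output (used by Grad-CAM).

Convolutions are 3×3 with "same" padding, placed so that a stride-2
convolution is identical to the stride-1 convolution followed by decimation
keeping even-indexed (0-based) rows and columns; output spatial size is
ceil(H/2). All convolutions pad with the edge mirror (scipy's
``boundary='symm'``): a spatially constant input stays constant through
every layer, the LSBDU low-pass branch has exact DC gain 1, and its
high-pass branch annihilates constants all the way to the image border.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Layer", "Conv3x3", "Pointwise", "Depthwise3x3", "BatchNorm2d", "ReLU",
    "MaxPool2x2", "GlobalAvgPool", "Linear", "LSBDULayer", "Model", "AdamW",
    "sigmoid", "softmax_stable",
]

# attention peaks at or below this are treated as an all-zero map
ATTENTION_ZERO_CUTOFF = 1e-5


def sigmoid(z: np.ndarray | float) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax_stable(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    m = np.max(z, axis=axis, keepdims=True)
    e = np.exp(z - m)
    return e / e.sum(axis=axis, keepdims=True)


def _same3(size: int, stride: int) -> tuple[int, int, int]:
    """Output size and (before, after) pad widths for a same-padded 3-tap conv."""
    out = -(-size // stride)
    pad_after = max(0, (out - 1) * stride + 3 - (size + 1))
    return out, 1, pad_after


def _pad_same(x: np.ndarray, stride: int) -> tuple[np.ndarray, int, int]:
    """Edge-mirror "same" padding (matches scipy's boundary='symm')."""
    _, _, h, w = x.shape
    oh, pt, pb = _same3(h, stride)
    ow, pl, pr = _same3(w, stride)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), mode="symmetric")
    return xp, oh, ow


def _dw_conv3x3(x: np.ndarray, w: np.ndarray, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Depthwise 3×3 conv (cross-correlation), mirror-padded same. w: (C,3,3)."""
    xp, oh, ow = _pad_same(x, stride)
    n, c = x.shape[:2]
    out = np.zeros((n, c, oh, ow), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            out += w[:, i, j].astype(x.dtype)[None, :, None, None] * \
                xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return out, xp


def _unpad_grad(gxp: np.ndarray, h: int, wd: int, stride: int) -> np.ndarray:
    """Strip pad gradients, folding mirror-pad contributions onto their sources."""
    _, pt, pb = _same3(h, stride)
    _, pl, pr = _same3(wd, stride)
    gx = gxp[:, :, pt:pt + h, pl:pl + wd].copy()
    if pt:
        gx[:, :, 0, :] += gxp[:, :, pt - 1, pl:pl + wd]
    if pb:
        gx[:, :, h - 1, :] += gxp[:, :, pt + h, pl:pl + wd]
    if pl:
        gx[:, :, :, 0] += gxp[:, :, pt:pt + h, pl - 1]
    if pr:
        gx[:, :, :, wd - 1] += gxp[:, :, pt:pt + h, pl + wd]
    if pt and pl:
        gx[:, :, 0, 0] += gxp[:, :, pt - 1, pl - 1]
    if pt and pr:
        gx[:, :, 0, wd - 1] += gxp[:, :, pt - 1, pl + wd]
    if pb and pl:
        gx[:, :, h - 1, 0] += gxp[:, :, pt + h, pl - 1]
    if pb and pr:
        gx[:, :, h - 1, wd - 1] += gxp[:, :, pt + h, pl + wd]
    return gx


def _dw_conv3x3_backward(
    gout: np.ndarray, xp: np.ndarray, w: np.ndarray, x_shape: tuple, stride: int,
    need_input_grad: bool = True,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Gradients of a depthwise conv w.r.t. input and kernel."""
    n, c, h, wd = x_shape
    oh, ow = gout.shape[2:]
    dw = np.zeros_like(w, dtype=np.float64)
    gxp = np.zeros_like(xp) if need_input_grad else None
    for i in range(3):
        for j in range(3):
            sl = np.s_[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            dw[:, i, j] = np.einsum("nchw,nchw->c", xp[sl], gout, optimize=True)
            if need_input_grad:
                gxp[sl] += w[:, i, j].astype(gout.dtype)[None, :, None, None] * gout
    gx = None
    if need_input_grad:
        gx = _unpad_grad(gxp, h, wd, stride)
    return gx, dw


class Layer:
    """Base layer: parameter dict, gradient dict, cached forward state."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        raise NotImplementedError  # pragma: no cover


class Conv3x3(Layer):
    """Full 3×3 convolution, stride 1, same padding, optional bias."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_ch * 9
        bound = float(np.sqrt(2.0 / fan_in))  # He init for ReLU nets
        self.params["w"] = rng.normal(0.0, bound, size=(out_ch, in_ch, 3, 3)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp, oh, ow = _pad_same(x, 1)
        self._xp, self._xshape = xp, x.shape
        w = self.params["w"]
        out = np.zeros((x.shape[0], self.out_ch, oh, ow), dtype=x.dtype)
        for i in range(3):
            for j in range(3):
                out += np.einsum(
                    "oc,nchw->nohw", w[:, :, i, j].astype(x.dtype),
                    xp[:, :, i:i + oh, j:j + ow], optimize=True)
        if "b" in self.params:
            out += self.params["b"].astype(x.dtype)[None, :, None, None]
        return out

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        xp, (n, c, h, wd) = self._xp, self._xshape
        oh, ow = gout.shape[2:]
        w = self.params["w"]
        dw = np.zeros_like(w, dtype=np.float64)
        gxp = np.zeros_like(xp) if need_input_grad else None
        for i in range(3):
            for j in range(3):
                xs = xp[:, :, i:i + oh, j:j + ow]
                dw[:, :, i, j] = np.einsum("nchw,nohw->oc", xs, gout, optimize=True)
                if need_input_grad:
                    gxp[:, :, i:i + oh, j:j + ow] += np.einsum(
                        "oc,nohw->nchw", w[:, :, i, j].astype(gout.dtype), gout, optimize=True)
        self.grads["w"] = dw
        if "b" in self.params:
            self.grads["b"] = gout.sum(axis=(0, 2, 3))
        if not need_input_grad:
            return None
        return _unpad_grad(gxp, h, wd, 1)


class Depthwise3x3(Layer):
    """Per-channel 3×3 convolution (groups = C), stride 1, same padding."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        bound = float(np.sqrt(2.0 / 9.0))
        self.params["w"] = rng.normal(0.0, bound, size=(channels, 3, 3)).astype(np.float32)
        self.channels = channels

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        out, self._xp = _dw_conv3x3(x, self.params["w"], stride=1)
        self._xshape = x.shape
        return out

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        gx, dw = _dw_conv3x3_backward(
            gout, self._xp, self.params["w"], self._xshape, 1, need_input_grad)
        self.grads["w"] = dw
        return gx


class Pointwise(Layer):
    """1×1 convolution mixing M input channels into N output channels."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = float(np.sqrt(2.0 / in_ch))
        self.params["w"] = rng.normal(0.0, bound, size=(out_ch, in_ch)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        self._x = x
        out = np.einsum("om,nmhw->nohw", self.params["w"].astype(x.dtype), x, optimize=True)
        if "b" in self.params:
            out += self.params["b"].astype(x.dtype)[None, :, None, None]
        return out

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        self.grads["w"] = np.einsum("nohw,nmhw->om", gout, self._x, optimize=True)
        if "b" in self.params:
            self.grads["b"] = gout.sum(axis=(0, 2, 3))
        if not need_input_grad:
            return None
        return np.einsum("om,nohw->nmhw", self.params["w"].astype(gout.dtype), gout, optimize=True)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.buffers["running_mean"] = np.zeros(channels, dtype=np.float64)
        self.buffers["running_var"] = np.ones(channels, dtype=np.float64)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            nelem = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * nelem / max(nelem - 1, 1)
            self.buffers["running_mean"] = (1 - m) * self.buffers["running_mean"] + m * mean
            self.buffers["running_var"] = (1 - m) * self.buffers["running_var"] + m * unbiased
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return self.params["gamma"].astype(x.dtype)[None, :, None, None] * xhat + \
            self.params["beta"].astype(x.dtype)[None, :, None, None]

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = np.einsum("nchw,nchw->c", gout, xhat, optimize=True)
        self.grads["beta"] = gout.sum(axis=(0, 2, 3))
        if not need_input_grad:
            return None
        g = self.params["gamma"].astype(gout.dtype)[None, :, None, None] * gout
        if not self._train:
            return g * inv[None, :, None, None]
        nelem = gout.shape[0] * gout.shape[2] * gout.shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = np.einsum("nchw,nchw->c", g, xhat, optimize=True)[None, :, None, None]
        return inv[None, :, None, None] / nelem * (nelem * g - sum_g - xhat * sum_gx)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        return gout * self._mask if need_input_grad else None


class MaxPool2x2(Layer):
    """2×2 max pool, stride 2, ceil mode (odd sizes padded with −inf)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = -(-h // 2), -(-w // 2)
        xp = np.full((n, c, 2 * oh, 2 * ow), -np.inf, dtype=x.dtype)
        xp[:, :, :h, :w] = x
        win = xp.reshape(n, c, oh, 2, ow, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
        self._arg = np.argmax(win, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if not need_input_grad:
            return None
        n, c, h, w = self._shape
        oh, ow = gout.shape[2:]
        gwin = np.zeros((n, c, oh, ow, 4), dtype=gout.dtype)
        np.put_along_axis(gwin, self._arg[..., None], gout[..., None], axis=-1)
        gxp = gwin.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * oh, 2 * ow)
        return gxp[:, :, :h, :w]


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        if not need_input_grad:
            return None
        n, c, h, w = self._shape
        return np.broadcast_to(gout[:, :, None, None] / (h * w), self._shape).astype(gout.dtype).copy()


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = float(np.sqrt(1.0 / in_features))
        self.params["w"] = rng.uniform(-bound, bound, size=(out_features, in_features)).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T.astype(x.dtype) + self.params["b"].astype(x.dtype)

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        self.grads["w"] = gout.T @ self._x
        self.grads["b"] = gout.sum(axis=0)
        if not need_input_grad:
            return None
        return gout @ self.params["w"].astype(gout.dtype)


class LSBDULayer(Layer):
    """Learnable spectral biorthogonal downsampling unit.

    Per channel c the input is filtered by a learnable low-pass kernel phi_c
    and a high-pass kernel psi_c (both 3×3, grouped per channel), decimated
    by stride 2, and the two bands are fused with sigmoid-gated per-channel
    scalars: Y_c = σ(a_c)·L̂_c + σ(b_c)·Ĥ_c. At initialization phi/psi carry
    Bior2.2 coefficients and a = b = 0 so both gates start at 0.5. The layer
    is linear in its input (no bias, no nonlinearity).
    """

    def __init__(self, channels: int, phi: np.ndarray, psi: np.ndarray):
        super().__init__()
        if channels < 1:
            raise ValueError("channel count must be positive")
        self.params["phi"] = np.broadcast_to(
            np.asarray(phi, dtype=np.float32), (channels, 3, 3)).copy()
        self.params["psi"] = np.broadcast_to(
            np.asarray(psi, dtype=np.float32), (channels, 3, 3)).copy()
        self.params["a"] = np.zeros(channels, dtype=np.float32)
        self.params["b"] = np.zeros(channels, dtype=np.float32)
        self.channels = channels

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if x.shape[2] < 2 or x.shape[3] < 2:
            raise ValueError("spatial dims must be >= 2 for downsampling")
        low, xp = _dw_conv3x3(x, self.params["phi"], stride=2)
        high, _ = _dw_conv3x3(x, self.params["psi"], stride=2)
        alpha = sigmoid(self.params["a"]).astype(x.dtype)
        beta = sigmoid(self.params["b"]).astype(x.dtype)
        self._xp, self._xshape = xp, x.shape
        self._low, self._high = low, high
        self._alpha, self._beta = alpha, beta
        return alpha[None, :, None, None] * low + beta[None, :, None, None] * high

    def backward(self, gout: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        alpha, beta = self._alpha, self._beta
        glow = alpha[None, :, None, None] * gout
        ghigh = beta[None, :, None, None] * gout
        # gates: dσ(a)/da = σ(1−σ)
        gl = np.einsum("nchw,nchw->c", gout, self._low, optimize=True)
        gh = np.einsum("nchw,nchw->c", gout, self._high, optimize=True)
        self.grads["a"] = gl * alpha * (1.0 - alpha)
        self.grads["b"] = gh * beta * (1.0 - beta)
        gx1, dphi = _dw_conv3x3_backward(
            glow, self._xp, self.params["phi"], self._xshape, 2, need_input_grad)
        gx2, dpsi = _dw_conv3x3_backward(
            ghigh, self._xp, self.params["psi"], self._xshape, 2, need_input_grad)
        self.grads["phi"], self.grads["psi"] = dphi, dpsi
        if not need_input_grad:
            return None
        return gx1 + gx2

    def project(self) -> None:
        """Retract psi onto the zero-sum plane (per channel).

        Called after each optimizer step: elementwise Adam updates do not
        preserve the zero-sum high-pass property, and the attention map's
        constants-vanish contract depends on it.
        """
        self.params["psi"] = self.params["psi"] - \
            self.params["psi"].mean(axis=(1, 2), keepdims=True)

    def attention(self, x: np.ndarray) -> np.ndarray:
        """Channel-mean |σ(b_c)·Ĥ_c| rescaled to [0,1]; (N, ⌈H/2⌉, ⌈W/2⌉)."""
        high, _ = _dw_conv3x3(x, self.params["psi"], stride=2)
        beta = sigmoid(self.params["b"]).astype(x.dtype)
        att = np.abs(beta[None, :, None, None] * high).mean(axis=1)
        # peaks below the numerical-zero cutoff are roundoff dust, not signal;
        # rescaling them would amplify float32 noise into a full-range map
        for i in range(att.shape[0]):
            mx = att[i].max()
            if mx > ATTENTION_ZERO_CUTOFF:
                att[i] = att[i] / mx
            else:
                att[i] = 0.0
        return att


class Model:
    """An ordered chain of named layers with activation/gradient capture."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        self._names = [n for n, _ in layers]
        if len(set(self._names)) != len(self._names):
            raise ValueError("layer names must be unique")

    def __getitem__(self, name: str) -> Layer:
        for n, l in self.layers:
            if n == name:
                return l
        raise KeyError(name)

    @property
    def layer_names(self) -> list[str]:
        return list(self._names)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._acts: dict[str, np.ndarray] = {}
        for name, layer in self.layers:
            x = layer.forward(x, train)
            self._acts[name] = x
        return x

    def activation(self, name: str) -> np.ndarray:
        return self._acts[name]

    def backward(self, gout: np.ndarray, capture: set[str] | None = None) -> dict[str, np.ndarray]:
        """Backpropagate from the output; return captured per-layer output grads."""
        captured: dict[str, np.ndarray] = {}
        capture = capture or set()
        g = gout
        for idx in range(len(self.layers) - 1, -1, -1):
            name, layer = self.layers[idx]
            if name in capture:
                captured[name] = g
            # the first layer's input gradient is never consumed
            g = layer.backward(g, need_input_grad=(idx > 0))
            if g is None and idx > 0:
                raise RuntimeError(f"layer {name} returned no input gradient")
        return captured

    def parameters(self) -> Iterator[tuple[str, Layer, str]]:
        for name, layer in self.layers:
            for key in layer.params:
                yield name, layer, key

    def count_parameters(self) -> int:
        return sum(layer.params[key].size for _, layer, key in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for key, val in layer.params.items():
                out[f"{name}.{key}"] = val
            for key, val in layer.buffers.items():
                out[f"{name}.buffer.{key}"] = val
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for key in layer.params:
                layer.params[key] = np.array(state[f"{name}.{key}"])
            for key in layer.buffers:
                layer.buffers[key] = np.array(state[f"{name}.buffer.{key}"])


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, model: Model, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.model = model
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self._m: dict[tuple[str, str], np.ndarray] = {}
        self._v: dict[tuple[str, str], np.ndarray] = {}
        for name, layer, key in model.parameters():
            self._m[(name, key)] = np.zeros(layer.params[key].shape, dtype=np.float64)
            self._v[(name, key)] = np.zeros(layer.params[key].shape, dtype=np.float64)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, layer, key in self.model.parameters():
            g = layer.grads.get(key)
            if g is None:
                continue
            g = np.asarray(g, dtype=np.float64)
            m = self._m[(name, key)]
            v = self._v[(name, key)]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p = layer.params[key].astype(np.float64)
            p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            layer.params[key] = p.astype(layer.params[key].dtype)
        for _, layer in self.model.layers:
            project = getattr(layer, "project", None)
            if project is not None:
                project()
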
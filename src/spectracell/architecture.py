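"""Spectral-aware CNN assembly, softmax head, and cost accounting.

The network is: a stem (3×3 conv → batch norm → ReLU), then a sequence of
stages, each holding one or more depthwise separable convolution (DSC)
blocks followed by exactly one downsampling unit (LSBDU, or 2×2 max pool
for the ablation), then global average pooling and a fully connected
softmax head.

Cost accounting follows the standard multiply–accumulate counts: a full
convolution costs DK²·M·N·DF² MACs while its depthwise separable
factorization costs DK²·M·DF² + M·N·DF², a reduction factor of
1/N + 1/DK².
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import filterbank
from ._nn import (BatchNorm2d, Conv3x3, Depthwise3x3, GlobalAvgPool, Linear,
                  LSBDULayer, MaxPool2x2, Model, Pointwise, ReLU,
                  softmax_stable)

__all__ = [
    "ArchitectureSpec", "CostReport", "build_model", "softmax",
    "cost_standard", "cost_dsc", "count_parameters", "model_cost_report",
    "predict_proba", "save_checkpoint", "load_checkpoint",
    "default_spec", "small_spec", "default_cam_layer", "first_lsbdu_name",
]


@dataclass
class ArchitectureSpec:
    """Declarative description of the network.

    ``stages`` is an ordered list of ``(dsc_blocks, out_channels)`` pairs;
    every stage ends in exactly one downsampling unit, so the spatial size
    is halved once per stage.
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    stem_channels: int = 32
    stages: list[tuple[int, int]] = field(
        default_factory=lambda: [(2, 64), (2, 128), (2, 256), (2, 512), (2, 512)])
    downsampler: str = "lsbdu"
    num_classes: int = 8

    def __post_init__(self) -> None:
        if self.downsampler not in ("lsbdu", "maxpool"):
            raise ValueError("downsampler must be 'lsbdu' or 'maxpool'")
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.input_size) != 3 or self.input_size[2] != 3:
            raise ValueError("input_size must be (H, W, 3)")
        h, w = self.input_size[:2]
        for _ in self.stages:
            if h < 2 or w < 2:
                raise ValueError("spatial size would collapse below 1×1")
            h, w = -(-h // 2), -(-w // 2)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        d["stages"] = [list(s) for s in self.stages]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(input_size=tuple(d["input_size"]),
                   stem_channels=int(d["stem_channels"]),
                   stages=[tuple(s) for s in d["stages"]],
                   downsampler=d["downsampler"],
                   num_classes=int(d["num_classes"]))


def default_spec(num_classes: int = 8) -> ArchitectureSpec:
    """Full-scale spec: 224×224 input, five stages, widths 64…512."""
    return ArchitectureSpec(num_classes=num_classes)


def small_spec(num_classes: int = 8, downsampler: str = "lsbdu") -> ArchitectureSpec:
    """Desk-scale spec: 64×64 input, three single-block stages (32/64/96)."""
    return ArchitectureSpec(input_size=(64, 64, 3), stem_channels=16,
                            stages=[(1, 32), (1, 64), (1, 96)],
                            downsampler=downsampler, num_classes=num_classes)


@dataclass
class CostReport:
    standard_macs: int
    dsc_macs: int
    ratio: float
    rows: list[dict] = field(default_factory=list)


def cost_standard(dk: int, m: int, n: int, df: int) -> int:
    """MACs of a same-padded stride-1 standard convolution: DK²·M·N·DF²."""
    for v in (dk, m, n, df):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError("all cost arguments must be positive integers")
    return dk * dk * m * n * df * df


def cost_dsc(dk: int, m: int, n: int, df: int) -> int:
    """MACs of the depthwise separable factorization: DK²·M·DF² + M·N·DF²."""
    for v in (dk, m, n, df):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError("all cost arguments must be positive integers")
    return dk * dk * m * df * df + m * n * df * df


def softmax(z: np.ndarray) -> np.ndarray:
    """ŷ_i = exp(z_i)/Σ_j exp(z_j), computed with max-subtraction."""
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax requires finite logits")
    return softmax_stable(z, axis=-1)


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Assemble the network with deterministic, seeded weight init.

    LSBDU kernels start from the Bior2.2 pair with fusion gates at 0.5; all
    other convolutions use He-style init from the given seed.
    """
    rng = np.random.default_rng(seed)
    kern = filterbank.make_kernels(filterbank.bior22_taps())
    layers: list[tuple[str, object]] = []
    layers.append(("stem.conv", Conv3x3(3, spec.stem_channels, rng)))
    layers.append(("stem.bn", BatchNorm2d(spec.stem_channels)))
    layers.append(("stem.relu", ReLU()))
    in_ch = spec.stem_channels
    for si, (blocks, out_ch) in enumerate(spec.stages, start=1):
        for bi in range(1, blocks + 1):
            pre = f"s{si}.b{bi}"
            layers.append((f"{pre}.dw", Depthwise3x3(in_ch, rng)))
            layers.append((f"{pre}.dwbn", BatchNorm2d(in_ch)))
            layers.append((f"{pre}.dwrelu", ReLU()))
            layers.append((f"{pre}.pw", Pointwise(in_ch, out_ch, rng)))
            layers.append((f"{pre}.pwbn", BatchNorm2d(out_ch)))
            layers.append((f"{pre}.pwrelu", ReLU()))
            in_ch = out_ch
        if spec.downsampler == "lsbdu":
            layers.append((f"s{si}.down", LSBDULayer(in_ch, kern.phi, kern.psi)))
        else:
            layers.append((f"s{si}.down", MaxPool2x2()))
    layers.append(("gap", GlobalAvgPool()))
    layers.append(("fc", Linear(in_ch, spec.num_classes, rng)))
    return Model(layers)


def predict_proba(model: Model, images: np.ndarray) -> np.ndarray:
    """Class probabilities for (H, W, 3) or (N, H, W, 3) images (eval mode)."""
    x = np.asarray(images, dtype=np.float32)
    single = x.ndim == 3
    if single:
        x = x[None]
    logits = model.forward(x.transpose(0, 3, 1, 2), train=False)
    probs = softmax(logits)
    return probs[0] if single else probs


def count_parameters(model: Model) -> int:
    """Total trainable scalar count across all parameter tensors."""
    return model.count_parameters()


def model_cost_report(spec: ArchitectureSpec) -> CostReport:
    """Per-layer standard-vs-DSC MAC comparison for the spec's DSC blocks."""
    h, w = spec.input_size[:2]
    in_ch = spec.stem_channels
    rows: list[dict] = []
    tot_std = tot_dsc = 0
    for si, (blocks, out_ch) in enumerate(spec.stages, start=1):
        for bi in range(1, blocks + 1):
            df = h  # square feature maps assumed for the report
            std = cost_standard(3, in_ch, out_ch, df)
            sep = cost_dsc(3, in_ch, out_ch, df)
            rows.append({"layer": f"s{si}.b{bi}", "DF": df, "M": in_ch,
                         "N": out_ch, "standard_macs": std, "dsc_macs": sep,
                         "ratio": sep / std})
            tot_std += std
            tot_dsc += sep
            in_ch = out_ch
        h, w = -(-h // 2), -(-w // 2)
    return CostReport(standard_macs=tot_std, dsc_macs=tot_dsc,
                      ratio=tot_dsc / tot_std, rows=rows)


def default_cam_layer(model: Model) -> str:
    """Name of the last DSC-block activation before global average pooling."""
    relus = [n for n in model.layer_names if n.endswith(".pwrelu")]
    if not relus:
        raise ValueError("model has no DSC blocks")
    return relus[-1]


def first_lsbdu_name(model: Model) -> str:
    for name, layer in model.layers:
        if isinstance(layer, LSBDULayer):
            return name
    raise ValueError("model has no LSBDU layers")


def save_checkpoint(model: Model, spec: ArchitectureSpec, path: str,
                    extra: dict | None = None) -> None:
    """Weights archive (.npz) plus a YAML sidecar of the architecture spec.

    ``extra`` (e.g. normalization statistics) is stored in the sidecar, so a
    checkpoint is reconstructable without code inspection.
    """
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    np.savez(path, **model.state_dict())
    doc = {"architecture": spec.to_dict(), "extra": extra or {}}
    with open(path[:-4] + ".yaml", "w") as fh:
        yaml.safe_dump(doc, fh)


def load_checkpoint(path: str) -> tuple[Model, ArchitectureSpec, dict]:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path[:-4] + ".yaml") as fh:
        doc = yaml.safe_load(fh)
    spec = ArchitectureSpec.from_dict(doc["architecture"])
    model = build_model(spec, seed=0)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, spec, doc.get("extra", {})
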
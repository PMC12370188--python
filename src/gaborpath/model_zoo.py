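"""Architecture specs, runnable models, and receptive-field arithmetic.

A model is described declaratively as an ordered list of :class:`LayerSpec`
entries; from the same spec we derive (a) a runnable NumPy model and (b) the
analytic effective receptive field of every spatial layer via the standard
composition recurrence

    r_l = r_{l-1} + (k_l - 1) * j_{l-1},    j_l = j_{l-1} * s_l,

with r_0 = j_0 = 1. An impulse-footprint oracle cross-checks the arithmetic
empirically on models with all-positive weights.

The zoo contains the reference backbone (the classic five-conv/three-pool
AlexNet topology, conv-5 block receptive field 195 px) and the PinholeNet
family: same depth and channel progression (64, 192, 384, 256, 256) but no
max-pooling and stride-1 kernels chosen so that fifth-block units see only
11 / 17 / 31 / 33 px of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "RFReport",
    "receptive_field",
    "rf_footprint_oracle",
    "build_model",
    "make_pinholenet",
    "make_reference_backbone",
    "make_toy_net",
    "PINHOLE_KERNELS",
    "PINHOLE_CHANNELS",
]

_SPATIAL = {"conv", "maxpool"}


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | relu | maxpool | avgpool_global | adaptive_avgpool | fc | dropout | flatten
    name: str
    kernel: int = 1
    stride: int = 1
    padding: int = 0
    out_channels: int = 0

    def __post_init__(self):
        if self.kind in _SPATIAL and (self.kernel < 1 or self.stride < 1):
            raise ValueError("kernel and stride must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    layers: tuple[LayerSpec, ...]
    input_size: int = 512
    in_channels: int = 1

    def to_yaml(self) -> str:
        return yaml.safe_dump({"name": self.name, "input_size": self.input_size,
                               "in_channels": self.in_channels,
                               "layers": [asdict(l) for l in self.layers]})

    @staticmethod
    def from_yaml(text: str) -> "ArchitectureSpec":
        d = yaml.safe_load(text)
        return ArchitectureSpec(name=d["name"], input_size=d["input_size"],
                                in_channels=d.get("in_channels", 1),
                                layers=tuple(LayerSpec(**l) for l in d["layers"]))

    @property
    def probe_points(self) -> list[str]:
        return [l.name for l in self.layers]


@dataclass
class RFReport:
    entries: list[dict] = field(default_factory=list)

    def rf_at(self, name: str) -> int:
        for e in self.entries:
            if e["layer"] == name:
                return e["rf_size"]
        raise KeyError(name)

    @property
    def final_rf(self) -> int:
        return self.entries[-1]["rf_size"]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.entries)


# ---------------------------------------------------------------------------
# receptive-field arithmetic
# ---------------------------------------------------------------------------

def receptive_field(arch: ArchitectureSpec) -> RFReport:
    """Analytic effective RF per spatial (conv/pool) layer; stops at the
    first flatten / global-pool / fc layer."""
    r, j = 1, 1
    report = RFReport()
    for layer in arch.layers:
        if layer.kind in ("flatten", "avgpool_global", "adaptive_avgpool"):
            break
        if layer.kind == "fc":
            raise ValueError("fc layer before flatten in architecture spec")
        if layer.kind not in _SPATIAL:
            continue
        r = r + (layer.kernel - 1) * j
        j = j * layer.stride
        report.entries.append({"layer": layer.name, "rf_size": r, "jump": j})
    return report


def rf_footprint_oracle(arch: ArchitectureSpec, input_size: int | None = None
                        ) -> tuple[int, bool]:
    """Empirical RF of a central unit in the last spatial layer.

    Builds the model with all-positive weights (no cancellation), takes the
    gradient of one central unit w.r.t. the input, and measures the extent
    (max of height/width) of the nonzero-sensitivity bounding box. Returns
    ``(extent, truncated)`` where ``truncated`` flags a footprint clipped by
    the image border, in which case the extent underestimates the analytic
    value.
    """
    size = input_size or arch.input_size
    # only the geometry matters for the footprint; narrow the channel
    # widths so wide architectures stay cheap to probe
    slim = ArchitectureSpec(
        arch.name,
        tuple(LayerSpec(l.kind, l.name, l.kernel, l.stride, l.padding,
                        min(l.out_channels, 2) if l.kind == "conv"
                        else l.out_channels)
              for l in arch.layers),
        input_size=arch.input_size, in_channels=arch.in_channels)
    model, spec = build_model(slim, seed=0, input_size=size)
    last_spatial = None
    for l in spec.layers:
        if l.kind in _SPATIAL:
            last_spatial = l.name
    if last_spatial is None:
        raise ValueError("no spatial layers in spec")
    for layer in model.layers:
        for p in layer.parameters():
            if p.ndim > 1:  # weights -> strictly positive
                np.abs(p, out=p)
                p += 1e-6
            else:
                p[:] = 0.0
    # max-pooling routes gradient only to per-window argmaxes, which would
    # under-report the influence field; substitute mean pooling of the same
    # geometry so every input that *can* influence the unit registers
    for i, layer in enumerate(model.layers):
        if isinstance(layer, nn.MaxPool2d):
            model.layers[i] = nn.AvgPool2d(layer.kernel, layer.stride)
    x = np.ones((1, spec.in_channels, size, size))
    out = model.forward(x, upto=last_spatial)
    _, c, h, w = out.shape
    g = np.zeros_like(out)
    g[0, 0, h // 2, w // 2] = 1.0
    dx = model.backward(g)
    mask = np.abs(dx[0]).sum(axis=0) > 0
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    extent = int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))
    truncated = bool(rows[0] == 0 or cols[0] == 0
                     or rows[-1] == size - 1 or cols[-1] == size - 1)
    return extent, truncated


# ---------------------------------------------------------------------------
# building runnable models
# ---------------------------------------------------------------------------

def build_model(arch: ArchitectureSpec, seed: int = 0,
                input_size: int | None = None
                ) -> tuple[nn.Sequential, ArchitectureSpec]:
    """Instantiate the spec as a runnable NumPy model (He init, seeded).

    ``input_size`` overrides the spec's canvas so every architecture has a
    reduced desk-scale twin; fc input dimensions are resolved by shape
    propagation, so this only works when an fc layer is preceded by a
    global pool or a size-independent flatten point.
    """
    size = input_size or arch.input_size
    if input_size is not None and input_size != arch.input_size:
        arch = ArchitectureSpec(arch.name, arch.layers, input_size=input_size,
                                in_channels=arch.in_channels)
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Layer]] = []
    c, h = arch.in_channels, size
    flat: int | None = None
    for l in arch.layers:
        if l.kind == "conv":
            lay = nn.Conv2d(c, l.out_channels, l.kernel, l.stride, l.padding,
                            seed=int(rng.integers(2 ** 31)))
            h = lay.out_size(h)
            c = l.out_channels
        elif l.kind == "relu":
            lay = nn.ReLU()
        elif l.kind == "maxpool":
            lay = nn.MaxPool2d(l.kernel, l.stride)
            h = lay.out_size(h)
        elif l.kind == "avgpool_global":
            lay = nn.GlobalAvgPool()
            flat = c
        elif l.kind == "adaptive_avgpool":
            lay = nn.AdaptiveAvgPool2d(l.kernel)
            h = l.kernel
        elif l.kind == "flatten":
            lay = nn.Flatten()
            flat = c * h * h
        elif l.kind == "dropout":
            lay = nn.Dropout(0.5)
        elif l.kind == "center":
            lay = nn.InputCenter(0.5)
        elif l.kind == "fc":
            if flat is None:
                raise ValueError("fc layer before flatten/global pool")
            lay = nn.Linear(flat, l.out_channels,
                            seed=int(rng.integers(2 ** 31)))
            flat = l.out_channels
        else:
            raise ValueError(f"unknown layer kind {l.kind!r}")
        layers.append((l.name, lay))
    return nn.Sequential(layers), arch


# ---------------------------------------------------------------------------
# the zoo
# ---------------------------------------------------------------------------

PINHOLE_CHANNELS = (64, 192, 384, 256, 256)
# stride-1, 'same'-padded kernel plans satisfying the fifth-block RF targets
PINHOLE_KERNELS = {
    "P11": (3, 3, 3, 3, 3),
    "P17": (5, 5, 5, 3, 3),
    "P31": (7, 7, 7, 7, 7),
    "P33": (9, 7, 7, 7, 7),
}


def make_pinholenet(variant: str, input_size: int = 512, seed: int = 0,
                    head_width: int = 4096, n_classes: int = 1000
                    ) -> tuple[nn.Sequential, ArchitectureSpec]:
    """PinholeNet: five conv+relu blocks (no pooling) with the reference
    channel progression, then global average pooling and the standard
    three-fc classifier head."""
    if variant not in PINHOLE_KERNELS:
        raise ValueError(f"unknown PinholeNet variant {variant!r}")
    kernels = PINHOLE_KERNELS[variant]
    layers: list[LayerSpec] = []
    for i, (k, ch) in enumerate(zip(kernels, PINHOLE_CHANNELS), start=1):
        layers.append(LayerSpec("conv", f"conv{i}", kernel=k, stride=1,
                                padding=k // 2, out_channels=ch))
        layers.append(LayerSpec("relu", f"relu{i}"))
    layers += [
        LayerSpec("avgpool_global", "avgpool"),
        LayerSpec("dropout", "drop6"),
        LayerSpec("fc", "fc6", out_channels=head_width),
        LayerSpec("relu", "relu6"),
        LayerSpec("dropout", "drop7"),
        LayerSpec("fc", "fc7", out_channels=head_width),
        LayerSpec("relu", "relu7"),
        LayerSpec("fc", "fc8", out_channels=n_classes),
    ]
    arch = ArchitectureSpec(variant, tuple(layers), input_size=input_size)
    model, arch = build_model(arch, seed=seed)
    return model, arch


def make_reference_backbone(input_size: int = 512, seed: int = 0,
                            n_classes: int = 1000
                            ) -> tuple[nn.Sequential, ArchitectureSpec]:
    """The classic five-conv/three-maxpool topology with 21 named probe
    points (conv/relu/pool stages, the 6x6 adaptive average pool, and the
    dropout/fc/relu stages of the three-layer classifier)."""
    L = LayerSpec
    layers = (
        L("conv", "conv1", kernel=11, stride=4, padding=2, out_channels=64),
        L("relu", "relu1"),
        L("maxpool", "pool1", kernel=3, stride=2),
        L("conv", "conv2", kernel=5, stride=1, padding=2, out_channels=192),
        L("relu", "relu2"),
        L("maxpool", "pool2", kernel=3, stride=2),
        L("conv", "conv3", kernel=3, stride=1, padding=1, out_channels=384),
        L("relu", "relu3"),
        L("conv", "conv4", kernel=3, stride=1, padding=1, out_channels=256),
        L("relu", "relu4"),
        L("conv", "conv5", kernel=3, stride=1, padding=1, out_channels=256),
        L("relu", "relu5"),
        L("maxpool", "pool5", kernel=3, stride=2),
        L("adaptive_avgpool", "avgpool", kernel=6),
        L("flatten", "flatten"),
        L("dropout", "drop6"),
        L("fc", "fc6", out_channels=4096),
        L("relu", "relu6"),
        L("dropout", "drop7"),
        L("fc", "fc7", out_channels=4096),
        L("relu", "relu7"),
        L("fc", "fc8", out_channels=n_classes),
    )
    arch = ArchitectureSpec("reference", layers, input_size=input_size)
    model, arch = build_model(arch, seed=seed)
    return model, arch


# the 21 probe points of the reference backbone (flatten is a reshaping of
# the avgpool output, not a separate probe point)
REFERENCE_PROBE_POINTS = [
    "conv1", "relu1", "pool1", "conv2", "relu2", "pool2", "conv3", "relu3",
    "conv4", "relu4", "conv5", "relu5", "pool5", "avgpool", "drop6", "fc6",
    "relu6", "drop7", "fc7", "relu7", "fc8",
]


def make_vernier_net(input_size: int = 128, seed: int = 0,
                     n_classes: int = 2) -> tuple[nn.Sequential, ArchitectureSpec]:
    """Desk-scale vernier-discrimination backbone: stacked 3x3 stride-1
    convolutions with 2x2 max-pooling between blocks, so the front end
    samples finely enough to resolve a few-pixel vernier offset (coarse
    strided front ends cannot)."""
    L = LayerSpec
    layers = [L("center", "center")]
    channels = (8, 12, 16, 16)
    for i, ch in enumerate(channels, start=1):
        layers.append(L("conv", f"conv{i}", kernel=3, stride=1, padding=1,
                        out_channels=ch))
        layers.append(L("relu", f"relu{i}"))
        layers.append(L("maxpool", f"pool{i}", kernel=2, stride=2))
    layers += [
        LayerSpec("flatten", "flatten"),
        LayerSpec("fc", "fc_out", out_channels=n_classes),
    ]
    arch = ArchitectureSpec("vernier-desk", tuple(layers),
                            input_size=input_size)
    model, arch = build_model(arch, seed=seed)
    return model, arch


def make_toy_net(kind: str, input_size: int = 128, seed: int = 0,
                 n_classes: int = 2) -> tuple[nn.Sequential, ArchitectureSpec]:
    """Desk-scale twins for CPU experiments: five conv+relu blocks with a
    small channel budget and a global-average-pool linear head.

    ``kind='full'`` uses large strided kernels so fifth-block units see most
    of a 128-px display (RF 107 px); ``kind='pinhole'`` matches depth,
    strides and channels but shrinks kernels so fifth-block units see less
    than one Gabor element (RF 7 px).
    """
    plans = {
        "full": ((7, 2), (7, 2), (7, 2), (5, 2), (3, 1)),
        "pinhole": ((3, 2), (3, 2), (1, 2), (1, 2), (1, 1)),
    }
    if kind not in plans:
        raise ValueError(f"unknown toy net kind {kind!r}")
    channels = (6, 8, 8, 8, 8)
    layers: list[LayerSpec] = [LayerSpec("center", "center")]
    for i, ((k, s), ch) in enumerate(zip(plans[kind], channels), start=1):
        layers.append(LayerSpec("conv", f"conv{i}", kernel=k, stride=s,
                                padding=k // 2, out_channels=ch))
        layers.append(LayerSpec("relu", f"relu{i}"))
    layers += [
        LayerSpec("avgpool_global", "avgpool"),
        LayerSpec("fc", "fc_out", out_channels=n_classes),
    ]
    arch = ArchitectureSpec(f"toy-{kind}", tuple(layers), input_size=input_size)
    model, arch = build_model(arch, seed=seed)
    return model, arch
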
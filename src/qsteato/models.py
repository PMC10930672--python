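"""Model assembly: backbone + hybrid (QDI) or classical head.

The hybrid head maps backbone features through one or two affine layers to the
QDI feature capacity (100 by default), squashes them to (-pi, pi) with
pi*tanh so the RZ encoding angles stay well-conditioned, runs the quantum
circuit, and maps the per-qubit readouts through a final affine layer to the
two class logits.  The classical head is the same affine stack with the
quantum block replaced by a plain affine layer, so the only structural
difference is the head being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    GlobalAvgPool,
    Linear,
    QDILayer,
    ReLU,
    ScaledTanh,
    Sequential,
    softmax,
)
from .quantum import QDIConfig

N_CLASSES = 2


@dataclass(frozen=True)
class BackboneSpec:
    kind: str = "tiny-test-cnn"  # or "pretrained-resnet18"
    output_dim: int = 32

    def __post_init__(self) -> None:
        if self.kind not in ("tiny-test-cnn", "pretrained-resnet18"):
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if self.output_dim <= 0:
            raise ValueError("output_dim must be positive")


@dataclass(frozen=True)
class HybridHeadSpec:
    fc_pre: tuple[int, ...] = (64,)  # hidden widths; final layer goes to qdi capacity
    qdi: QDIConfig = field(default_factory=QDIConfig)
    # fc_post is always qdi.n_qubits -> 2


@dataclass(frozen=True)
class ClassicalHeadSpec:
    hidden: tuple[int, ...] = (64, 100)


def _affine_stack(widths: list[int], rng: np.random.Generator, prefix: str,
                  final_activation: bool = False) -> list[tuple[str, object]]:
    layers: list[tuple[str, object]] = []
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
        layers.append((f"{prefix}{i}", Linear(a, b, rng)))
        if i < len(widths) - 2 or final_activation:
            layers.append((f"{prefix}{i}_relu", ReLU()))
    return layers


def build_tiny_cnn(output_dim: int, rng: np.random.Generator) -> Sequential:
    """3 stride-2 conv blocks + global average pool; trains on CPU in minutes."""
    c1, c2 = 8, 16
    return Sequential([
        ("conv0", Conv2d(3, c1, rng, stride=2)),
        ("relu0", ReLU()),
        ("conv1", Conv2d(c1, c2, rng, stride=2)),
        ("relu1", ReLU()),
        ("conv2", Conv2d(c2, output_dim, rng, stride=2)),
        ("relu2", ReLU()),
        ("pool", GlobalAvgPool()),
    ])


def build_backbone(spec: BackboneSpec, rng: np.random.Generator) -> Sequential:
    if spec.kind == "tiny-test-cnn":
        return build_tiny_cnn(spec.output_dim, rng)
    raise RuntimeError(
        "pretrained-resnet18 requires torch + torchvision with downloaded "
        "weights; install them and use the TorchBackbone adapter, or use "
        "kind='tiny-test-cnn'"
    )


class Model:
    """A backbone + head pair with softmax probability output."""

    def __init__(self, net: Sequential, backbone_spec: BackboneSpec, head_spec,
                 kind: str) -> None:
        self.net = net
        self.backbone_spec = backbone_spec
        self.head_spec = head_spec
        self.kind = kind  # "hybrid" or "classical"

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (batch, 3, H, W) images, got {x.shape}")
        return self.net.forward(x, train=train)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(softmax(self.forward_logits(x[i : i + batch_size])))
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.net.named_params().items()}

    def set_weights(self, named: dict[str, np.ndarray]) -> None:
        self.net.set_params(named)


def build_hybrid_model(backbone: BackboneSpec, head: HybridHeadSpec,
                       seed: int = 0) -> Model:
    rng = np.random.default_rng([seed, 81])
    layers = [("backbone", build_backbone(backbone, rng))]
    widths = [backbone.output_dim, *head.fc_pre, head.qdi.feature_capacity]
    layers += _affine_stack(widths, rng, "fc_pre")
    layers.append(("squash", ScaledTanh(scale=np.pi)))
    layers.append(("qdi", QDILayer(head.qdi, rng)))
    layers.append(("fc_post0", Linear(head.qdi.n_qubits, N_CLASSES, rng)))
    return Model(Sequential(layers), backbone, head, kind="hybrid")


def build_classical_model(backbone: BackboneSpec, head: ClassicalHeadSpec,
                          seed: int = 0) -> Model:
    rng = np.random.default_rng([seed, 81])
    layers = [("backbone", build_backbone(backbone, rng))]
    widths = [backbone.output_dim, *head.hidden, N_CLASSES]
    layers += _affine_stack(widths, rng, "fc")
    return Model(Sequential(layers), backbone, head, kind="classical")


def build_model(kind: str, backbone: BackboneSpec | None = None, head=None,
                seed: int = 0) -> Model:
    backbone = backbone or BackboneSpec()
    if kind == "hybrid":
        return build_hybrid_model(backbone, head or HybridHeadSpec(), seed)
    if kind == "classical":
        return build_classical_model(backbone, head or ClassicalHeadSpec(), seed)
    raise ValueError(f"unknown model kind {kind!r}")


def count_parameters(model: Model) -> dict[str, int]:
    """Exact trainable-parameter counts per component."""
    counts: dict[str, int] = {"backbone": 0, "fc_pre": 0, "qdi": 0, "fc_post": 0, "fc": 0}
    for name, arr in model.net.named_params().items():
        top = name.split(".")[0]
        if top == "backbone":
            counts["backbone"] += arr.size
        elif top.startswith("fc_pre"):
            counts["fc_pre"] += arr.size
        elif top == "qdi":
            counts["qdi"] += arr.size
        elif top.startswith("fc_post"):
            counts["fc_post"] += arr.size
        else:
            counts["fc"] += arr.size
    counts["head"] = counts["fc_pre"] + counts["qdi"] + counts["fc_post"] + counts["fc"]
    counts["total"] = counts["backbone"] + counts["head"]
    return counts
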
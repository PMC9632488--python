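"""Architectures: the paper-scale VGG-16 variant and a tiny desk-scale CNN.

``vgg16-paper`` is the classic VGG-16 stack — thirteen 3x3 convolution
layers in five blocks (64,64 | 128,128 | 256,256,256 | 512,512,512 |
512,512,512), each block closed by a 2x2 max-pool — followed by three fully
connected layers of width 2048, 2048 and k (the class count) and a terminal
softmax.  The 2048-wide FC layers (instead of the canonical 4096) match the
published variant this package implements.

``tiny`` is a 3-block CNN (8, 16, 32 channels, each block conv+ReLU+pool)
with FC(64) and FC(k), meant for 64x64 inputs: the same structural family
at a scale a single CPU trains in seconds, used throughout the synthetic
experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from eegfuse.nn.layers import Conv2D, Dense, Flatten, Layer, MaxPool2D, ReLU

_ARCH_BLOCKS = {
    "vgg16-paper": ((64, 64), (128, 128), (256, 256, 256),
                    (512, 512, 512), (512, 512, 512)),
    "tiny": ((8,), (16,), (32,)),
}
_DEFAULT_INPUT = {"vgg16-paper": 224, "tiny": 64}


@dataclass
class ModelConfig:
    """Classifier architecture and training hyperparameters.

    Defaults follow the published protocol: 20 training epochs at learning
    rate 1e-4, 90/10 split handled by :class:`eegfuse.train.SplitPolicy`.
    ``fc_width`` applies to the two hidden FC layers of ``vgg16-paper``.
    """

    architecture: str = "vgg16-paper"
    n_classes: int = 2
    input_size: int | None = None
    fc_width: int = 2048
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.architecture not in _ARCH_BLOCKS:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(_ARCH_BLOCKS)}"
            )
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_size is None:
            self.input_size = _DEFAULT_INPUT[self.architecture]
        n_pools = len(_ARCH_BLOCKS[self.architecture])
        if self.input_size % (2**n_pools) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{n_pools} "
                f"(one 2x2 max-pool per block)"
            )


@dataclass
class NetworkSummary:
    """Structural description of a built network."""

    architecture: str
    layers: list[tuple[str, str]]  # (kind, detail)
    conv_layer_count: int
    fc_layer_count: int
    output_dim: int
    n_params: int


class Sequential:
    """Minimal sequential container with explicit backprop.

    The final layer is the Dense logit layer; softmax lives in the loss /
    prediction functions.  ``features`` exposes the penultimate activations
    (input to the final Dense) for t-SNE visualization.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer activations (everything up to the final Dense)."""
        for layer in self.layers[:-1]:
            x = layer.forward(x, train=False)
        return x

    @property
    def n_params(self) -> int:
        return sum(
            getattr(layer, "n_params", 0) for layer in self.layers
        )

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name in layer.param_names:
                out[f"layer{i}.{name}"] = getattr(layer, name)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.param_names:
                key = f"layer{i}.{name}"
                target = getattr(layer, name)
                if arrays[key].shape != target.shape:
                    raise ValueError(f"shape mismatch for {key}")
                target[...] = arrays[key]


def build_network(config: ModelConfig) -> tuple[NetworkSummary, Sequential]:
    """Construct the architecture described by ``config`` with seeded weights."""
    rng = np.random.default_rng(config.seed)
    blocks = _ARCH_BLOCKS[config.architecture]
    layers: list[Layer] = []
    summary_rows: list[tuple[str, str]] = [
        ("input", f"RGB image {config.input_size}x{config.input_size}")
    ]
    in_ch = 3
    size = config.input_size
    for block in blocks:
        for out_ch in block:
            layers += [Conv2D(in_ch, out_ch, rng), ReLU()]
            summary_rows.append(("conv", f"3x3, {in_ch}->{out_ch}"))
            in_ch = out_ch
        layers.append(MaxPool2D())
        summary_rows.append(("maxpool", "2x2"))
        size //= 2
    layers.append(Flatten())
    flat = in_ch * size * size

    if config.architecture == "vgg16-paper":
        fc_widths = [config.fc_width, config.fc_width]
    else:
        fc_widths = [64]
    in_f = flat
    for width in fc_widths:
        layers += [Dense(in_f, width, rng), ReLU()]
        summary_rows.append(("fc", f"{in_f}->{width}"))
        in_f = width
    layers.append(Dense(in_f, config.n_classes, rng))
    summary_rows.append(("fc", f"{in_f}->{config.n_classes}"))
    summary_rows.append(("softmax", f"k={config.n_classes}"))

    net = Sequential(layers)
    summary = NetworkSummary(
        architecture=config.architecture,
        layers=summary_rows,
        conv_layer_count=sum(1 for kind, _ in summary_rows if kind == "conv"),
        fc_layer_count=sum(1 for kind, _ in summary_rows if kind == "fc"),
        output_dim=config.n_classes,
        n_params=net.n_params,
    )
    return summary, net


def save_checkpoint(path, config: ModelConfig, net: Sequential) -> None:
    """Write architecture id + config + weights to an .npz container."""
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(asdict(config)).encode(), dtype=np.uint8),
        **net.state_arrays(),
    )


def load_checkpoint(path) -> tuple[ModelConfig, Sequential]:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        _, net = build_network(cfg)
        net.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return cfg, net
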
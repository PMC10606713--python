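"""Model builders: ResNet18 topology for grayscale/binary use, plus a small CNN.

``resnet18_gray_binary`` is the standard 2-2-2-2 basic-block ResNet18 with a
1-channel stem and a 2-class head, trained from scratch; global average
pooling makes it input-size agnostic (minimum 32x32).  ``small_cnn`` is a
3-block convolutional network intended for CPU-scale experiments and tests;
it is not part of the reference recipe.
"""

from __future__ import annotations

import numpy as np

from capnet.nn.layers import (
    CenterContextPool,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    Param,
    ReLU,
    Sequential,
)

__all__ = ["BasicBlock", "build_model", "count_parameters", "MODEL_VARIANTS"]

MODEL_VARIANTS = ("resnet18_gray_binary", "small_cnn")


class BasicBlock(Module):
    """Two 3x3 conv-BN pairs with an identity (or 1x1 projection) shortcut."""

    def __init__(
        self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator, name: str
    ) -> None:
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, 1, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_ch, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, 1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_ch, name=f"{name}.bn2")
        self.relu2 = ReLU()
        if stride != 1 or in_ch != out_ch:
            self.downsample: Sequential | None = Sequential(
                Conv2d(in_ch, out_ch, 1, stride, 0, rng=rng, name=f"{name}.down.conv"),
                BatchNorm2d(out_ch, name=f"{name}.down.bn"),
            )
        else:
            self.downsample = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        main = self.bn1.forward(self.conv1.forward(x, train), train)
        main = self.relu1.forward(main, train)
        main = self.bn2.forward(self.conv2.forward(main, train), train)
        short = self.downsample.forward(x, train) if self.downsample is not None else x
        return self.relu2.forward(main + short, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu2.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(dy))
        )))
        dshort = self.downsample.backward(dy) if self.downsample is not None else dy
        return dmain + dshort

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.downsample is not None:
            out += self.downsample.params()
        return out

    def state_items(self):
        out = (
            self.conv1.state_items()
            + self.bn1.state_items()
            + self.conv2.state_items()
            + self.bn2.state_items()
        )
        if self.downsample is not None:
            out += self.downsample.state_items()
        return out


def _resnet18(rng: np.random.Generator) -> Sequential:
    layers: list[Module] = [
        Conv2d(1, 64, 7, 2, 3, rng=rng, name="stem.conv"),
        BatchNorm2d(64, name="stem.bn"),
        ReLU(),
        MaxPool2d(3, 2, 1),
    ]
    in_ch = 64
    for stage, out_ch in enumerate((64, 128, 256, 512)):
        for block in range(2):
            stride = 2 if (stage > 0 and block == 0) else 1
            layers.append(BasicBlock(in_ch, out_ch, stride, rng, f"layer{stage + 1}.{block}"))
            in_ch = out_ch
    layers += [GlobalAvgPool(), Linear(512, 2, rng=rng, name="head")]
    return Sequential(*layers)


def _small_cnn(rng: np.random.Generator) -> Sequential:
    # center+context pooling lets the head weight the labeled central
    # second of a window separately from its flanks
    return Sequential(
        Conv2d(1, 8, 3, 2, 1, rng=rng, name="b1.conv"),
        BatchNorm2d(8, name="b1.bn"),
        ReLU(),
        MaxPool2d(2),
        Conv2d(8, 16, 3, 1, 1, rng=rng, name="b2.conv"),
        BatchNorm2d(16, name="b2.bn"),
        ReLU(),
        MaxPool2d(2),
        Conv2d(16, 32, 3, 1, 1, rng=rng, name="b3.conv"),
        BatchNorm2d(32, name="b3.bn"),
        ReLU(),
        CenterContextPool(),
        Linear(32 * 2, 2, rng=rng, name="head"),
    )


def build_model(
    variant: str, input_shape: tuple[int, int], seed: int = 0
) -> Sequential:
    """Build a randomly initialized model for (n_freq, n_time) images.

    The returned model consumes NCHW batches with one channel and emits two
    logits (index 0 = B phase, index 1 = A phase).
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {MODEL_VARIANTS}")
    n_freq, n_time = input_shape
    rng = np.random.default_rng(seed)
    if variant == "resnet18_gray_binary":
        if n_freq < 32 or n_time < 32:
            raise ValueError(
                f"resnet18_gray_binary needs images of at least 32x32, got {input_shape}"
            )
        return _resnet18(rng)
    if n_freq < 16 or n_time < 32:
        raise ValueError(f"small_cnn needs images of at least 16x32, got {input_shape}")
    return _small_cnn(rng)


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars."""
    return int(sum(p.data.size for p in model.params()))


def state_dict(model: Module) -> dict[str, np.ndarray]:
    return {name: arr.copy() for name, arr in model.state_items()}


def load_state_dict(model: Module, state: dict[str, np.ndarray]) -> None:
    for name, arr in model.state_items():
        if name not in state:
            raise KeyError(f"missing array {name!r} in state dict")
        if arr.shape != state[name].shape:
            raise ValueError(f"shape mismatch for {name!r}")
        arr[...] = state[name]
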
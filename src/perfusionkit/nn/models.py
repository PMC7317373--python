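"""Network architectures: a small 4-conv classifier/regressor CNN and a U-Net.

The CNN mirrors the classic image-recognition layout: four 3x3 convolution
layers, each followed by 2x2 max-pooling, batch normalization and ReLU, then
two fully-connected layers (dropout on the hidden one).  The U-Net has
``depth`` pooling steps with skip connections and channel doubling; its head
is a 1x1 convolution producing logits (sigmoid for binary segmentation or
4-way softmax for action maps is applied by the loss / at inference).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    DTYPE,
    BatchNorm2d,
    Conv2d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool2d,
    Param,
    ReLU,
    Sequential,
    Upsample2x,
)


class SimpleCNN(Layer):
    def __init__(
        self,
        in_channels: int,
        out_units: int,
        input_size: int,
        channels: tuple[int, ...] = (32, 64, 128, 256),
        fc_units: int = 256,
        dropout_p: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        if len(channels) != 4:
            raise ValueError("the classifier CNN uses exactly four conv layers")
        if input_size % 16 != 0:
            raise ValueError("input_size must be divisible by 16 (four 2x2 pools)")
        layers: list[Layer] = []
        cin = in_channels
        for i, c in enumerate(channels):
            layers += [Conv2d(cin, c, rng, name=f"conv{i}"), MaxPool2d(), BatchNorm2d(c, name=f"bn{i}"), ReLU()]
            cin = c
        spatial = input_size // 16
        layers += [
            Flatten(),
            Linear(cin * spatial * spatial, fc_units, rng, name="fc0"),
            ReLU(),
            Dropout(dropout_p, rng),
            Linear(fc_units, out_units, rng, name="fc1"),
        ]
        self.net = Sequential(layers)
        self.input_size = input_size
        self.in_channels = in_channels

    def params(self) -> list[Param]:
        return self.net.params()

    def buffers(self) -> dict[str, np.ndarray]:
        return self.net.buffers()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x.astype(DTYPE), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)


def _block(cin: int, cout: int, rng: np.random.Generator, name: str) -> Sequential:
    return Sequential(
        [
            Conv2d(cin, cout, rng, name=f"{name}.c0"),
            BatchNorm2d(cout, name=f"{name}.b0"),
            ReLU(),
            Conv2d(cout, cout, rng, name=f"{name}.c1"),
            BatchNorm2d(cout, name=f"{name}.b1"),
            ReLU(),
        ]
    )


class UNet(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        base: int = 32,
        depth: int = 4,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.in_channels = in_channels
        self.enc: list[Sequential] = []
        self.pools = [MaxPool2d() for _ in range(depth)]
        cin = in_channels
        for i in range(depth):
            c = base * 2**i
            self.enc.append(_block(cin, c, rng, f"enc{i}"))
            cin = c
        self.bottleneck = _block(cin, base * 2**depth, rng, "bott")
        self.ups: list[Upsample2x] = []
        self.reduces: list[Conv2d] = []
        self.dec: list[Sequential] = []
        cup = base * 2**depth
        for i in reversed(range(depth)):
            c = base * 2**i
            self.ups.append(Upsample2x())
            self.reduces.append(Conv2d(cup, c, rng, name=f"red{i}"))
            self.dec.append(_block(2 * c, c, rng, f"dec{i}"))
            cup = c
        self.head = Conv2d(base, out_channels, rng, k=1, name="head")

    def _modules(self) -> list[Layer]:
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.reduces, *self.dec, self.head]

    def params(self) -> list[Param]:
        return [p for m in self._modules() for p in m.params()]

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for j, m in enumerate(self._modules()):
            for k, v in m.buffers().items():
                out[f"m{j}.{k}"] = v
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = x.astype(DTYPE)
        skips = []
        for i in range(self.depth):
            x = self.enc[i].forward(x, train)
            skips.append(x)
            x = self.pools[i].forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for j, i in enumerate(reversed(range(self.depth))):
            x = self.ups[j].forward(x, train)
            x = self.reduces[j].forward(x, train)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[j].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(self.depth)):
            i = self.depth - 1 - j
            g = self.dec[j].backward(grad)
            c = self._skip_channels[i]
            skip_grads[i] = g[:, :c]
            g = self.reduces[j].backward(np.ascontiguousarray(g[:, c:]))
            grad = self.ups[j].backward(g)
        grad = self.bottleneck.backward(grad)
        for i in reversed(range(self.depth)):
            g = self.pools[i].backward(grad)
            g = g + skip_grads[i]
            grad = self.enc[i].backward(g)
        return grad
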
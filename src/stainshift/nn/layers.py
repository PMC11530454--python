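"""Network building blocks: convolution modules and ResNet-style backbones.

Backbones expose the feature maps of their second, third and fourth stages
(strides 1/8, 1/16, 1/32 for the ResNet family; 1/4, 1/8, 1/16 for the
``tiny`` desk-scale backbone), matching the three-level feature pyramids
used by the detectors in this package.
"""

from __future__ import annotations

import numpy as np

from .autograd import AdamW, Tensor, conv2d, maxpool2x

__all__ = ["Module", "Conv2d", "ConvBlock", "Linear", "TinyBackbone",
           "ResNetBackbone", "count_parameters", "AdamW"]


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []

        def collect(v):
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in self.__dict__.values():
            collect(v)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data[...] = state[str(i)]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng or np.random.default_rng(0)
        # He initialisation for ReLU networks
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.weight = Tensor(rng.normal(0.0, std, size=(cin, cout)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class ConvBlock(Module):
    """3x3 conv + ReLU."""

    def __init__(self, cin: int, cout: int, stride: int, rng):
        self.conv = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x).relu()


class TinyBackbone(Module):
    """Desk-scale backbone: a stem plus three single-conv stages.

    Emits stage outputs at strides 4, 8 and 16 with the configured channel
    widths; spatial sizes strictly halve from one emitted level to the next.
    """

    strides = (4, 8, 16)

    def __init__(self, channels=(12, 16, 24, 32), rng=None):
        rng = rng or np.random.default_rng(0)
        c0, c1, c2, c3 = channels
        self.stem = ConvBlock(3, c0, 2, rng)
        self.stage2 = ConvBlock(c0, c1, 2, rng)
        self.stage3 = ConvBlock(c1, c2, 2, rng)
        self.stage4 = ConvBlock(c2, c3, 2, rng)
        self.out_channels = (c1, c2, c3)

    def __call__(self, x: Tensor) -> list[Tensor]:
        s = self.stem(x)
        l2 = self.stage2(s)
        l3 = self.stage3(l2)
        l4 = self.stage4(l3)
        return [l2, l3, l4]


class _BasicBlock(Module):
    expansion = 1

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng)
        self.down = Conv2d(cin, cout, 1, stride=stride, rng=rng) \
            if (stride != 1 or cin != cout) else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).relu())
        sc = self.down(x) if self.down is not None else x
        return (y + sc).relu()


class _Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, cout, stride, rng):
        self.conv1 = Conv2d(cin, cout, 1, rng=rng)
        self.conv2 = Conv2d(cout, cout, 3, stride=stride, pad=1, rng=rng)
        self.conv3 = Conv2d(cout, cout * 4, 1, rng=rng)
        self.down = Conv2d(cin, cout * 4, 1, stride=stride, rng=rng) \
            if (stride != 1 or cin != cout * 4) else None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv1(x).relu()
        y = self.conv2(y).relu()
        y = self.conv3(y)
        sc = self.down(x) if self.down is not None else x
        return (y + sc).relu()


_RESNET_SPECS = {
    "resnet18": (_BasicBlock, (2, 2, 2, 2)),
    "resnet101": (_Bottleneck, (3, 4, 23, 3)),
}


class ResNetBackbone(Module):
    """ResNet-18/101 feature stem emitting the stage-2/3/4 feature maps.

    For a 512x512 input the ResNet-18 variant yields 64^2, 32^2 and 16^2
    maps with 128, 256 and 512 channels; batch-norm layers are folded away
    (affine behaviour is absorbed into the conv biases), which leaves the
    per-stage shapes and parameter ordering of the reference design intact.
    """

    strides = (8, 16, 32)

    def __init__(self, arch: str = "resnet18", rng=None):
        if arch not in _RESNET_SPECS:
            raise ValueError(f"unknown backbone architecture: {arch!r}")
        rng = rng or np.random.default_rng(0)
        block, layers = _RESNET_SPECS[arch]
        self.conv1 = Conv2d(3, 64, 7, stride=2, pad=3, rng=rng)
        widths = (64, 128, 256, 512)
        self.stages = []
        cin = 64
        for i, (w, n) in enumerate(zip(widths, layers)):
            stride = 1 if i == 0 else 2
            blocks = [block(cin, w, stride, rng)]
            cin = w * block.expansion
            for _ in range(n - 1):
                blocks.append(block(cin, w, 1, rng))
            self.stages.append(blocks)
        e = block.expansion
        self.out_channels = (128 * e, 256 * e, 512 * e)

    def __call__(self, x: Tensor) -> list[Tensor]:
        y = self.conv1(x).relu()
        y = maxpool2x(y)
        outs = []
        for i, blocks in enumerate(self.stages):
            for b in blocks:
                y = b(y)
            if i >= 1:  # stages 2, 3, 4
                outs.append(y)
        return outs


def make_backbone(name: str, rng=None, tiny_channels=(12, 16, 24, 32)):
    if name == "tiny":
        return TinyBackbone(channels=tiny_channels, rng=rng)
    return ResNetBackbone(name, rng=rng)


def count_parameters(module: Module) -> int:
    return int(sum(p.data.size for p in module.parameters()))
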
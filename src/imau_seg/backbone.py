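"""InceptionV3-style encoder with named ``mixed0`` … ``mixed10`` endpoints.

The block structure and channel widths follow the canonical InceptionV3
(stem, three 35x35 inception-A blocks, grid reduction, four 17x17
inception-B blocks with factorized 7x7 convolutions, a second reduction,
and two 8x8 inception-C blocks), with two deliberate deviations:

* every convolution and pooling uses ``same`` padding so that a 256x256
  input yields clean power-of-two grids (mixed0 at 32x32, mixed3/mixed6 at
  16x16, mixed10 at 8x8) instead of the odd 35/17/8 sizes of the
  299-convention network;
* weights are seeded random draws — ImageNet weights are an optional
  download this package does not perform, and requesting them raises
  :class:`~imau_seg.errors.PretrainedWeightsUnavailable`.

The four endpoints tapped as decoder skip connections are ``mixed0``
(width 256), ``mixed3`` (768), ``mixed6`` (768) and ``mixed10`` (2048);
their channel widths are those of the real network, scaled by the
encoder's width multiplier.
"""

from __future__ import annotations

import numpy as np

from .errors import PretrainedWeightsUnavailable
from .nn import ConvBNReLU, MaxPool2D, AvgPool2D, Module, Tensor
from .nn.ops import concat

__all__ = ["InceptionV3Encoder", "build_encoder_taps"]

TAP_NAMES = ("mixed0", "mixed3", "mixed6", "mixed10")


def _width(mult: float):
    def w(c: int) -> int:
        return max(1, int(round(c * mult)))

    return w


class _InceptionA(Module):
    """35x35-grid block: 1x1 / 5x5 / double-3x3 / pooled branches."""

    def __init__(self, cin, pool_ch, rng, w):
        self.b1 = ConvBNReLU(cin, w(64), 1, rng=rng)
        self.b5_1 = ConvBNReLU(cin, w(48), 1, rng=rng)
        self.b5_2 = ConvBNReLU(w(48), w(64), 5, rng=rng)
        self.b3_1 = ConvBNReLU(cin, w(64), 1, rng=rng)
        self.b3_2 = ConvBNReLU(w(64), w(96), 3, rng=rng)
        self.b3_3 = ConvBNReLU(w(96), w(96), 3, rng=rng)
        self.pool = AvgPool2D(3, 1)
        self.bp = ConvBNReLU(cin, w(pool_ch), 1, rng=rng)
        self.out_channels = w(64) + w(64) + w(96) + w(pool_ch)

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b1(x),
                self.b5_2(self.b5_1(x)),
                self.b3_3(self.b3_2(self.b3_1(x))),
                self.bp(self.pool(x)),
            ]
        )


class _ReductionA(Module):
    """Grid reduction to 17x17 (mixed3)."""

    def __init__(self, cin, rng, w):
        self.b3 = ConvBNReLU(cin, w(384), 3, stride=2, rng=rng)
        self.bd_1 = ConvBNReLU(cin, w(64), 1, rng=rng)
        self.bd_2 = ConvBNReLU(w(64), w(96), 3, rng=rng)
        self.bd_3 = ConvBNReLU(w(96), w(96), 3, stride=2, rng=rng)
        self.pool = MaxPool2D(3, 2)
        self.out_channels = w(384) + w(96) + cin

    def forward(self, x: Tensor) -> Tensor:
        return concat([self.b3(x), self.bd_3(self.bd_2(self.bd_1(x))), self.pool(x)])


class _InceptionB(Module):
    """17x17-grid block with factorized 7x7 convolutions."""

    def __init__(self, cin, mid, rng, w):
        self.b1 = ConvBNReLU(cin, w(192), 1, rng=rng)
        self.b7_1 = ConvBNReLU(cin, w(mid), 1, rng=rng)
        self.b7_2 = ConvBNReLU(w(mid), w(mid), (1, 7), rng=rng)
        self.b7_3 = ConvBNReLU(w(mid), w(192), (7, 1), rng=rng)
        self.bd_1 = ConvBNReLU(cin, w(mid), 1, rng=rng)
        self.bd_2 = ConvBNReLU(w(mid), w(mid), (7, 1), rng=rng)
        self.bd_3 = ConvBNReLU(w(mid), w(mid), (1, 7), rng=rng)
        self.bd_4 = ConvBNReLU(w(mid), w(mid), (7, 1), rng=rng)
        self.bd_5 = ConvBNReLU(w(mid), w(192), (1, 7), rng=rng)
        self.pool = AvgPool2D(3, 1)
        self.bp = ConvBNReLU(cin, w(192), 1, rng=rng)
        self.out_channels = 4 * w(192)

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b1(x),
                self.b7_3(self.b7_2(self.b7_1(x))),
                self.bd_5(self.bd_4(self.bd_3(self.bd_2(self.bd_1(x))))),
                self.bp(self.pool(x)),
            ]
        )


class _ReductionB(Module):
    """Grid reduction to 8x8 (mixed8)."""

    def __init__(self, cin, rng, w):
        self.b3_1 = ConvBNReLU(cin, w(192), 1, rng=rng)
        self.b3_2 = ConvBNReLU(w(192), w(320), 3, stride=2, rng=rng)
        self.b7_1 = ConvBNReLU(cin, w(192), 1, rng=rng)
        self.b7_2 = ConvBNReLU(w(192), w(192), (1, 7), rng=rng)
        self.b7_3 = ConvBNReLU(w(192), w(192), (7, 1), rng=rng)
        self.b7_4 = ConvBNReLU(w(192), w(192), 3, stride=2, rng=rng)
        self.pool = MaxPool2D(3, 2)
        self.out_channels = w(320) + w(192) + cin

    def forward(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b3_2(self.b3_1(x)),
                self.b7_4(self.b7_3(self.b7_2(self.b7_1(x)))),
                self.pool(x),
            ]
        )


class _InceptionC(Module):
    """8x8-grid block with split 3x3 branches."""

    def __init__(self, cin, rng, w):
        self.b1 = ConvBNReLU(cin, w(320), 1, rng=rng)
        self.b3_1 = ConvBNReLU(cin, w(384), 1, rng=rng)
        self.b3_2a = ConvBNReLU(w(384), w(384), (1, 3), rng=rng)
        self.b3_2b = ConvBNReLU(w(384), w(384), (3, 1), rng=rng)
        self.bd_1 = ConvBNReLU(cin, w(448), 1, rng=rng)
        self.bd_2 = ConvBNReLU(w(448), w(384), 3, rng=rng)
        self.bd_3a = ConvBNReLU(w(384), w(384), (1, 3), rng=rng)
        self.bd_3b = ConvBNReLU(w(384), w(384), (3, 1), rng=rng)
        self.pool = AvgPool2D(3, 1)
        self.bp = ConvBNReLU(cin, w(192), 1, rng=rng)
        self.out_channels = w(320) + 4 * w(384) + w(192)

    def forward(self, x: Tensor) -> Tensor:
        s = self.b3_1(x)
        d = self.bd_2(self.bd_1(x))
        return concat(
            [
                self.b1(x),
                concat([self.b3_2a(s), self.b3_2b(s)]),
                concat([self.bd_3a(d), self.bd_3b(d)]),
                self.bp(self.pool(x)),
            ]
        )


class InceptionV3Encoder(Module):
    def __init__(
        self,
        width: float = 1.0,
        pretrained: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        if pretrained:
            raise PretrainedWeightsUnavailable(
                "ImageNet weights for the InceptionV3 encoder are not bundled; "
                "build with pretrained_backbone=False for seeded random "
                "initialization (offline mode)."
            )
        rng = rng or np.random.default_rng(0)
        w = _width(width)
        self.stem = [
            ConvBNReLU(3, w(32), 3, stride=2, rng=rng),
            ConvBNReLU(w(32), w(32), 3, rng=rng),
            ConvBNReLU(w(32), w(64), 3, rng=rng),
            MaxPool2D(3, 2),
            ConvBNReLU(w(64), w(80), 1, rng=rng),
            ConvBNReLU(w(80), w(192), 3, rng=rng),
            MaxPool2D(3, 2),
        ]
        blocks: list[Module] = []
        cin = w(192)
        for pool_ch in (32, 64, 64):  # mixed0..mixed2
            blk = _InceptionA(cin, pool_ch, rng, w)
            blocks.append(blk)
            cin = blk.out_channels
        blocks.append(_ReductionA(cin, rng, w))  # mixed3
        cin = blocks[-1].out_channels
        for mid in (128, 160, 160, 192):  # mixed4..mixed7
            blk = _InceptionB(cin, mid, rng, w)
            blocks.append(blk)
            cin = blk.out_channels
        blocks.append(_ReductionB(cin, rng, w))  # mixed8
        cin = blocks[-1].out_channels
        for _ in range(2):  # mixed9, mixed10
            blk = _InceptionC(cin, rng, w)
            blocks.append(blk)
            cin = blk.out_channels
        self.blocks = blocks
        self.tap_channels = {
            "mixed0": blocks[0].out_channels,
            "mixed3": blocks[3].out_channels,
            "mixed6": blocks[6].out_channels,
            "mixed10": blocks[10].out_channels,
        }

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_taps(x)["mixed10"]

    def forward_taps(self, x: Tensor) -> dict[str, Tensor]:
        """Run the encoder, returning the four skip-connection endpoints."""
        for layer in self.stem:
            x = layer(x)
        taps: dict[str, Tensor] = {}
        for i, blk in enumerate(self.blocks):
            x = blk(x)
            name = f"mixed{i}"
            if name in TAP_NAMES:
                taps[name] = x
        return taps


def build_encoder_taps(
    pretrained: bool = False,
    width: float = 1.0,
    seed: int = 0,
    input_size: tuple[int, int] = (256, 256),
):
    """Construct the backbone and record the actual tap shapes.

    Returns ``(encoder, shapes)`` where ``shapes`` maps each endpoint name
    to its (height, width, channels) for the given ``input_size``.  The
    shapes are measured by a forward pass, not assumed.
    """
    enc = InceptionV3Encoder(width=width, pretrained=pretrained,
                             rng=np.random.default_rng(seed))
    enc.eval()
    h, w = input_size
    dummy = Tensor(np.zeros((1, h, w, 3), np.float32))
    taps = enc.forward_taps(dummy)
    shapes = {name: tuple(t.shape[1:]) for name, t in taps.items()}
    enc.train()
    return enc, shapes
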
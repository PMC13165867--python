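"""Builders for the segmentation model family.

Four encoder–decoder variants share one decoder design:

``inceptionv3_unet``
    InceptionV3 encoder taps + plain decoder (the baseline).
``mcp_unet``
    Plain convolutional encoder + Multi-Core Pooling bottleneck: three
    parallel stride-1 same-padded max pools (kernels 2/3/5), each followed
    by a learnable 1x1 convolution, channel-concatenated (768 channels at
    default width).
``aspp_unet``
    Plain encoder + improved atrous spatial pyramid pooling bottleneck:
    four 3x3 dilated convolutions (rates 2/4/6/8) plus a global-average-
    pooling branch, concatenated to 1280 channels and reduced to 512 by a
    1x1 convolution.
``imau_net``
    InceptionV3 taps + the two bottlenecks fused by channel concatenation
    (768 + 512 = 1280 channels at defaults).

Decoder stages are transposed convolution (stride 2) -> resize the skip tap
to the current grid -> concatenate -> two 3x3 convolutions; skip-tap
spatial sizes therefore never need to match exactly.  The head is a 1x1
convolution with sigmoid, after upsampling back to the input resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .backbone import InceptionV3Encoder, build_encoder_taps  # noqa: F401
from .errors import ConfigurationError
from .nn import Conv2D, ConvBNReLU, ConvTranspose2D, MaxPool2D, Module, Tensor
from .nn.ops import (
    broadcast_hw,
    concat,
    global_avg_pool,
    relu,
    resize_bilinear,
    sigmoid,
)

__all__ = [
    "VARIANTS",
    "ArchitectureSpec",
    "MCPBlock",
    "ASPPBlock",
    "Model",
    "build_mcp_block",
    "build_aspp_block",
    "build_model",
]

VARIANTS = ("inceptionv3_unet", "mcp_unet", "aspp_unet", "imau_net")


@dataclass
class ArchitectureSpec:
    """Declarative description of which variant to build.

    ``width_multiplier`` scales every filter count in the network (rounded,
    minimum 1); 1.0 reproduces the published widths, small values give
    desk-scale models that train on a CPU.
    """

    variant: str = "imau_net"
    input_size: tuple[int, int, int] = (256, 256, 3)
    mcp_kernels: tuple[int, ...] = (2, 3, 5)
    aspp_dilations: tuple[int, ...] = (2, 4, 6, 8)
    branch_filters: int = 256
    aspp_reduced_filters: int = 512
    decoder_filters: tuple[int, ...] = (768, 384, 288, 144, 256, 64)
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512)
    final_up_filters: tuple[int, ...] = (64, 32)
    width_multiplier: float = 1.0
    pretrained_backbone: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"variant: unknown variant {self.variant!r}; valid: {VARIANTS}"
            )
        if any(k < 1 for k in self.mcp_kernels):
            raise ConfigurationError("mcp_kernels: all kernels must be positive")
        if any(b <= a for a, b in zip(self.aspp_dilations, self.aspp_dilations[1:])):
            raise ConfigurationError(
                "aspp_dilations: dilation rates must be strictly increasing"
            )
        if not (0.0 < self.width_multiplier <= 1.0):
            raise ConfigurationError("width_multiplier: must be in (0, 1]")
        if self.branch_filters < 1 or self.aspp_reduced_filters < 1:
            raise ConfigurationError("branch_filters: filter counts must be >= 1")
        if len(self.decoder_filters) != 6:
            raise ConfigurationError(
                "decoder_filters: expected 6 values "
                "(transpose/conv filters for three stages)"
            )

    def scaled(self, channels: int) -> int:
        return max(1, int(round(channels * self.width_multiplier)))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ArchitectureSpec":
        d = json.loads(payload)
        for key in (
            "input_size",
            "mcp_kernels",
            "aspp_dilations",
            "decoder_filters",
            "encoder_filters",
            "final_up_filters",
        ):
            d[key] = tuple(d[key])
        return cls(**d)


class MCPBlock(Module):
    """Parallel stride-1 max pools + learnable 1x1 convs, concatenated.

    Output channels = len(kernels) x branch_filters, spatial size preserved.
    Each convolution is followed by batch normalization and ReLU.
    """

    def __init__(self, in_channels: int, spec: ArchitectureSpec,
                 rng: np.random.Generator | None = None) -> None:
        if in_channels < 1:
            raise ConfigurationError("in_channels: must be >= 1")
        bf = spec.scaled(spec.branch_filters)
        self.kernels = tuple(sorted(spec.mcp_kernels))
        self.pools = [MaxPool2D(k, stride=1, padding="same") for k in self.kernels]
        self.convs = [
            ConvBNReLU(in_channels, bf, 1, rng=rng) for _ in self.kernels
        ]
        self.out_channels = len(self.kernels) * bf

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[1], x.shape[2]
        biggest = self.kernels[-1]
        if biggest > h or biggest > w:
            raise ConfigurationError(
                f"mcp_kernels: kernel {biggest} exceeds the {h}x{w} input grid"
            )
        return concat([conv(pool(x)) for pool, conv in zip(self.pools, self.convs)])


class ASPPBlock(Module):
    """Improved atrous spatial pyramid pooling bottleneck.

    Four dilated 3x3 convolutions plus a global-average-pool branch
    (1x1 conv, broadcast back to the grid), concatenated and reduced by a
    1x1 convolution.  ``concat_channels``/``out_channels`` record the two
    endpoint widths.
    """

    def __init__(self, in_channels: int, spec: ArchitectureSpec,
                 rng: np.random.Generator | None = None) -> None:
        if in_channels < 1:
            raise ConfigurationError("in_channels: must be >= 1")
        bf = spec.scaled(spec.branch_filters)
        self.branches = [
            ConvBNReLU(in_channels, bf, 3, dilation=r, rng=rng)
            for r in spec.aspp_dilations
        ]
        self.gap_conv = ConvBNReLU(in_channels, bf, 1, rng=rng)
        self.reduce = ConvBNReLU(
            (len(self.branches) + 1) * bf, spec.scaled(spec.aspp_reduced_filters),
            1, rng=rng,
        )
        self.concat_channels = (len(self.branches) + 1) * bf
        self.out_channels = spec.scaled(spec.aspp_reduced_filters)

    def forward_detail(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return (five-branch concatenation, reduced output)."""
        h, w = x.shape[1], x.shape[2]
        outs = [b(x) for b in self.branches]
        gap = broadcast_hw(self.gap_conv(global_avg_pool(x)), (h, w))
        cat = concat(outs + [gap])
        return cat, self.reduce(cat)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_detail(x)[1]


def build_mcp_block(in_channels: int, spec: ArchitectureSpec,
                    seed: int = 0) -> MCPBlock:
    return MCPBlock(in_channels, spec, np.random.default_rng(seed))


def build_aspp_block(in_channels: int, spec: ArchitectureSpec,
                     seed: int = 0) -> ASPPBlock:
    return ASPPBlock(in_channels, spec, np.random.default_rng(seed))


class _DecoderStage(Module):
    """Transposed conv (stride 2, ReLU) -> resized-skip concat -> two 3x3 convs."""

    def __init__(self, in_channels, skip_channels, t_filters, c_filters, rng):
        self.up = ConvTranspose2D(in_channels, t_filters, 3, stride=2, rng=rng)
        self.c1 = Conv2D(t_filters + skip_channels, c_filters, 3, rng=rng)
        self.c2 = Conv2D(c_filters, c_filters, 3, rng=rng)
        self.out_channels = c_filters

    def forward_with_skip(self, x: Tensor, skip: Tensor) -> Tensor:
        u = relu(self.up(x))
        s = resize_bilinear(skip, (u.shape[1], u.shape[2]))
        z = relu(self.c1(concat([u, s])))
        return relu(self.c2(z))


class _BackboneUNet(Module):
    """InceptionV3-tap variants: the baseline and the fused-bottleneck model."""

    SKIP_ORDER = ("mixed6", "mixed3", "mixed0")

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        self.encoder = InceptionV3Encoder(
            width=spec.width_multiplier, pretrained=spec.pretrained_backbone, rng=rng
        )
        ch = self.encoder.tap_channels
        if spec.variant == "imau_net":
            self.mcp = MCPBlock(ch["mixed10"], spec, rng)
            self.aspp = ASPPBlock(ch["mixed10"], spec, rng)
            bott_ch = self.mcp.out_channels + self.aspp.out_channels
        else:
            self.mcp = self.aspp = None
            bott_ch = ch["mixed10"]
        self.bottleneck_channels = bott_ch
        df = [spec.scaled(f) for f in spec.decoder_filters]
        skip_ch = [ch[name] for name in self.SKIP_ORDER]
        self.stages = []
        cin = bott_ch
        for (t_f, c_f), s_ch in zip(zip(df[0::2], df[1::2]), skip_ch):
            stage = _DecoderStage(cin, s_ch, t_f, c_f, rng)
            self.stages.append(stage)
            cin = stage.out_channels
        f0, f1 = (spec.scaled(f) for f in spec.final_up_filters)
        self.up_final1 = ConvTranspose2D(cin, f0, 3, stride=2, rng=rng)
        self.up_final2 = ConvTranspose2D(f0, f1, 3, stride=2, rng=rng)
        self.head = Conv2D(f1, 1, 1, rng=rng)

    def forward(self, x: Tensor, disable_skips: tuple[str, ...] = ()) -> Tensor:
        return self.forward_with_endpoints(x, disable_skips)[0]

    def forward_with_endpoints(
        self, x: Tensor, disable_skips: tuple[str, ...] = ()
    ):
        h, w = x.shape[1], x.shape[2]
        taps = self.encoder.forward_taps(x)
        c4 = taps["mixed10"]
        if self.mcp is not None:
            bott = concat([self.mcp(c4), self.aspp(c4)])
        else:
            bott = c4
        endpoints: dict[str, Tensor] = {"bottleneck": bott}
        z = bott
        for i, (stage, name) in enumerate(zip(self.stages, self.SKIP_ORDER), 1):
            skip = taps[name]
            if name in disable_skips:
                skip = Tensor(np.zeros_like(skip.data))
            z = stage.forward_with_skip(z, skip)
            endpoints[f"d{i}"] = z
        z = relu(self.up_final1(z))
        z = relu(self.up_final2(z))
        z = resize_bilinear(z, (h, w))
        y = sigmoid(self.head(z))
        endpoints["output"] = y
        return y, endpoints


class _PlainUNet(Module):
    """Plain convolutional encoder + MCP or ASPP bottleneck + mirrored decoder."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator):
        self.spec = spec
        filters = [spec.scaled(f) for f in spec.encoder_filters]
        self.enc_blocks = []
        cin = spec.input_size[2]
        for f in filters:
            self.enc_blocks.append(
                [Conv2D(cin, f, 3, rng=rng), Conv2D(f, f, 3, rng=rng)]
            )
            cin = f
        self.pool = MaxPool2D(2, stride=2, padding="same")
        if spec.variant == "mcp_unet":
            self.bottleneck = MCPBlock(cin, spec, rng)
        else:
            self.bottleneck = ASPPBlock(cin, spec, rng)
        self.bottleneck_channels = self.bottleneck.out_channels
        self.stages = []
        z_ch = self.bottleneck.out_channels
        for f in reversed(filters):
            stage = _DecoderStage(z_ch, f, f, f, rng)
            self.stages.append(stage)
            z_ch = f
        self.head = Conv2D(z_ch, 1, 1, rng=rng)

    def forward(self, x: Tensor, disable_skips: tuple[str, ...] = ()) -> Tensor:
        return self.forward_with_endpoints(x, disable_skips)[0]

    def forward_with_endpoints(
        self, x: Tensor, disable_skips: tuple[str, ...] = ()
    ):
        h, w = x.shape[1], x.shape[2]
        skips: list[Tensor] = []
        z = x
        for c1, c2 in self.enc_blocks:
            z = relu(c2(relu(c1(z))))
            skips.append(z)
            z = self.pool(z)
        bott = self.bottleneck(z)
        endpoints = {"bottleneck": bott}
        z = bott
        for i, (stage, skip) in enumerate(zip(self.stages, reversed(skips)), 1):
            name = f"s{len(skips) - i + 1}"
            if name in disable_skips:
                skip = Tensor(np.zeros_like(skip.data))
            z = stage.forward_with_skip(z, skip)
            endpoints[f"d{i}"] = z
        z = resize_bilinear(z, (h, w))
        y = sigmoid(self.head(z))
        endpoints["output"] = y
        return y, endpoints


class Model:
    """A built variant: forward contract (H, W, 3) in [0,1] -> (H, W, 1) in (0,1)."""

    def __init__(self, spec: ArchitectureSpec, net: Module, seed: int) -> None:
        self.spec = spec
        self.net = net
        self.seed = seed
        self.endpoints: dict[str, tuple[int, ...]] = {}

    @property
    def parameter_count(self) -> int:
        return self.net.n_parameters()

    @property
    def bottleneck_channels(self) -> int:
        return self.net.bottleneck_channels

    def train(self) -> "Model":
        self.net.train()
        return self

    def eval(self) -> "Model":
        self.net.eval()
        return self

    def forward(self, x, disable_skips: tuple[str, ...] = ()) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        y, endpoints = self.net.forward_with_endpoints(x, disable_skips)
        self.endpoints = {k: tuple(v.shape[1:]) for k, v in endpoints.items()}
        return y

    def predict(self, images: np.ndarray,
                disable_skips: tuple[str, ...] = ()) -> np.ndarray:
        """Probability maps for (H, W, 3) or (N, H, W, 3) inputs, in eval mode."""
        arr = np.asarray(images, np.float32)
        single = arr.ndim == 3
        if single:
            arr = arr[None]
        was_training = self.net.training
        self.net.eval()
        try:
            y = self.forward(Tensor(arr), disable_skips)
        finally:
            self.net.train(was_training)
        probs = y.data[..., 0]
        return probs[0] if single else probs

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        arrays = self.net.state_arrays()
        np.savez(
            path,
            spec_json=np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8),
            seed=np.asarray(self.seed),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as data:
            spec = ArchitectureSpec.from_json(bytes(data["spec_json"]).decode())
            seed = int(data["seed"])
            model = build_model(spec, seed=seed)
            model.net.load_state_arrays({k: data[k] for k in data.files})
        return model


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Model:
    """Construct a variant with seeded initialization."""
    rng = np.random.default_rng(seed)
    if spec.variant in ("inceptionv3_unet", "imau_net"):
        net: Module = _BackboneUNet(spec, rng)
    elif spec.variant in ("mcp_unet", "aspp_unet"):
        net = _PlainUNet(spec, rng)
    else:  # pragma: no cover - caught by spec validation
        raise ConfigurationError(f"unknown variant {spec.variant!r}; valid: {VARIANTS}")
    return Model(spec, net, seed)
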
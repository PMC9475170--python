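"""N-Net architecture: multi-scale pyramid input, attention-gated skip
connections, and a stackable dilated-convolution (SDC) bottleneck on a
U-shaped encoder-decoder backbone.

The network segments hypoechoic nodules in B-mode ultrasound frames.
Three additions distinguish it from a plain U-Net, each independently
switchable for ablation:

* **Multi-scale input** -- an image pyramid built with non-overlapping
  2x2 average pooling; each downscaled image is convolved and
  concatenated with the pooled features entering the matching encoder
  level, so every level sees the raw image at its own resolution.
* **Attention guidance** -- before each skip connection the encoder
  features are gated by a single-channel spatial mask computed from the
  pyramid image and the features themselves, suppressing background
  speckle.
* **SDC block** -- at the bottleneck, parallel cascades of 3x3 dilated
  convolutions (dilation stacks ``[1]``, ``[3]``, ``[1, 3]`` and
  ``[1, 3, 11]``, giving receptive fields 3, 7, 9 and 31 pixels) are
  summed with an identity skip, enlarging the receptive field without
  changing channel count or resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.modules import count_parameters  # noqa: F401  (re-exported)
from .nn.tensor import Tensor, as_tensor

DEFAULT_SDC_BRANCHES: tuple[tuple[int, ...], ...] = ((1,), (3,), (1, 3), (1, 3, 11))


@dataclass(frozen=True)
class LayerSpec:
    """A convolution layer abstracted to what matters for receptive-field
    arithmetic: kernel side ``kernel``, dilation ``dilation``, stride 1."""

    kernel: int
    dilation: int = 1
    stride: int = 1

    def __post_init__(self):
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError(f"kernel must be odd and >= 1, got {self.kernel}")
        if self.dilation < 1:
            raise ValueError(f"dilation must be >= 1, got {self.dilation}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")


def receptive_field(stack: list[LayerSpec] | tuple[LayerSpec, ...]) -> int:
    """Side length (pixels) of the theoretical receptive field of a
    stride-1 convolution cascade: ``1 + sum((k_i - 1) * d_i)``.

    For the four default SDC branches with 3x3 kernels this yields
    3, 7, 9 and 31.
    """
    if not stack:
        raise ValueError("stack must contain at least one layer")
    if any(s.stride != 1 for s in stack):
        raise ValueError("receptive_field assumes stride-1 stacks")
    return 1 + sum((s.kernel - 1) * s.dilation for s in stack)


def sdc_branch_specs(branches: tuple[tuple[int, ...], ...] = DEFAULT_SDC_BRANCHES,
                     kernel: int = 3) -> list[list[LayerSpec]]:
    """LayerSpec stacks for each SDC dilation branch (1x1 fusion excluded,
    it does not grow the receptive field)."""
    return [[LayerSpec(kernel, d) for d in branch] for branch in branches]


def impulse_footprint(stack: list[LayerSpec], pad_to: int | None = None) -> int:
    """Measured receptive-field side: propagate a unit impulse through an
    all-ones-kernel instantiation of ``stack`` and return the side length
    of the bounding box of non-zero output.

    Serves as a numerical check on :func:`receptive_field`; a forward
    convolution of the impulse with all-ones kernels marks exactly the
    output positions the centre pixel can influence, whose extent equals
    the extent of inputs influencing one output by symmetry.
    """
    side = pad_to or (receptive_field(stack) + 4)
    if side % 2 == 0:
        side += 1
    x = np.zeros((1, 1, side, side), dtype=np.float64)
    x[0, 0, side // 2, side // 2] = 1.0
    t = Tensor(x)
    with nn.no_grad():
        for spec in stack:
            w = Tensor(np.ones((1, 1, spec.kernel, spec.kernel), dtype=np.float64))
            t = F.conv2d(t, w, dilation=spec.dilation,
                         padding=spec.dilation * (spec.kernel - 1) // 2)
    rows = np.nonzero(t.data[0, 0].sum(axis=1))[0]
    cols = np.nonzero(t.data[0, 0].sum(axis=0))[0]
    h = int(rows[-1] - rows[0] + 1)
    w_ = int(cols[-1] - cols[0] + 1)
    if h != w_:
        raise RuntimeError(f"asymmetric footprint {h}x{w_} (grid too small?)")
    return h


@dataclass
class ArchitectureConfig:
    """Structural hyperparameters of the network.

    ``depth`` encoder levels with ``base_channels * 2**(i-1)`` channels at
    level ``i``; the bottleneck doubles once more.  The three ablation
    flags correspond to the multi-scale input layer, attention-gated
    skips and the SDC bottleneck; with all three off the build is a plain
    U-Net baseline.
    """

    depth: int = 4
    base_channels: int = 64
    input_size: int = 512
    sdc_branches: tuple[tuple[int, ...], ...] = DEFAULT_SDC_BRANCHES
    use_multiscale: bool = True
    use_attention: bool = True
    use_sdc: bool = True
    use_batchnorm: bool = True

    def __post_init__(self):
        self.sdc_branches = tuple(tuple(int(d) for d in b) for b in self.sdc_branches)
        self.validate()

    def validate(self) -> None:
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2 ** self.depth}")
        for branch in self.sdc_branches:
            if not branch:
                raise ValueError("every SDC branch needs at least one dilation rate")
            if any(d < 1 for d in branch):
                raise ValueError(f"dilation rates must be >= 1, got {branch}")

    def channels(self, level: int) -> int:
        """Channel width at encoder level ``level`` (1-based)."""
        return self.base_channels * 2 ** (level - 1)

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "input_size": self.input_size,
            "sdc_branches": [list(b) for b in self.sdc_branches],
            "use_multiscale": self.use_multiscale,
            "use_attention": self.use_attention,
            "use_sdc": self.use_sdc,
            "use_batchnorm": self.use_batchnorm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        if "sdc_branches" in d:
            d["sdc_branches"] = tuple(tuple(b) for b in d["sdc_branches"])
        return cls(**d)


ABLATION_CONFIGS: tuple[tuple[str, dict], ...] = (
    ("unet", dict(use_multiscale=False, use_attention=False, use_sdc=False)),
    ("ag_unet", dict(use_multiscale=False, use_attention=True, use_sdc=False)),
    ("ms_ag_unet", dict(use_multiscale=True, use_attention=True, use_sdc=False)),
    ("nnet", dict(use_multiscale=True, use_attention=True, use_sdc=True)),
)


def ablation_configs(**common) -> list[tuple[str, ArchitectureConfig]]:
    """The four ablation rows: plain U-Net, +attention, +multi-scale,
    +SDC (the full model), sharing all other hyperparameters."""
    return [(name, ArchitectureConfig(**{**common, **flags}))
            for name, flags in ABLATION_CONFIGS]


def multi_scale_pyramid(image, levels: int) -> list[np.ndarray]:
    """Image pyramid by repeated non-overlapping 2x2 average pooling.

    ``image`` is (..., H, W); level 1 is the input unchanged and level
    ``i`` has spatial dims divided by ``2**(i-1)``.  Global mean
    intensity is preserved exactly at every level.
    """
    arr = image.data if isinstance(image, Tensor) else np.asarray(image)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = arr.shape[-2], arr.shape[-1]
    factor = 2 ** (levels - 1)
    if h % factor:
        raise ValueError(f"height {h} not divisible by {factor} (axis -2)")
    if w % factor:
        raise ValueError(f"width {w} not divisible by {factor} (axis -1)")
    out = [arr]
    cur = arr
    for _ in range(levels - 1):
        lead = cur.shape[:-2]
        hh, ww = cur.shape[-2] // 2, cur.shape[-1] // 2
        cur = cur.reshape(*lead, hh, 2, ww, 2).mean(axis=(-3, -1))
        out.append(cur)
    return out


class ConvBlock(nn.Module):
    """``stages`` x (3x3 conv + [BN] + ReLU); two stages is the standard
    U-Net level block, one stage is used to lift pyramid images."""

    def __init__(self, in_ch: int, out_ch: int, batchnorm: bool, rng,
                 stages: int = 2):
        super().__init__()
        layers: list[nn.Module] = []
        for s in range(stages):
            cin = in_ch if s == 0 else out_ch
            layers.append(nn.Conv2d(cin, out_ch, 3, bias=not batchnorm, rng=rng))
            if batchnorm:
                layers.append(nn.BatchNorm2d(out_ch))
            layers.append(nn.ReLU())
        self.block = nn.Sequential(*layers)

    def forward(self, x):
        return self.block(x)


class AttentionGate(nn.Module):
    """Spatial attention over encoder features, guided by the pyramid image.

    ``g = sigmoid(conv1x1(relu(conv1x1(I_s) + conv1x1(F_m))))`` with a
    single gating channel; the gated output is ``g * F_m`` broadcast over
    channels.  Gating values are strictly inside (0, 1).
    """

    def __init__(self, feature_channels: int, rng, image_channels: int = 1,
                 inter_channels: int | None = None):
        super().__init__()
        inter = inter_channels or max(feature_channels // 2, 1)
        self.image_transform = nn.Conv2d(image_channels, inter, 1, rng=rng)
        self.feature_transform = nn.Conv2d(feature_channels, inter, 1, rng=rng)
        self.gate = nn.Conv2d(inter, 1, 1, rng=rng)

    def forward(self, scaled_image, features):
        scaled_image = as_tensor(scaled_image)
        if scaled_image.shape[-2:] != features.shape[-2:]:
            raise ValueError(
                f"spatial mismatch: image {scaled_image.shape[-2:]} vs "
                f"features {features.shape[-2:]}")
        mixed = F.relu(F.add(self.image_transform(scaled_image),
                             self.feature_transform(features)))
        g = F.sigmoid(self.gate(mixed))
        return F.mul(g, features)

    def gating_map(self, scaled_image, features) -> np.ndarray:
        """The (N, 1, H, W) attention coefficients alone, for inspection."""
        scaled_image = as_tensor(scaled_image)
        mixed = F.relu(F.add(self.image_transform(scaled_image),
                             self.feature_transform(features)))
        return F.sigmoid(self.gate(mixed)).data


class SDCBlock(nn.Module):
    """Stackable dilated convolutions: parallel branch cascades of 3x3
    dilated convs (padding = dilation keeps resolution), each closed by a
    1x1 conv + ReLU, summed together with an identity skip.  Input and
    output shapes are identical."""

    def __init__(self, channels: int, branches: tuple[tuple[int, ...], ...],
                 rng):
        super().__init__()
        if not branches:
            raise ValueError("SDC needs at least one branch")
        self.branches = []
        for bi, stack in enumerate(branches):
            if not stack:
                raise ValueError("every SDC branch stack must be nonempty")
            layers: list[nn.Module] = []
            for d in stack:
                layers += [nn.Conv2d(channels, channels, 3, dilation=d,
                                     padding=d, rng=rng), nn.ReLU()]
            layers += [nn.Conv2d(channels, channels, 1, rng=rng), nn.ReLU()]
            branch = nn.Sequential(*layers)
            self.branches.append(branch)
            self._modules[f"branch{bi}"] = branch

    def forward(self, x):
        out = x
        in_shape = x.shape
        for branch in self.branches:
            y = branch(x)
            if y.shape != in_shape:
                raise RuntimeError(
                    f"SDC branch changed shape {in_shape} -> {y.shape}")
            out = F.add(out, y)
        return out


class NNet(nn.Module):
    """The assembled segmentation network: 1-channel image in, 1-channel
    sigmoid probability map of identical spatial size out."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        d, bn = config.depth, config.use_batchnorm

        self.encoders = []
        self.ms_convs = []
        self.gates = []
        for i in range(1, d + 1):
            if i == 1:
                in_ch = 1
            else:
                in_ch = config.channels(i - 1)
                if config.use_multiscale:
                    ms = ConvBlock(1, in_ch, bn, rng, stages=1)
                    self.ms_convs.append(ms)
                    self._modules[f"ms{i}"] = ms
                    in_ch *= 2
            enc = ConvBlock(in_ch, config.channels(i), bn, rng)
            self.encoders.append(enc)
            self._modules[f"enc{i}"] = enc
            if config.use_attention:
                gate = AttentionGate(config.channels(i), rng)
                self.gates.append(gate)
                self._modules[f"gate{i}"] = gate

        bottleneck_ch = config.channels(d + 1)
        self.bottleneck = ConvBlock(config.channels(d), bottleneck_ch, bn, rng)
        if config.use_sdc:
            self.sdc = SDCBlock(bottleneck_ch, config.sdc_branches, rng)

        self.up_convs = []
        self.decoders = []
        for i in range(d, 0, -1):
            up = ConvBlock(config.channels(i + 1), config.channels(i), bn, rng)
            dec = ConvBlock(2 * config.channels(i), config.channels(i), bn, rng)
            self.up_convs.append(up)
            self.decoders.append(dec)
            self._modules[f"up{i}"] = up
            self._modules[f"dec{i}"] = dec

        self.head = nn.Conv2d(config.channels(1), 1, 1, rng=rng)

    def forward(self, x):
        x = as_tensor(x)
        cfg = self.config
        h, w = x.shape[-2:]
        if h % 2 ** cfg.depth or w % 2 ** cfg.depth:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth = {2 ** cfg.depth}")

        need_pyramid = cfg.use_multiscale or cfg.use_attention
        pyramid = multi_scale_pyramid(x.data, cfg.depth) if need_pyramid else None

        skips = []
        cur = x
        for i in range(1, cfg.depth + 1):
            if i > 1:
                cur = F.max_pool2x2(cur)
                if cfg.use_multiscale:
                    scale_img = Tensor(pyramid[i - 1])
                    cur = F.concat([cur, self.ms_convs[i - 2](scale_img)], axis=1)
            cur = self.encoders[i - 1](cur)
            skips.append(cur)

        cur = F.max_pool2x2(cur)
        cur = self.bottleneck(cur)
        if cfg.use_sdc:
            cur = self.sdc(cur)

        for j, i in enumerate(range(cfg.depth, 0, -1)):
            cur = F.upsample_bilinear2x(cur)
            cur = self.up_convs[j](cur)
            skip = skips[i - 1]
            if cfg.use_attention:
                skip = self.gates[i - 1](Tensor(pyramid[i - 1]), skip)
            cur = F.concat([cur, skip], axis=1)
            cur = self.decoders[j](cur)

        return F.sigmoid(self.head(cur))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps for a (N, 1, H, W) batch, eval mode, no grad."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(Tensor(np.asarray(images, dtype=np.float32))).data
        finally:
            self.train(was_training)
        return out


def build_model(config: ArchitectureConfig, seed: int = 0) -> NNet:
    """Assemble the network described by ``config`` with seeded weights."""
    return NNet(config, seed=seed)
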
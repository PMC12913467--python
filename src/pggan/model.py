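"""Conditional generator (3D U-Net with progress-map fusion) and discriminator.

The generator is a four-stage stride-2 encoder / four-stage decoder U-Net
with concatenation skips.  At full scale the encoder convolution pairs are
(in, 64), (64, 128), (128, 256), (256, 512); the decoder *block-level*
pairs — counting the concatenated skip in each block's output — are
(512, 512), (512, 256), (256, 128), (128, 64), i.e. the deconvolutions
themselves emit 256, 128, 64, 64 channels.  A final 1x1x1 convolution and a
tanh head map back to one channel in the signed intensity range.

Conditioning variants
---------------------
``none``          unconditioned baseline (image-to-image GAN).
``image_concat``  progress map stacked as a second input channel.
``ffm``           feature-wise fusion: a strided convolution of the map
                  yields spatial (scale, shift) that modulate the stage-1
                  features, out = scale * F + shift.
``ffm_parallel``  second fusion at stage 2, parameters computed from the
                  stage-1 *fused* feature maps.
``ffm_cascade``   second fusion at stage 2, parameters from a fresh conv
                  stack on the raw progress map.
``mffm``          multi-view fusion: map-derived and attribute-derived
                  (age, sex) modulation parameters added before modulating.
``attr_concat``   attribute vector tiled onto the bottleneck (mi-GAN).
``attr_film``     per-channel FiLM from attributes on the first three
                  encoder feature maps (FiLM-GAN).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor, concat
from .progress import ProgressMap
from .volume import Volume

__all__ = [
    "FUSION_MODES",
    "GeneratorSpec",
    "FeatureModulation",
    "ffm_modulate",
    "mffm_modulate",
    "Generator",
    "Discriminator",
    "predict_volume",
]

FUSION_MODES = (
    "none",
    "image_concat",
    "ffm",
    "ffm_parallel",
    "ffm_cascade",
    "mffm",
    "attr_concat",
    "attr_film",
)

MAP_MODES = ("image_concat", "ffm", "ffm_parallel", "ffm_cascade", "mffm")
ATTR_MODES = ("mffm", "attr_concat", "attr_film")


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Architectural configuration of the conditional generator.

    ``base_channels`` = 64 reproduces the full-scale channel schedule;
    smaller values (e.g. 8) give the desk-scale profile with every width
    divided proportionally.
    """

    fusion_mode: str = "none"
    base_channels: int = 64
    conv_kernel: int = 4
    conv_stride: int = 2
    attr_hidden: int = 64
    leaky_slope: float = 0.2

    def __post_init__(self) -> None:
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {self.fusion_mode!r}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be positive")

    @property
    def needs_map(self) -> bool:
        return self.fusion_mode in MAP_MODES

    @property
    def needs_attrs(self) -> bool:
        return self.fusion_mode in ATTR_MODES

    @property
    def input_channels(self) -> int:
        return 2 if self.fusion_mode == "image_concat" else 1

    @property
    def attribute_dims(self) -> int:
        return 2 if self.needs_attrs else 0

    @property
    def encoder_channels(self) -> list[tuple[int, int]]:
        b = self.base_channels
        return [(self.input_channels, b), (b, 2 * b), (2 * b, 4 * b), (4 * b, 8 * b)]

    @property
    def decoder_channels(self) -> list[tuple[int, int]]:
        """Block-level (input, output) pairs; outputs include the skip concat."""
        b = self.base_channels
        first_in = 8 * b + (self.attribute_dims if self.fusion_mode == "attr_concat" else 0)
        return [(first_in, 8 * b), (8 * b, 4 * b), (4 * b, 2 * b), (2 * b, b)]

    @property
    def deconv_out_channels(self) -> list[int]:
        b = self.base_channels
        return [4 * b, 2 * b, b, b]

    @property
    def map_conv(self) -> tuple[int, int, int, int]:
        """(in_channels, out_channels, kernel, stride) of the map-embedding conv."""
        return (1, 2 * self.base_channels, self.conv_kernel, self.conv_stride)


@dataclasses.dataclass
class FeatureModulation:
    """A (scale, shift) parameter pair for feature-wise modulation."""

    scale: Tensor
    shift: Tensor
    source: str = "map"  # map | attribute | combined

    def __post_init__(self) -> None:
        if self.source not in ("map", "attribute", "combined"):
            raise ValueError(f"unknown modulation source {self.source!r}")
        if not isinstance(self.scale, Tensor):
            self.scale = Tensor(np.asarray(self.scale))
        if not isinstance(self.shift, Tensor):
            self.shift = Tensor(np.asarray(self.shift))
        if self.scale.shape != self.shift.shape:
            raise ValueError("scale and shift must have identical shapes")


def _broadcastable(mod: FeatureModulation, fin: Tensor) -> tuple[Tensor, Tensor]:
    """Validate shapes; reshape per-channel attribute parameters for broadcast."""
    if mod.source == "attribute":
        if mod.scale.data.ndim != 2 or mod.scale.shape[:2] != fin.shape[:2]:
            raise ValueError(
                f"attribute modulation must be (batch, channels)={fin.shape[:2]}, "
                f"got {mod.scale.shape}"
            )
        extra = (1,) * (len(fin.shape) - 2)
        return (
            mod.scale.reshape(*mod.scale.shape, *extra),
            mod.shift.reshape(*mod.shift.shape, *extra),
        )
    if mod.scale.shape != fin.shape:
        raise ValueError(
            f"modulation shape {mod.scale.shape} does not match features {fin.shape}"
        )
    return mod.scale, mod.shift


def ffm_modulate(fin: Tensor, mod: FeatureModulation) -> Tensor:
    """Feature-wise fusion: out = scale * fin + shift, element-wise."""
    scale, shift = _broadcastable(mod, fin)
    return scale * fin + shift


def mffm_modulate(
    fin: Tensor, map_mod: FeatureModulation, attr_mod: FeatureModulation
) -> Tensor:
    """Multi-view fusion: out = (scale_a + scale_m) * fin + (shift_a + shift_m)."""
    ms, mb = _broadcastable(map_mod, fin)
    as_, ab = _broadcastable(attr_mod, fin)
    return (as_ + ms) * fin + (ab + mb)


def _split_mod(y: Tensor, channels: int, source: str) -> FeatureModulation:
    return FeatureModulation(
        scale=y[:, :channels], shift=y[:, channels : 2 * channels], source=source
    )


class Generator(nn.Module):
    """Progress-map-guided 3D U-Net generator."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        b = spec.base_channels
        k, s = spec.conv_kernel, spec.conv_stride
        enc = spec.encoder_channels
        self.enc_convs = [nn.Conv3d(ci, co, k, s, rng) for ci, co in enc]
        self.enc_bns = [nn.BatchNorm3d(co) for _, co in enc]
        dec_in = [spec.decoder_channels[0][0]] + [
            out for _, out in spec.decoder_channels[:-1]
        ]
        self.dec_convs = [
            nn.ConvTranspose3d(ci, co, k, s, rng)
            for ci, co in zip(dec_in, spec.deconv_out_channels)
        ]
        self.dec_bns = [nn.BatchNorm3d(co) for co in spec.deconv_out_channels]
        self.head = nn.Conv3d(b, 1, 1, 1, rng)

        if spec.fusion_mode in ("ffm", "ffm_parallel", "ffm_cascade", "mffm"):
            cin, cout, mk, ms = spec.map_conv
            self.map_conv = nn.Conv3d(cin, cout, mk, ms, rng)
        if spec.fusion_mode == "ffm_parallel":
            self.par_conv = nn.Conv3d(b, 4 * b, k, s, rng)
        if spec.fusion_mode == "ffm_cascade":
            self.cas_conv1 = nn.Conv3d(1, b, k, s, rng)
            self.cas_conv2 = nn.Conv3d(b, 4 * b, k, s, rng)
        if spec.fusion_mode == "mffm":
            self.attr_fc1 = nn.Dense(2, spec.attr_hidden, rng)
            self.attr_fc2 = nn.Dense(spec.attr_hidden, 2 * b, rng)
        if spec.fusion_mode == "attr_film":
            film_out = 2 * (b + 2 * b + 4 * b)
            self.film_fc1 = nn.Dense(2, spec.attr_hidden, rng)
            self.film_fc2 = nn.Dense(spec.attr_hidden, film_out, rng)
        self.training = True

    # -- condition plumbing ----------------------------------------------

    def map_to_modulation(self, map_tensor: Tensor) -> FeatureModulation:
        """Learned conv embeds the progress map into a stage-1 (scale, shift).

        The first half of the output channels are scaling parameters, the
        second half shifting parameters; the stride-2 conv makes the spatial
        dims match the stage-1 feature block exactly.
        """
        y = self.map_conv(map_tensor)
        return _split_mod(y, self.spec.base_channels, "map")

    def _attr_modulation(self, attrs: Tensor) -> FeatureModulation:
        h = self.attr_fc1(attrs).leaky_relu(self.spec.leaky_slope)
        y = self.attr_fc2(h)
        return _split_mod(y, self.spec.base_channels, "attribute")

    # -- forward -----------------------------------------------------------

    def __call__(
        self,
        x: Tensor,
        map_tensor: Tensor | None = None,
        attrs: Tensor | None = None,
    ) -> Tensor:
        spec = self.spec
        spatial = x.shape[2:]
        if min(spatial) < 16:
            raise ValueError(f"spatial dims {spatial} too small for four stride-2 stages")
        if spec.needs_map and map_tensor is None:
            raise ValueError(f"fusion mode {spec.fusion_mode!r} requires a progress map")
        if not spec.needs_map and map_tensor is not None:
            raise ValueError(f"fusion mode {spec.fusion_mode!r} takes no progress map")
        if spec.needs_attrs and attrs is None:
            raise ValueError(f"fusion mode {spec.fusion_mode!r} requires attributes")
        if not spec.needs_attrs and attrs is not None:
            raise ValueError(f"fusion mode {spec.fusion_mode!r} takes no attributes")

        slope = spec.leaky_slope
        if spec.fusion_mode == "image_concat":
            x = concat([x, map_tensor], axis=1)

        film = None
        if spec.fusion_mode == "attr_film":
            h = self.film_fc1(attrs).leaky_relu(slope)
            film = self.film_fc2(h)

        skips: list[Tensor] = []
        h = x
        film_off = 0
        stage1_fused: Tensor | None = None
        for stage, (conv, bn) in enumerate(zip(self.enc_convs, self.enc_bns)):
            h = bn(conv(h).leaky_relu(slope))
            h = self._fuse(stage, h, map_tensor, attrs, film, film_off, stage1_fused)
            if stage == 0:
                stage1_fused = h
            if spec.fusion_mode == "attr_film" and stage < 3:
                film_off += 2 * h.shape[1]
            skips.append(h)

        h = skips[-1]
        if spec.fusion_mode == "attr_concat":
            tiled = attrs.reshape(attrs.shape[0], attrs.shape[1], 1, 1, 1)
            ones = Tensor(np.ones((1, 1) + h.shape[2:], dtype=h.data.dtype))
            h = concat([h, tiled * ones], axis=1)

        for i, (deconv, bn) in enumerate(zip(self.dec_convs, self.dec_bns)):
            h = bn(deconv(h)).leaky_relu(slope)
            if i < 3:
                skip = skips[2 - i]
                h = _crop_to(h, skip.shape[2:])
                h = concat([h, skip], axis=1)
        return self.head(h).tanh()

    def _fuse(self, stage, h, map_tensor, attrs, film, film_off, stage1_fused):
        spec = self.spec
        mode = spec.fusion_mode
        if stage == 0 and mode in ("ffm", "ffm_parallel", "ffm_cascade"):
            return ffm_modulate(h, self.map_to_modulation(map_tensor))
        if stage == 0 and mode == "mffm":
            return mffm_modulate(
                h, self.map_to_modulation(map_tensor), self._attr_modulation(attrs)
            )
        if stage == 1 and mode == "ffm_parallel":
            # parameters derived from the stage-1 *fused* features
            y = self.par_conv(stage1_fused)
            return ffm_modulate(h, _split_mod(y, 2 * spec.base_channels, "map"))
        if stage == 1 and mode == "ffm_cascade":
            # parameters from a fresh conv stack on the raw map
            y = self.cas_conv2(self.cas_conv1(map_tensor).leaky_relu(spec.leaky_slope))
            return ffm_modulate(h, _split_mod(y, 2 * spec.base_channels, "map"))
        if mode == "attr_film" and stage < 3:
            c = h.shape[1]
            block = film[:, film_off : film_off + 2 * c]
            mod = FeatureModulation(
                scale=block[:, :c], shift=block[:, c : 2 * c], source="attribute"
            )
            return ffm_modulate(h, mod)
        return h


def _crop_to(t: Tensor, spatial: tuple[int, ...]) -> Tensor:
    """Crop trailing voxels so deconv outputs match odd-sized encoder stages."""
    if t.shape[2:] == tuple(spatial):
        return t
    sl = (slice(None), slice(None)) + tuple(slice(0, s) for s in spatial)
    return t[sl]


class Discriminator(nn.Module):
    """Unconditional real/fake discriminator.

    Four stride-2 convolution + leaky-ReLU stages — full-scale channel pairs
    (1, 32), (32, 64), (64, 128), (128, 256) — then two fully connected
    layers (1000 and 1 output nodes at full scale) and a sigmoid.
    """

    def __init__(
        self,
        input_shape: tuple[int, int, int],
        rng: np.random.Generator,
        base_channels: int = 32,
        fc_hidden: int | None = None,
        kernel: int = 4,
        stride: int = 2,
        leaky_slope: float = 0.2,
    ):
        self.input_shape = tuple(input_shape)
        self.leaky_slope = leaky_slope
        chans = [(1, base_channels), (base_channels, 2 * base_channels),
                 (2 * base_channels, 4 * base_channels),
                 (4 * base_channels, 8 * base_channels)]
        self.channel_pairs = chans
        self.convs = [nn.Conv3d(ci, co, kernel, stride, rng) for ci, co in chans]
        spatial = list(self.input_shape)
        for _ in chans:
            spatial = [-(-s // stride) for s in spatial]
        self.flat_dim = 8 * base_channels * int(np.prod(spatial))
        if fc_hidden is None:
            fc_hidden = max(1, round(1000 * base_channels / 32))
        self.fc1 = nn.Dense(self.flat_dim, fc_hidden, rng)
        self.fc2 = nn.Dense(fc_hidden, 1, rng)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if tuple(x.shape[2:]) != self.input_shape:
            raise ValueError(
                f"discriminator built for {self.input_shape}, got {x.shape[2:]}"
            )
        h = x
        for conv in self.convs:
            h = conv(h).leaky_relu(self.leaky_slope)
        h = h.reshape(h.shape[0], self.flat_dim)
        h = self.fc1(h).leaky_relu(self.leaky_slope)
        return self.fc2(h).sigmoid()


def predict_volume(
    gen: Generator,
    baseline: Volume,
    pmap: ProgressMap | None = None,
    attrs: np.ndarray | None = None,
) -> Volume:
    """Run the generator on one preprocessed (signed) baseline volume."""
    if baseline.intensity_range != "signed":
        raise ValueError("generator consumes signed [-1, 1] volumes")
    x = Tensor(baseline.data[None, None].astype(np.float32))
    m = None
    if pmap is not None:
        m = Tensor(pmap.data[None, None].astype(np.float32))
    a = None
    if attrs is not None:
        a = Tensor(np.asarray(attrs, dtype=np.float32)[None])
    gen.eval()
    out = gen(x, m, a)
    return baseline.with_data(
        np.clip(out.data[0, 0].astype(np.float64), -1.0, 1.0),
        intensity_range="signed",
        session="predicted",
    )
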
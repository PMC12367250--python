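"""Dual-channel 2D U-Net for fat/water MR slice segmentation.

The full preset follows the published architecture: 6 encoder blocks (each a
pair of same-padded 3x3 convolutions with LeakyReLU slope 0.01, followed by
2x2 max pooling), a (480, 480) bottleneck block, and 6 decoder blocks (2x2
transposed convolution, concatenation with the matching encoder feature map,
then a convolution pair), closed by a 1x1 convolution head.  Encoder filter
pairs are (32,32), (64,64), (128,128), (256,256), (480,480), (480,480); the
decoder mirrors them.  A 512x512 input reaches an 8x8 bottleneck.  The input
carries two channels (fat, water); single-channel ablation variants differ
only in ``in_channels``.

Class scores are unnormalized; inference applies softmax and argmax with
ties broken toward the lower class id (numpy argmax order).  When deep
supervision is enabled, auxiliary 1x1 heads emit score maps at the 1/2 and
1/4 decoder resolutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .imgio import CropPadTransform, DualVolume, LabelMask
from .schema import LabelSchema

FULL_ENCODER_FILTERS: Tuple[Tuple[int, int], ...] = (
    (32, 32), (64, 64), (128, 128), (256, 256), (480, 480), (480, 480))
FULL_BOTTLENECK: Tuple[int, int] = (480, 480)


@dataclass(frozen=True)
class NetConfig:
    in_channels: int = 2
    out_channels: int = 5
    encoder_filters: Tuple[Tuple[int, int], ...] = FULL_ENCODER_FILTERS
    bottleneck_filters: Tuple[int, int] = FULL_BOTTLENECK
    negative_slope: float = 0.01
    input_size: Tuple[int, int] = (512, 512)
    deep_supervision: bool = False
    strict_size: bool = True

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 2:
            raise ValueError("need >= 1 input channel and >= 2 classes")
        if len(self.encoder_filters) < 1:
            raise ValueError("need at least one encoder level")
        object.__setattr__(self, "encoder_filters",
                           tuple(tuple(f) for f in self.encoder_filters))
        object.__setattr__(self, "bottleneck_filters", tuple(self.bottleneck_filters))
        object.__setattr__(self, "input_size", tuple(self.input_size))
        div = 2 ** self.levels
        if self.strict_size and any(s % div for s in self.input_size):
            raise ValueError(f"input_size must be divisible by {div}")

    @property
    def levels(self) -> int:
        return len(self.encoder_filters)


def tiny_config(out_channels: int = 5, in_channels: int = 2,
                deep_supervision: bool = False) -> NetConfig:
    """Desk-scale preset: 4 levels, filters capped at 64, 128x128 nominal."""
    return NetConfig(
        in_channels=in_channels, out_channels=out_channels,
        encoder_filters=((16, 16), (32, 32), (64, 64), (64, 64)),
        bottleneck_filters=(64, 64), input_size=(128, 128),
        deep_supervision=deep_supervision,
    )


def full_config(region: str, in_channels: int = 2,
                deep_supervision: bool = False) -> NetConfig:
    """Published preset; abdomen head = 7 labels + background = 8 channels."""
    out = {"abdomen": 8, "thigh": 5}[region]
    return NetConfig(in_channels=in_channels, out_channels=out,
                     deep_supervision=deep_supervision)


class SegmentationModel:
    """U-Net graph over the numpy engine with explicit forward/backward."""

    def __init__(self, config: NetConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        a = config.negative_slope
        self.enc_blocks: List[nn.ConvBlock] = []
        self.pools: List[nn.MaxPool2x2] = []
        c = config.in_channels
        for filters in config.encoder_filters:
            self.enc_blocks.append(nn.ConvBlock(c, filters, rng, a))
            self.pools.append(nn.MaxPool2x2())
            c = filters[1]
        self.bottleneck = nn.ConvBlock(c, config.bottleneck_filters, rng, a)
        c = config.bottleneck_filters[1]
        self.ups: List[nn.ConvTranspose2x2] = []
        self.dec_blocks: List[nn.ConvBlock] = []
        for filters in reversed(config.encoder_filters):
            skip_c = filters[1]
            self.ups.append(nn.ConvTranspose2x2(c, skip_c, rng))
            self.dec_blocks.append(nn.ConvBlock(2 * skip_c, filters, rng, a))
            c = filters[1]
        self.head = nn.Conv2d(c, config.out_channels, 1, rng)
        # auxiliary heads at 1/2 and 1/4 resolution (finest-first order)
        self.aux_heads: List[nn.Conv2d] = []
        if config.deep_supervision:
            for lvl in (1, 2):
                if lvl < config.levels:
                    c_lvl = config.encoder_filters[lvl][1]
                    self.aux_heads.append(nn.Conv2d(c_lvl, config.out_channels, 1, rng))
        self._skips: List[np.ndarray] = []
        self._layers = (self.enc_blocks + self.pools + [self.bottleneck]
                        + self.ups + self.dec_blocks + [self.head] + self.aux_heads)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> List[np.ndarray]:
        """(B, C, H, W) -> [scores at full res, then aux scores coarse-ward]."""
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (B, {self.config.in_channels}, H, W), got {x.shape}")
        div = 2 ** self.config.levels
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial dims must be divisible by {div}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            s = block.forward(x)
            self._skips.append(s)
            x = pool.forward(s)
        x = self.bottleneck.forward(x)
        self.last_bottleneck_shape = tuple(x.shape[2:])
        dec_feats: List[np.ndarray] = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(self._skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x)
            dec_feats.append(x)
        outputs = [self.head.forward(x)]
        for i, aux in enumerate(self.aux_heads):
            # dec_feats are coarse->fine; level 1 is dec_feats[-2], level 2 [-3]
            outputs.append(aux.forward(dec_feats[-2 - i]))
        return outputs

    def backward(self, d_outputs: Sequence[np.ndarray]) -> None:
        """Accumulate parameter gradients given gradients w.r.t. each output."""
        # gradient flowing into each decoder feature map
        d_feat = {len(self.dec_blocks) - 1: self.head.backward(
            np.ascontiguousarray(d_outputs[0], dtype=np.float32))}
        for i, aux in enumerate(self.aux_heads):
            idx = len(self.dec_blocks) - 2 - i
            g = aux.backward(np.ascontiguousarray(d_outputs[1 + i], dtype=np.float32))
            d_feat[idx] = d_feat.get(idx, 0) + g
        dx = None
        d_skips: List[Optional[np.ndarray]] = [None] * len(self.enc_blocks)
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            g = d_feat.get(j)
            if g is None:
                g = dx
            elif dx is not None:
                g = g + dx
            g = self.dec_blocks[j].backward(np.ascontiguousarray(g, dtype=np.float32))
            skip_idx = len(self.enc_blocks) - 1 - j
            c_up = self.ups[j].params["w"].shape[1]
            d_up, d_skip = g[:, :c_up], g[:, c_up:]
            d_skips[skip_idx] = d_skip
            dx = self.ups[j].backward(np.ascontiguousarray(d_up))
        dx = self.bottleneck.backward(dx)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.pools[i].backward(dx)
            if d_skips[i] is not None:
                g = g + d_skips[i]
            dx = self.enc_blocks[i].backward(np.ascontiguousarray(g))

    # -- bookkeeping --------------------------------------------------------

    def parameter_count(self) -> int:
        return sum(int(v.size) for v in nn.collect_params(self._layers).values())

    def optimizer(self, momentum: float = 0.99) -> nn.SGDNesterov:
        return nn.SGDNesterov(self._layers, momentum)

    def save(self, path: Path) -> None:
        flat = nn.collect_params(self._layers)
        cfg = json.dumps(asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8), **flat)

    @classmethod
    def load(cls, path: Path) -> "SegmentationModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            model = cls(NetConfig(**{k: v for k, v in cfg.items()}))
            nn.load_params(model._layers, {k: data[k] for k in data.files
                                           if k != "__config__"})
        return model


def build_unet(config: NetConfig, seed: int = 0) -> SegmentationModel:
    """Construct a He-initialized model from its declared configuration."""
    return SegmentationModel(config, seed=seed)


def declared_conv_shapes(config: NetConfig) -> List[Tuple[int, int, int]]:
    """(k, c_in, c_out) for every convolutional layer the config declares."""
    shapes: List[Tuple[int, int, int]] = []
    c = config.in_channels
    for f in config.encoder_filters:
        shapes += [(3, c, f[0]), (3, f[0], f[1])]
        c = f[1]
    shapes += [(3, c, config.bottleneck_filters[0]),
               (3, config.bottleneck_filters[0], config.bottleneck_filters[1])]
    c = config.bottleneck_filters[1]
    for f in reversed(config.encoder_filters):
        shapes.append((2, c, f[1]))            # transposed conv
        shapes += [(3, 2 * f[1], f[0]), (3, f[0], f[1])]
        c = f[1]
    shapes.append((1, c, config.out_channels))
    if config.deep_supervision:
        for lvl in (1, 2):
            if lvl < config.levels:
                shapes.append((1, config.encoder_filters[lvl][1], config.out_channels))
    return shapes


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def predict_volume(
    model: SegmentationModel,
    volume: DualVolume,
    schema: LabelSchema,
    class_ids: Optional[Sequence[int]] = None,
    transform: Optional[CropPadTransform] = None,
    batch_size: int = 2,
) -> LabelMask:
    """Slice-wise inference: softmax, argmax, restack into the volume geometry.

    ``class_ids`` maps output channel -> label id (default: channel 0 is
    background, channel i is label i).  Ties break toward the lower channel.
    """
    cfg = model.config
    if cfg.in_channels == 2:
        stack = volume.channels()
    elif cfg.in_channels == 1:
        stack = volume.fat[None]
    else:
        raise ValueError("model expects 1 or 2 input channels")
    ns = stack.shape[1]
    x = stack.transpose(1, 0, 2, 3)  # (slices, channels, H, W)
    pred_slices = []
    for i in range(0, ns, batch_size):
        scores = model.forward(x[i:i + batch_size])[0]
        pred_slices.append(np.argmax(softmax(scores), axis=1))
    pred = np.concatenate(pred_slices).astype(np.int32)
    if class_ids is not None:
        lut = np.asarray(class_ids, dtype=np.int32)
        pred = lut[pred]
    if transform is not None:
        pred = transform.invert_mask(pred)
    return LabelMask(pred, schema, volume.spacing)
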
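"""Paired ¹H/¹³C spectral-image encoder.

Both spectra pass through one *frozen* convolutional backbone; each branch
then owns a trainable 1×1 channel reduction (2048 -> 16), an optional
multi-scale convolution stage (parallel 3×3 and 5×5, summed), and its own
channel--spatial attention block (CBAM).  A joint gate computed from the
concatenated global descriptors of the two refined streams recalibrates the
channels of both, and global average pooling of the recalibrated maps is
concatenated into the 32-d spectral embedding ``f_spec``.

Two backbones are provided:

* ``resnet101`` — the standard ResNet-101 trunk (classification head
  removed), 42,500,160 parameters, used for parameter accounting and for
  full-scale runs;
* ``tiny`` — a 4-block trunk ending in 2048 channels for fast CPU runs.
  Its input is augmented with two fixed coordinate channels so that, even
  with random frozen filters, globally pooled features stay sensitive to
  peak *position* along the chemical-shift axis, not just peak shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .nn import BatchNorm1d, BatchNorm2d, Conv2d, Linear, Module

IMAGE_SIZE = 256


class ImageSizeError(ValueError):
    pass


class BackboneNotFrozenError(RuntimeError):
    pass


@dataclass
class SpectralEncoderConfig:
    reduced_channels: int = 16
    cbam_ratio: int = 4          # channel-attention bottleneck 16 -> 4 -> 16
    multiscale: bool = True      # parallel 3x3/5x5 convs before CBAM
    backbone: str = "tiny"       # "tiny" or "resnet101"
    pretrained: bool = False     # ImageNet weights are not bundled; seeded
                                 # random frozen weights are used instead
    gate_hidden: int = 64    # budget-fitted (see harness.search_budget)


# --------------------------------------------------------------------- backbones

def _maxpool2d(x: Tensor, kernel: int, stride: int, padding: int) -> Tensor:
    if x.requires_grad:
        raise NotImplementedError("maxpool is only used inside frozen trunks")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    return Tensor(win[:, :, ::stride, ::stride].max(axis=(4, 5)))


class Bottleneck(Module):
    expansion = 4

    def __init__(self, in_ch: int, planes: int, stride: int,
                 rng: np.random.Generator, downsample: bool):
        super().__init__()
        out_ch = planes * self.expansion
        self.conv1 = Conv2d(in_ch, planes, 1, rng, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, out_ch, 1, rng, bias=False)
        self.bn3 = BatchNorm2d(out_ch)
        if downsample:
            self.down_conv = Conv2d(in_ch, out_ch, 1, rng, stride=stride,
                                    bias=False)
            self.down_bn = BatchNorm2d(out_ch)
        else:
            self.down_conv = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNetTrunk(Module):
    """Bottleneck ResNet without the classification head (NCHW input)."""

    def __init__(self, blocks_per_stage: tuple[int, ...],
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(3, 64, 7, rng, stride=2, padding=3, bias=False)
        self.bn1 = BatchNorm2d(64)
        in_ch = 64
        stages = []
        for stage, n_blocks in enumerate(blocks_per_stage):
            planes = 64 * 2 ** stage
            stride = 1 if stage == 0 else 2
            for b in range(n_blocks):
                down = b == 0 and (stride != 1 or in_ch != planes * 4)
                stages.append(Bottleneck(in_ch, planes, stride if b == 0 else 1,
                                         rng, down))
                in_ch = planes * 4
        for i, blk in enumerate(stages):
            self._modules[f"block{i}"] = blk
        self.blocks = stages
        self.out_channels = in_ch

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        x = _maxpool2d(x, 3, 2, 1)
        for blk in self.blocks:
            x = blk(x)
        return x


def resnet101_trunk(rng: np.random.Generator | None = None,
                    frozen: bool = True) -> ResNetTrunk:
    """Standard ResNet-101 trunk (stages 3-4-23-3), head removed."""
    rng = rng or np.random.default_rng(0)
    trunk = ResNetTrunk((3, 4, 23, 3), rng)
    trunk.eval()
    if frozen:
        trunk.freeze()
    return trunk


def _avgpool(x: np.ndarray, k: int) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))


class TinyBackbone(Module):
    """4-block residual trunk ending in 2048 channels (for CPU runs).

    A stand-in for a pretrained trunk with two properties a pretrained
    network provides and plain stacked random convolutions do not:

    * two fixed coordinate channels are appended to the input, keeping
      globally pooled features sensitive to peak *position* along the
      chemical-shift axis;
    * each block carries an average-pool skip connection into its first
      input-channel block, so multi-resolution ink statistics of the raw
      trace stay linearly decodable at the 2048-channel output instead of
      being scrambled by four layers of random filters.
    """

    out_channels = 2048

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(5, 32, 7, rng, stride=4, padding=3)   # 3 img + 2 coord
        self.conv2 = Conv2d(32, 64, 3, rng, stride=2, padding=1)
        self.conv3 = Conv2d(64, 128, 3, rng, stride=2, padding=1)
        self.conv4 = Conv2d(128, 2048, 3, rng, stride=2, padding=1)
        self.eval()

    def forward(self, x: Tensor) -> Tensor:
        n, _, h, w = x.shape
        yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                             indexing="ij")
        coords = np.broadcast_to(
            np.stack([xx, yy]).astype(x.data.dtype), (n, 2, h, w))
        x = concat([x, Tensor(np.ascontiguousarray(coords))], axis=1)
        for conv, stride in ((self.conv1, 4), (self.conv2, 2),
                             (self.conv3, 2), (self.conv4, 2)):
            y = conv(x).relu()
            skip = _avgpool(x.data, stride)
            if y.requires_grad:   # pragma: no cover - trunk is frozen in use
                pad = np.zeros((n, y.shape[1] - skip.shape[1]) + y.shape[2:],
                               dtype=skip.dtype)
                y = y + Tensor(np.concatenate([skip, pad], axis=1))
            else:
                out = y.data.copy()
                out[:, :skip.shape[1]] += skip
                y = Tensor(out)
            x = y
        return x


def make_backbone(name: str, rng: np.random.Generator, frozen: bool = True):
    if name == "resnet101":
        return resnet101_trunk(rng, frozen=frozen)
    if name == "tiny":
        bb = TinyBackbone(rng)
        if frozen:
            bb.freeze()
        return bb
    raise ValueError(f"unknown backbone {name!r}; use 'tiny' or 'resnet101'")


# ----------------------------------------------------------------- attention

class ChannelAttention(Module):
    """Mc = sigmoid(MLP(GAP(F)) + MLP(GMP(F))) with a shared bottleneck MLP."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        n, c = fmap.shape[0], fmap.shape[1]
        flat = fmap.reshape(n, c, -1)
        gap = flat.mean(axis=2)
        gmp = flat.max(axis=2)
        mlp = lambda g: self.fc2(self.fc1(g).relu())
        return (mlp(gap) + mlp(gmp)).sigmoid()          # (n, c) in (0,1)


class SpatialAttention(Module):
    """Ms = sigmoid(conv7x7([mean_c(F) || max_c(F)])), one value per pixel."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel, rng, padding=kernel // 2)

    def forward(self, fmap: Tensor) -> Tensor:
        avg = fmap.mean(axis=1, keepdims=True)
        mx = fmap.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()  # (n,1,h,w)


class CBAM(Module):
    """Sequential channel-then-spatial attention refinement."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        self.channel = ChannelAttention(channels, ratio, rng)
        self.spatial = SpatialAttention(rng)

    def forward(self, fmap: Tensor, return_masks: bool = False):
        mc = self.channel(fmap)
        refined = fmap * mc.reshape(mc.shape[0], mc.shape[1], 1, 1)
        ms = self.spatial(refined)
        out = refined * ms
        return (out, mc, ms) if return_masks else out


class MultiScaleConv(Module):
    """Parallel 3x3 and 5x5 padding-preserving convolutions, summed."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv3 = Conv2d(channels, channels, 3, rng, padding=1)
        self.conv5 = Conv2d(channels, channels, 5, rng, padding=2)

    def forward(self, fmap: Tensor) -> Tensor:
        return (self.conv3(fmap) + self.conv5(fmap)).relu()


class JointGate(Module):
    """Cross-branch channel gate from the two global descriptors.

    gate = sigmoid(MLP([g_H || g_C])), length 2C; the first C values rescale
    the ¹H channels and the last C the ¹³C channels.
    """

    def __init__(self, channels: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(2 * channels, hidden, rng)
        self.fc2 = Linear(hidden, 2 * channels, rng)
        self.channels = channels

    def forward(self, map_h: Tensor, map_c: Tensor):
        if map_h.shape[1] != map_c.shape[1]:
            raise ValueError("branch channel counts differ")
        n, c = map_h.shape[0], map_h.shape[1]
        g_h = map_h.reshape(n, c, -1).mean(axis=2)
        g_c = map_c.reshape(n, c, -1).mean(axis=2)
        gate = self.fc2(self.fc1(concat([g_h, g_c], axis=1)).relu()).sigmoid()
        gh = gate[:, :c].reshape(n, c, 1, 1)
        gc = gate[:, c:].reshape(n, c, 1, 1)
        return map_h * gh, map_c * gc, gate


# ------------------------------------------------------------------- encoder

class SpectralEncoder(Module):
    """Paired spectral images -> 32-d embedding ``f_spec``."""

    def __init__(self, cfg: SpectralEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.backbone = make_backbone(cfg.backbone, rng, frozen=True)
        c = cfg.reduced_channels
        in_ch = self.backbone.out_channels
        self.reduce_h = Conv2d(in_ch, c, 1, rng)
        self.reduce_c = Conv2d(in_ch, c, 1, rng)
        if cfg.multiscale:
            self.ms_h = MultiScaleConv(c, rng)
            self.ms_c = MultiScaleConv(c, rng)
        self.cbam_h = CBAM(c, cfg.cbam_ratio, rng)
        self.cbam_c = CBAM(c, cfg.cbam_ratio, rng)
        self.gate = JointGate(c, cfg.gate_hidden, rng)
        # output calibration: keeps the embedding well-scaled for fusion
        self.out_norm = BatchNorm1d(2 * c)
        # per-channel standardization of the frozen trunk's maps, fitted
        # once on training-split features (identity until fitted)
        self._buffers["feat_mean_h"] = np.zeros((in_ch, 1, 1), dtype=np.float32)
        self._buffers["feat_scale_h"] = np.ones((in_ch, 1, 1), dtype=np.float32)
        self._buffers["feat_mean_c"] = np.zeros((in_ch, 1, 1), dtype=np.float32)
        self._buffers["feat_scale_c"] = np.ones((in_ch, 1, 1), dtype=np.float32)

    @property
    def embed_dim(self) -> int:
        return 2 * self.cfg.reduced_channels

    def check_frozen(self) -> None:
        bad = [n for n, p in self.backbone.named_parameters() if not p.frozen]
        if bad:
            raise BackboneNotFrozenError(
                f"backbone parameters must be frozen, found trainable: {bad[:3]}")

    def backbone_features(self, images: np.ndarray) -> np.ndarray:
        """Frozen-trunk feature maps for a (N,3,256,256) image stack.

        Pure inference (no graph recorded); safe to cache per image.
        """
        if images.ndim != 4 or images.shape[1] != 3 or \
                images.shape[2:] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ImageSizeError(
                f"expected (N,3,{IMAGE_SIZE},{IMAGE_SIZE}) images, got "
                f"{images.shape}; resize spectra to {IMAGE_SIZE}x{IMAGE_SIZE} first")
        self.check_frozen()
        with no_grad():
            return self.backbone(Tensor(images.astype(np.float32))).data

    def fit_feature_scaler(self, feats_h: np.ndarray, feats_c: np.ndarray,
                           eps: float = 1e-3) -> None:
        """Fit the per-channel feature standardization from (N,C,h,w) stacks.

        Frozen random trunks emit maps whose channel means dwarf their
        between-image variance; standardizing with training-split statistics
        conditions the trainable layers.  Statistics are stored as buffers
        so checkpoints carry them.
        """
        for tag, arr in (("h", feats_h), ("c", feats_c)):
            self._buffers[f"feat_mean_{tag}"] = \
                arr.mean(axis=(0, 2, 3))[:, None, None].astype(np.float32)
            self._buffers[f"feat_scale_{tag}"] = \
                (1.0 / (arr.std(axis=(0, 2, 3)) + eps)
                 )[:, None, None].astype(np.float32)

    def branch(self, feats: Tensor, which: str, return_masks: bool = False):
        feats = (feats - Tensor(self._buffers[f"feat_mean_{which}"])) * \
            Tensor(self._buffers[f"feat_scale_{which}"])
        reduce = self.reduce_h if which == "h" else self.reduce_c
        fmap = reduce(feats)
        if self.cfg.multiscale:
            ms = self.ms_h if which == "h" else self.ms_c
            fmap = ms(fmap)
        cbam = self.cbam_h if which == "h" else self.cbam_c
        return cbam(fmap, return_masks=return_masks)

    def forward_from_features(self, feats_h: Tensor, feats_c: Tensor) -> Tensor:
        ref_h = self.branch(feats_h, "h")
        ref_c = self.branch(feats_c, "c")
        cal_h, cal_c, _ = self.gate(ref_h, ref_c)
        n, c = cal_h.shape[0], cal_h.shape[1]
        pooled_h = cal_h.reshape(n, c, -1).mean(axis=2)
        pooled_c = cal_c.reshape(n, c, -1).mean(axis=2)
        return self.out_norm(concat([pooled_h, pooled_c], axis=1))

    def forward(self, himg: np.ndarray, cimg: np.ndarray) -> Tensor:
        fh = Tensor(self.backbone_features(himg))
        fc = Tensor(self.backbone_features(cimg))
        return self.forward_from_features(fh, fc)
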
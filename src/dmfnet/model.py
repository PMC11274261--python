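"""DMF-Net: dual-path multi-view fusion network.

Two independent trimmed multi-scale backbones process the frontal (9-channel)
and lateral (6-channel) view stacks.  Each backbone is a ResNet18-style
network with exactly ONE basic residual block per stage — this trim is what
brings the per-path footprint down to 4.91 M parameters / ~0.89 G MACs at a
224 px, 3-channel input while keeping the four-scale pyramid (strides 4, 8,
16, 32; channels 64, 128, 256, 512).

Per path the four pyramid scales are fused by the Multi-Scale Feature Fusion
Module (MFFM: 1x1 conv to a common width, resample to the stride-16 grid,
channel concat), refined by the Hybrid Co-Attention Module (HCAM: a channel
branch with row/column pooled descriptors and a spatial branch with
channel-pooled position profiles, both sigmoid-gated), then globally average
pooled.  Shared linear projection heads produce the CPP (complementarity) and
CSP (consistency) embeddings used by the metric losses, and a two-layer
classifier on the concatenated pooled features outputs the probability of a
difficult airway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import BatchNorm2d, Conv2d, Linear, Module


@dataclass
class BackboneConfig:
    in_channels: int = 3
    stage_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)


@dataclass
class ModelConfig:
    use_mffm: bool = True
    use_hcam: bool = True
    d_z: int = 128           # projection-head width
    dropout: float = 0.5
    mffm_width: int = 128    # per-scale channel width inside the MFFM
    shared_heads: bool = True
    seed: int = 0


@dataclass
class ModelOutput:
    p: Tensor                       # (N,) probability of difficult airway
    f_gap: tuple[Tensor, Tensor]    # pooled 512-vectors per path
    z_cpp: tuple[Tensor, Tensor]    # complementarity embeddings per path
    z_csp: tuple[Tensor, Tensor]    # consistency embeddings per path


class BasicBlock(Module):
    """Two 3x3 conv+BN with identity (or strided 1x1 projection) shortcut."""

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)
        else:
            self.proj = None

    def forward(self, x):
        out = ag.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return ag.relu(ag.add(out, shortcut))


class Backbone(Module):
    """Trimmed multi-scale feature extractor; returns the 4-scale pyramid."""

    def __init__(self, config: BackboneConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.config = config
        ch = config.stage_channels
        self.stem_conv = Conv2d(config.in_channels, ch[0], 7, stride=2, padding=3, rng=rng)
        self.stem_bn = BatchNorm2d(ch[0])
        in_ch = ch[0]
        for s, (out_ch, n_blocks) in enumerate(zip(ch, config.blocks_per_stage)):
            stride = 1 if s == 0 else 2
            blocks = []
            for b in range(n_blocks):
                blocks.append(BasicBlock(in_ch, out_ch, stride if b == 0 else 1, rng))
                in_ch = out_ch
            for b, blk in enumerate(blocks):
                setattr(self, f"stage{s + 1}_{b}", blk)
            setattr(self, f"_stage{s + 1}_n", n_blocks)

    def forward(self, x) -> list[Tensor]:
        x = ag.relu(self.stem_bn(self.stem_conv(x)))
        x = ag.max_pool2d(x, kernel=3, stride=2, padding=1)
        pyramid = []
        for s in range(4):
            for b in range(getattr(self, f"_stage{s + 1}_n")):
                x = getattr(self, f"stage{s + 1}_{b}")(x)
            pyramid.append(x)
        return pyramid


def build_backbone(config: BackboneConfig, rng: np.random.Generator | None = None) -> Backbone:
    if config.in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    return Backbone(config, rng)


class MFFM(Module):
    """Multi-Scale Feature Fusion Module.

    Each pyramid scale passes a 1x1 conv to ``width`` channels; the two
    shallow scales are average-pooled down and the deepest scale bilinearly
    up-sampled so all four sit on the stride-16 grid, then concatenated
    (4 * width channels).
    """

    def __init__(self, in_channels: Sequence[int] = (64, 128, 256, 512),
                 width: int = 128, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        for i, c in enumerate(in_channels):
            setattr(self, f"reduce{i}", Conv2d(c, width, 1, bias=True, rng=rng))
        self.width = width

    def forward(self, pyramid: list[Tensor]) -> Tensor:
        target_h = pyramid[2].shape[2]
        target_w = pyramid[2].shape[3]
        maps = []
        for i, fmap in enumerate(pyramid):
            m = getattr(self, f"reduce{i}")(fmap)
            h = m.shape[2]
            if h > target_h:
                m = ag.avg_pool_block(m, h // target_h)
            elif h < target_h:
                m = ag.bilinear_resize(m, (target_h, target_w))
            maps.append(m)
        return ag.concat(maps, axis=1)


class HCAM(Module):
    """Hybrid Co-Attention Module (channel + spatial branches).

    Channel branch: width/height average pooling gives per-row and per-column
    channel descriptors; a kernel-3 1-D convolution along the spatial axis
    (channels preserved) plus sigmoid yields gates A_H (C x H x 1) and
    A_W (C x 1 x W); the gated copies are concatenated to 2C channels.

    Spatial branch: channel-wise average and max pooling are merged by a 1x1
    conv to a single map; full-height (H,1) and full-width (1,W) convolutions
    give column and row position profiles, sigmoid-gated and applied to the
    input, concatenated to 2C channels.

    The 4C-channel concatenation of both branches is projected back to C
    channels by a final 1x1 convolution, so output shape equals input shape.
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c = channels
        self.conv_h = Conv2d(c, c, (3, 1), padding=(1, 0), bias=True, rng=rng)
        self.conv_w = Conv2d(c, c, (1, 3), padding=(0, 1), bias=True, rng=rng)
        self.spatial_merge = Conv2d(2, 1, 1, bias=True, rng=rng)
        self.spatial_col = None   # built lazily: kernels depend on H, W
        self.spatial_row = None
        self.project = Conv2d(4 * c, c, 1, bias=True, rng=rng)
        self._rng_state = rng

    def _build_spatial(self, h: int, w: int):
        if self.spatial_col is None:
            self.spatial_col = Conv2d(1, 1, (h, 1), bias=True, rng=self._rng_state)
            self.spatial_row = Conv2d(1, 1, (1, w), bias=True, rng=self._rng_state)
        else:
            if self.spatial_col.weight.shape[2] != h or self.spatial_row.weight.shape[3] != w:
                raise ValueError("HCAM spatial kernels were built for a different map size")

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        self._build_spatial(h, w)
        # ---- channel co-attention
        f_h = ag.tmean(x, axis=3, keepdims=True)          # (N, C, H, 1)
        f_w = ag.tmean(x, axis=2, keepdims=True)          # (N, C, 1, W)
        a_h = ag.sigmoid(self.conv_h(f_h))                # (N, C, H, 1)
        a_w = ag.sigmoid(self.conv_w(f_w))                # (N, C, 1, W)
        f_c = ag.concat([ag.mul(x, a_h), ag.mul(x, a_w)], axis=1)
        # ---- spatial co-attention
        avg = ag.tmean(x, axis=1, keepdims=True)          # (N, 1, H, W)
        mx = ag.tmax(x, axis=1, keepdims=True)
        s = self.spatial_merge(ag.concat([avg, mx], axis=1))
        a_col = ag.sigmoid(self.spatial_col(s))           # (N, 1, 1, W)
        a_row = ag.sigmoid(self.spatial_row(s))           # (N, 1, H, 1)
        f_p = ag.concat([ag.mul(x, a_col), ag.mul(x, a_row)], axis=1)
        # ---- merge and project back to C channels
        return self.project(ag.concat([f_c, f_p], axis=1))

    def attention_maps(self, x: Tensor) -> dict[str, np.ndarray]:
        """The four sigmoid gate maps, for inspection/tests."""
        n, c, h, w = x.shape
        self._build_spatial(h, w)
        f_h = ag.tmean(x, axis=3, keepdims=True)
        f_w = ag.tmean(x, axis=2, keepdims=True)
        avg = ag.tmean(x, axis=1, keepdims=True)
        mx = ag.tmax(x, axis=1, keepdims=True)
        s = self.spatial_merge(ag.concat([avg, mx], axis=1))
        return {
            "A_H": ag.sigmoid(self.conv_h(f_h)).data,
            "A_W": ag.sigmoid(self.conv_w(f_w)).data,
            "A_col": ag.sigmoid(self.spatial_col(s)).data,
            "A_row": ag.sigmoid(self.spatial_row(s)).data,
        }


class Classifier(Module):
    """concat(f1_gap, f2_gap) -> FC 1024->256 -> ReLU -> dropout -> FC 256->1 -> sigmoid."""

    def __init__(self, in_features: int, hidden: int = 256, dropout: float = 0.5, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(in_features, hidden, rng=rng)
        self.fc2 = Linear(hidden, 1, rng=rng)
        self.p_drop = dropout

    def forward(self, x, rng: np.random.Generator):
        x = ag.relu(self.fc1(x))
        x = ag.dropout(x, self.p_drop, rng, self.training)
        x = self.fc2(x)
        return ag.reshape(ag.sigmoid(x), (x.shape[0],))


class DMFNet(Module):
    """The full dual-path network; ablation flags reduce it to the baseline."""

    FRONT_CHANNELS = 9
    SIDE_CHANNELS = 6

    def __init__(self, config: ModelConfig = ModelConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.fem1 = Backbone(BackboneConfig(in_channels=self.FRONT_CHANNELS), rng)
        self.fem2 = Backbone(BackboneConfig(in_channels=self.SIDE_CHANNELS), rng)
        feat_ch = 4 * config.mffm_width if config.use_mffm else 512
        if config.use_mffm:
            self.mffm1 = MFFM(width=config.mffm_width, rng=rng)
            self.mffm2 = MFFM(width=config.mffm_width, rng=rng)
        if config.use_hcam:
            self.hcam1 = HCAM(feat_ch, rng=rng)
            self.hcam2 = HCAM(feat_ch, rng=rng)
        self.cpp = Linear(feat_ch, config.d_z, rng=rng)
        self.csp = Linear(feat_ch, config.d_z, rng=rng)
        if not config.shared_heads:
            self.cpp2 = Linear(feat_ch, config.d_z, rng=rng)
            self.csp2 = Linear(feat_ch, config.d_z, rng=rng)
        self.classifier = Classifier(2 * feat_ch, dropout=config.dropout, rng=rng)
        self._drop_rng = np.random.default_rng(config.seed + 1)

    @staticmethod
    def _pyramid_sizes(s: int) -> list[int]:
        s = (s - 1) // 2 + 1          # stem conv, stride 2, pad 3, k7
        s = (s - 1) // 2 + 1          # max-pool, stride 2, pad 1, k3
        sizes = [s]
        for _ in range(3):
            s = (s - 1) // 2 + 1      # strided first block of stages 2-4
            sizes.append(s)
        return sizes

    def build_for_input(self, size: int):
        """Materialise the size-dependent HCAM spatial kernels up front so the
        full parameter set exists before an optimiser is constructed."""
        if self.config.use_hcam:
            sizes = self._pyramid_sizes(size)
            s = sizes[2] if self.config.use_mffm else sizes[3]
            self.hcam1._build_spatial(s, s)
            self.hcam2._build_spatial(s, s)
        return self

    def _path(self, x, fem, which: int) -> Tensor:
        pyramid = fem(x)
        if self.config.use_mffm:
            fused = (self.mffm1 if which == 1 else self.mffm2)(pyramid)
        else:
            fused = pyramid[-1]
        if self.config.use_hcam:
            fused = (self.hcam1 if which == 1 else self.hcam2)(fused)
        return ag.global_avg_pool(fused)

    def forward(self, x1, x2, drop_rng: np.random.Generator | None = None) -> ModelOutput:
        x1, x2 = ag.as_tensor(x1), ag.as_tensor(x2)
        if x1.shape[1] != self.FRONT_CHANNELS or x2.shape[1] != self.SIDE_CHANNELS:
            raise ValueError(
                f"expected {self.FRONT_CHANNELS}/{self.SIDE_CHANNELS} channel inputs, "
                f"got {x1.shape[1]}/{x2.shape[1]}")
        drop_rng = drop_rng if drop_rng is not None else self._drop_rng
        f1 = self._path(x1, self.fem1, 1)
        f2 = self._path(x2, self.fem2, 2)
        cpp2 = self.cpp if self.config.shared_heads else self.cpp2
        csp2 = self.csp if self.config.shared_heads else self.csp2
        z_cpp = (self.cpp(f1), cpp2(f2))
        z_csp = (self.csp(f1), csp2(f2))
        p = self.classifier(ag.concat([f1, f2], axis=1), drop_rng)
        return ModelOutput(p=p, f_gap=(f1, f2), z_cpp=z_cpp, z_csp=z_csp)
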
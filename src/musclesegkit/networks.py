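"""The four segmentation architectures: U-Net, UNet++, FFU and AFFU.

All are 2D encoder-decoder networks over single-channel slices producing
per-class score maps of the same spatial size as the input.

* U-Net: the standard contracting/expanding backbone with skip
  concatenation.
* UNet++: nested dense skip pathways — every skip connection is bridged
  by convolution nodes X[i][j] that fuse all previous nodes of the same
  level with the upsampled node from the level below.
* FFU (feature-fusion U-Net): the U-Net backbone plus a fusion head.
  Decoder feature maps from levels 4/3/2 are upsampled x8/x4/x2 to full
  resolution, passed through ASPP (atrous spatial pyramid pooling) blocks,
  concatenated with the level-1 decoder output and merged by convolution,
  with an additive residual connection around the top merge.
* AFFU (attention-FFU): FFU plus an additive attention gate on every
  encoder-to-decoder skip connection and a CBAM (channel-then-spatial
  attention) block on the concatenated fusion features before the final
  projection.

Inputs whose height/width are not divisible by 2^(depth-1) are
zero-padded symmetrically and the output is cropped back, so odd widths
(such as the 125-pixel training crops) are accepted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import BatchNorm2d, Conv2d, ConvBlock, Linear, Module

__all__ = [
    "NetworkConfig",
    "build_network",
    "count_parameters",
    "AttentionGate",
    "ASPPBlock",
    "CBAM",
    "attention_gate",
    "aspp_block",
    "UNet",
    "UNetPP",
    "FFU",
]

ARCHS = ("unet", "unetpp", "ffu", "affu")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``depth`` counts encoder levels (5 means four down-samplings);
    ``base_width`` is the channel count at the top level, doubled per
    level.  ``aspp_rates`` are the dilation rates of the fusion blocks.
    """

    arch: str = "unet"
    in_channels: int = 1
    n_classes: int = 17
    base_width: int = 64
    depth: int = 5
    aspp_rates: tuple[int, ...] = (1, 2, 4, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arch not in ARCHS:
            raise ValueError(f"arch must be one of {ARCHS}, got {self.arch!r}")
        if self.depth < 4:
            raise ValueError("depth must be >= 4 (fusion uses decoder levels 4/3/2)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_json(self) -> str:
        return json.dumps(
            {
                "arch": self.arch,
                "in_channels": self.in_channels,
                "n_classes": self.n_classes,
                "base_width": self.base_width,
                "depth": self.depth,
                "aspp_rates": list(self.aspp_rates),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "NetworkConfig":
        d = json.loads(s)
        d["aspp_rates"] = tuple(d["aspp_rates"])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks


class AttentionGate(Module):
    """Additive attention gate on a skip connection.

    The gating signal (one level coarser) is projected, upsampled and
    added to the projected skip features; a 1x1 convolution plus sigmoid
    yields an attention map in [0, 1] that multiplies the skip features.
    ``passthrough`` forces the map to 1 (identity), used for ablation.
    """

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int | None = None, rng=None):
        super().__init__()
        inter_ch = inter_ch or max(skip_ch // 2, 1)
        self.theta = Conv2d(skip_ch, inter_ch, k=1, rng=rng)
        self.phi = Conv2d(gate_ch, inter_ch, k=1, rng=rng)
        self.psi = Conv2d(inter_ch, 1, k=1, rng=rng)
        self.passthrough = False

    def forward(self, skip: Tensor, gate: Tensor) -> Tensor:
        if self.passthrough:
            return skip
        t = self.theta(skip)
        g = self.phi(gate)
        if g.shape[2] != t.shape[2]:
            g = ag.upsample_nearest(g, t.shape[2] // g.shape[2])
        alpha = ag.sigmoid(self.psi(ag.relu(ag.add(t, g))))
        return ag.mul(skip, alpha)

    def attention_map(self, skip: Tensor, gate: Tensor) -> np.ndarray:
        if self.passthrough:
            return np.ones((skip.shape[0], 1) + skip.shape[2:], dtype=np.float32)
        t = self.theta(skip)
        g = self.phi(gate)
        if g.shape[2] != t.shape[2]:
            g = ag.upsample_nearest(g, t.shape[2] // g.shape[2])
        return ag.sigmoid(self.psi(ag.relu(ag.add(t, g)))).data


def attention_gate(skip: Tensor, gate: Tensor, module: AttentionGate) -> Tensor:
    """Functional wrapper: gated skip features (skip * learned map)."""
    return module(skip, gate)


class ASPPBlock(Module):
    """Atrous spatial pyramid pooling: parallel dilated branches + global
    pooling, concatenated and projected.  Spatial size is preserved."""

    def __init__(self, in_ch: int, out_ch: int, rates=(1, 2, 4, 8), rng=None):
        super().__init__()
        if not rates:
            raise ValueError("rates must be nonempty")
        self.rates = tuple(int(r) for r in rates)
        br = max(out_ch // 2, 4)
        self.branches = [Conv2d(in_ch, br, k=3, dilation=r, rng=rng) for r in self.rates]
        self.branch_norms = [BatchNorm2d(br) for _ in self.rates]
        self.global_proj = Conv2d(in_ch, br, k=1, rng=rng)
        self.project = Conv2d(br * (len(self.rates) + 1), out_ch, k=1, rng=rng)
        self.norm = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        size = min(x.shape[2], x.shape[3])
        outs = []
        for conv, bn, r in zip(self.branches, self.branch_norms, self.rates):
            eff = 2 * r + 1
            d = r
            if eff > size:
                d = max((size - 1) // 2, 1)
                warnings.warn(
                    f"ASPP rate {r} exceeds feature size {size}; using dilation {d}"
                )
            y = ag.conv2d(x, conv.weight, conv.bias, dilation=d)
            outs.append(ag.relu(bn(y)))
        gap = ag.global_avg_pool(x)
        g = ag.relu(self.global_proj(gap))
        g = ag.add(g, Tensor(np.zeros((1, 1) + x.shape[2:], dtype=np.float32)))
        outs.append(g)
        return ag.relu(self.norm(self.project(ag.concat(outs, axis=1))))


def aspp_block(x: Tensor, module: ASPPBlock) -> Tensor:
    """Functional wrapper over :class:`ASPPBlock`."""
    return module(x)


class CBAM(Module):
    """Channel attention (shared MLP over average+max pooled descriptors)
    followed by spatial attention (7x7 conv over channel mean+max maps).
    ``identity`` bypasses the block, used for ablation."""

    def __init__(self, n_ch: int, reduction: int = 8, rng=None):
        super().__init__()
        hidden = max(n_ch // reduction, 1)
        self.fc1 = Linear(n_ch, hidden, rng=rng)
        self.fc2 = Linear(hidden, n_ch, rng=rng)
        self.spatial = Conv2d(2, 1, k=7, rng=rng)
        self.identity = False

    def forward(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        B, C = x.shape[0], x.shape[1]
        avg = ag.reshape(ag.global_avg_pool(x), (B, C))
        mx = ag.reshape(ag.amax(ag.amax(x, axis=3), axis=2), (B, C))
        att = ag.add(
            self.fc2(ag.relu(self.fc1(avg))), self.fc2(ag.relu(self.fc1(mx)))
        )
        ch_att = ag.reshape(ag.sigmoid(att), (B, C, 1, 1))
        x = ag.mul(x, ch_att)
        sp_in = ag.concat(
            [ag.mean(x, axis=1, keepdims=True), ag.amax(x, axis=1)], axis=1
        )
        sp_att = ag.sigmoid(self.spatial(sp_in))
        return ag.mul(x, sp_att)


# ---------------------------------------------------------------------------
# padding policy


def _pad_to_multiple(x: Tensor, m: int) -> tuple[Tensor, tuple[int, int, int, int]]:
    H, W = x.shape[2], x.shape[3]
    ph = (-H) % m
    pw = (-W) % m
    pad = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
    if ph or pw:
        x = ag.pad2d(x, pad)
    return x, pad


# ---------------------------------------------------------------------------
# architectures


class _SegNet(Module):
    """Shared plumbing: padding policy + classifier contract."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        m = 2 ** (self.config.depth - 1)
        x, pad = _pad_to_multiple(x, m)
        out = self._forward_padded(x)
        t, b, l, r = pad
        if any(pad):
            out = ag.crop2d(out, (t, b, l, r))
        return out

    def predict_classes(self, x) -> np.ndarray:
        """Argmax class map, (B, H, W), computed without a tape."""
        with ag.no_grad():
            out = self.forward(x)
        return out.data.argmax(axis=1)


class UNet(_SegNet):
    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__(config)
        rng = rng or np.random.default_rng(config.seed)
        w, d = config.base_width, config.depth
        widths = [w * 2**l for l in range(d)]
        self.enc = [
            ConvBlock(config.in_channels if l == 0 else widths[l - 1], widths[l], rng=rng)
            for l in range(d)
        ]
        self.up = [Conv2d(widths[l + 1], widths[l], k=3, rng=rng) for l in range(d - 1)]
        self.dec = [ConvBlock(2 * widths[l], widths[l], rng=rng) for l in range(d - 1)]
        self.classifier = Conv2d(w, config.n_classes, k=1, rng=rng)
        self.use_gates = False

    def _encode(self, x):
        skips = []
        for l, block in enumerate(self.enc):
            x = block(x)
            skips.append(x)
            if l < len(self.enc) - 1:
                x = ag.maxpool2(x)
        return skips

    def _decode(self, skips):
        """Returns decoder features per level, top (full-res) first."""
        d = self.config.depth
        feats = [None] * (d - 1)
        cur = skips[-1]
        for l in range(d - 2, -1, -1):
            up = self.up[l](ag.upsample_nearest(cur, 2))
            skip = skips[l]
            if self.use_gates:
                skip = self.gates[l](skip, cur)
            cur = self.dec[l](ag.concat([skip, up], axis=1))
            feats[l] = cur
        return feats

    def _forward_padded(self, x):
        feats = self._decode(self._encode(x))
        return self.classifier(feats[0])


class UNetPP(_SegNet):
    """Nested U-Net: convolution nodes on every skip pathway."""

    def __init__(self, config: NetworkConfig, rng=None):
        super().__init__(config)
        rng = rng or np.random.default_rng(config.seed)
        w, d = config.base_width, config.depth
        widths = [w * 2**l for l in range(d)]
        self.enc = [
            ConvBlock(config.in_channels if l == 0 else widths[l - 1], widths[l], rng=rng)
            for l in range(d)
        ]
        # skip-pathway nodes X[i][j], i = level, j = 1..d-1-i
        self.nodes = []
        for i in range(d - 1):
            row = []
            for j in range(1, d - i):
                in_ch = widths[i] * j + widths[i + 1]
                row.append(ConvBlock(in_ch, widths[i], rng=rng))
            self.nodes.append(row)
        self.classifier = Conv2d(w, config.n_classes, k=1, rng=rng)

    @property
    def n_skip_nodes(self) -> int:
        return sum(len(row) for row in self.nodes)

    def _forward_padded(self, x):
        d = self.config.depth
        X: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i in range(d):
            cur = self.enc[i](cur if i == 0 else ag.maxpool2(X[(i - 1, 0)]))
            X[(i, 0)] = cur
        for j in range(1, d):
            for i in range(d - j):
                prev = [X[(i, jj)] for jj in range(j)]
                below = ag.upsample_nearest(X[(i + 1, j - 1)], 2)
                X[(i, j)] = self.nodes[i][j - 1](ag.concat(prev + [below], axis=1))
        return self.classifier(X[(0, d - 1)])


class FFU(UNet):
    """Feature-fusion U-Net; with ``use_gates``/``use_cbam`` it is AFFU.

    Decoder levels 2..4 are upsampled to full resolution, passed through
    ASPP blocks, concatenated with the level-1 decoder output (optionally
    CBAM-reweighted) and merged with a residual connection.
    """

    def __init__(self, config: NetworkConfig, rng=None, use_gates=False, use_cbam=False):
        super().__init__(config, rng=rng)
        rng2 = np.random.default_rng(config.seed + 1)
        w, d = config.base_width, config.depth
        widths = [w * 2**l for l in range(d)]
        self.fusion_levels = list(range(1, min(4, d - 1)))  # decoder levels 2..4
        self.aspp = [
            ASPPBlock(widths[l], w, rates=config.aspp_rates, rng=rng2)
            for l in self.fusion_levels
        ]
        fused_ch = w * (1 + len(self.fusion_levels))
        self.merge = Conv2d(fused_ch, w, k=3, rng=rng2)
        self.merge_norm = BatchNorm2d(w)
        self.use_gates = use_gates
        self.use_cbam = use_cbam
        if use_gates:
            rng3 = np.random.default_rng(config.seed + 2)
            self.gates = [
                AttentionGate(widths[l], widths[l + 1], rng=rng3) for l in range(d - 1)
            ]
        if use_cbam:
            rng4 = np.random.default_rng(config.seed + 3)
            self.cbam = CBAM(fused_ch, rng=rng4)

    def set_ablation(self, gates_passthrough=False, cbam_identity=False):
        """Force attention gates to 1 and/or CBAM to identity."""
        if self.use_gates:
            for g in self.gates:
                g.passthrough = gates_passthrough
        if self.use_cbam:
            self.cbam.identity = cbam_identity
        return self

    def _forward_padded(self, x):
        feats = self._decode(self._encode(x))
        top = feats[0]
        fused = [top]
        for a, l in zip(self.aspp, self.fusion_levels):
            zoomed = ag.upsample_nearest(feats[l], 2**l)
            fused.append(a(zoomed))
        cat = ag.concat(fused, axis=1)
        if self.use_cbam:
            cat = self.cbam(cat)
        merged = ag.relu(self.merge_norm(self.merge(cat)))
        merged = ag.add(merged, top)  # residual around the top merge
        return self.classifier(merged)


def build_network(config: NetworkConfig) -> _SegNet:
    """Instantiate the requested architecture with seeded initialisation."""
    rng = np.random.default_rng(config.seed)
    if config.arch == "unet":
        return UNet(config, rng=rng)
    if config.arch == "unetpp":
        return UNetPP(config, rng=rng)
    if config.arch == "ffu":
        return FFU(config, rng=rng)
    return FFU(config, rng=rng, use_gates=True, use_cbam=True)


def count_parameters(net: Module) -> int:
    return int(sum(p.data.size for p in net.parameters()))


def save_checkpoint(net: _SegNet, path: str | Path) -> None:
    """Write weights (npz) with the architecture config embedded."""
    state = net.state_dict()
    np.savez_compressed(path, __config__=net.config.to_json(), **state)


def load_checkpoint(path: str | Path) -> _SegNet:
    with np.load(path, allow_pickle=False) as z:
        config = NetworkConfig.from_json(str(z["__config__"]))
        state = {k: z[k] for k in z.files if k != "__config__"}
    net = build_network(config)
    net.load_state_dict(state)
    return net


def summary(net: _SegNet) -> str:
    lines = [f"{net.config.arch}: {count_parameters(net)} parameters"]
    for name, p in net.named_parameters():
        lines.append(f"  {name:50s} {str(p.data.shape):20s} {p.data.size}")
    return "\n".join(lines)
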
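"""AtDU-Net: shared attention encoder with two task-specific decoders.

The encoder is a stem of two 3x3 convolutions followed by ``depth``
downsampling stages.  Each stage is a Hierarchical Attention Sampling
Module (HASM) — strided compression, squeeze-excite channel gating and a
large-kernel global-context aggregation — followed by a Split Axial
Detail Module (SADM) that applies single-head self-attention separately
along rows and columns with a residual connection.  Each enabled head
(palpebral fissure, cornea) gets an independent U-Net style decoder with
skip connections from every encoder stage, ending in a sigmoid map.

Ablation flags reduce HASM to a plain strided convolution and SADM to
identity, yielding the single/dual-decoder "BaseNet" baselines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.modules import Conv2d, ConvNormRelu, Linear, Module

HEADS = ("fissure", "cornea")


@dataclass
class NetConfig:
    """Architecture hyperparameters.

    ``heads_enabled`` selects the decoder branches; with
    ``dual_decoder=False`` exactly one head must remain (the
    single-region ablation rows).
    """

    base_channels: int = 32
    depth: int = 3
    use_has: bool = True
    use_sad: bool = True
    dual_decoder: bool = True
    heads_enabled: tuple[str, ...] = HEADS
    input_size: tuple[int, int] = (496, 744)  # (height, width)

    def validate(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 8:
            raise ValueError("base_channels must be >= 8")
        heads = tuple(self.heads_enabled)
        if not heads or any(h not in HEADS for h in heads):
            raise ValueError(f"heads_enabled must be a nonempty subset of {HEADS}")
        if not self.dual_decoder and len(heads) != 1:
            raise ValueError("single-decoder config requires exactly one head")
        h, w = self.input_size
        if h % (1 << self.depth) or w % (1 << self.depth):
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth={1 << self.depth}"
            )

    def to_dict(self) -> dict:
        return {
            "base_channels": self.base_channels,
            "depth": self.depth,
            "use_has": self.use_has,
            "use_sad": self.use_sad,
            "dual_decoder": self.dual_decoder,
            "heads_enabled": list(self.heads_enabled),
            "input_size": list(self.input_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        cfg = cls(
            base_channels=int(d["base_channels"]),
            depth=int(d["depth"]),
            use_has=bool(d["use_has"]),
            use_sad=bool(d["use_sad"]),
            dual_decoder=bool(d["dual_decoder"]),
            heads_enabled=tuple(d["heads_enabled"]),
            input_size=tuple(d["input_size"]),
        )
        cfg.validate()
        return cfg


def _broadcast_to(desc: Tensor, h: int, w: int) -> Tensor:
    # (N,C,1,1) -> (N,C,h,w) via broadcast add; the adjoint sums back
    return desc + Tensor(np.zeros((1, 1, h, w), dtype=np.float32))


class HASM(Module):
    """Hierarchical Attention Sampling Module: halves space, doubles channels.

    Compression: 3x3 stride-2 convolution.  Hierarchical attention:
    global-average descriptor -> bottleneck MLP (reduction 4) -> sigmoid
    channel gates.  Context aggregation: broadcast global max/avg
    descriptors concatenated with the gated map, 7x7 convolution,
    residual add.
    """

    def __init__(self, cin: int, rng: np.random.Generator):
        cout = 2 * cin
        self.compress = ConvNormRelu(cin, cout, 3, stride=2, rng=rng)
        self.fc1 = Linear(cout, max(cout // 4, 4), rng=rng)
        self.fc2 = Linear(max(cout // 4, 4), cout, rng=rng)
        self.context = Conv2d(3 * cout, cout, 7, rng=rng)
        self.last_gates: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"HASM requires even spatial dims, got {h}x{w}")
        y = self.compress(x)
        desc = ag.reshape(ag.global_avg_pool(y), (n, 2 * c))
        gates = ag.sigmoid(self.fc2(ag.relu(self.fc1(desc))))
        self.last_gates = gates.data.copy()
        gated = y * ag.reshape(gates, (n, 2 * c, 1, 1))
        ho, wo = h // 2, w // 2
        mx = _broadcast_to(ag.global_max_pool(gated), ho, wo)
        av = _broadcast_to(ag.global_avg_pool(gated), ho, wo)
        ctx = self.context(ag.concat([gated, mx, av], axis=1))
        return gated + ctx


class PlainDown(Module):
    """Ablation replacement for HASM: bare strided convolution."""

    def __init__(self, cin: int, rng: np.random.Generator):
        self.compress = ConvNormRelu(cin, 2 * cin, 3, stride=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError(f"downsampling requires even spatial dims, got {h}x{w}")
        return self.compress(x)


class _AxialAttention(Module):
    """Single-head self-attention along one spatial axis (shared weights per axis)."""

    def __init__(self, c: int, axis: int, rng: np.random.Generator):
        self.q = Conv2d(c, c, 1, rng=rng)
        self.k = Conv2d(c, c, 1, rng=rng)
        self.v = Conv2d(c, c, 1, rng=rng)
        self.axis = axis  # 2 = attend along H (column module), 3 = along W (row module)
        self.last_attn: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        q, k, v = self.q(x), self.k(x), self.v(x)
        if self.axis == 3:  # sequence = the W positions of each row
            perm, inv, b, l = (0, 2, 3, 1), (0, 3, 1, 2), n * h, w
        else:               # sequence = the H positions of each column
            perm, inv, b, l = (0, 3, 2, 1), (0, 3, 2, 1), n * w, h

        def seq(t: Tensor) -> Tensor:
            return ag.reshape(ag.transpose(t, perm), (b, l, c))

        qs, ks, vs = seq(q), seq(k), seq(v)
        scores = ag.matmul(qs, ag.transpose(ks, (0, 2, 1))) * (1.0 / np.sqrt(c))
        attn = ag.softmax(scores, axis=-1)
        self.last_attn = attn.data.copy()
        out = ag.matmul(attn, vs)
        if self.axis == 3:
            out = ag.transpose(ag.reshape(out, (n, h, w, c)), inv)
        else:
            out = ag.transpose(ag.reshape(out, (n, w, h, c)), inv)
        return out


class SADM(Module):
    """Split Axial Detail Module: local feature generation, then row and
    column attention, combined with a residual connection (shape-preserving)."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.gen = ConvNormRelu(c, c, 3, rng=rng)
        self.row = _AxialAttention(c, axis=3, rng=rng)
        self.col = _AxialAttention(c, axis=2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        f = self.gen(x)
        return x + self.row(f) + self.col(f)


class _DecoderStage(Module):
    def __init__(self, cin: int, cskip: int, cout: int, rng: np.random.Generator):
        self.conv1 = ConvNormRelu(cin + cskip, cout, 3, rng=rng)
        self.conv2 = ConvNormRelu(cout, cout, 3, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = ag.concat([ag.upsample2x(x), skip], axis=1)
        return self.conv2(self.conv1(x))


class Decoder(Module):
    def __init__(self, base: int, depth: int, rng: np.random.Generator):
        self.stages = [
            _DecoderStage(base << (i + 1), base << i, base << i, rng)
            for i in reversed(range(depth))
        ]
        self.head = Conv2d(base, 1, 1, rng=rng)

    def forward(self, bottom: Tensor, skips: list[Tensor]) -> Tensor:
        x = bottom
        for stage, skip in zip(self.stages, reversed(skips)):
            x = stage(x, skip)
        return ag.sigmoid(self.head(x))


class AtDUNet(Module):
    """Shared encoder, per-head decoders; see module docstring."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b = cfg.base_channels
        self.stem1 = ConvNormRelu(3, b, 3, rng=rng)
        self.stem2 = ConvNormRelu(b, b, 3, rng=rng)
        self.downs = []
        self.sadms = []
        for i in range(cfg.depth):
            cin = b << i
            self.downs.append(HASM(cin, rng) if cfg.use_has else PlainDown(cin, rng))
            self.sadms.append(SADM(cin << 1, rng) if cfg.use_sad else None)
        self.decoders = {h: Decoder(b, cfg.depth, rng)
                         for h in cfg.heads_enabled}

    def encode(self, x: Tensor) -> list[Tensor]:
        feats = [self.stem2(self.stem1(x))]
        for down, sadm in zip(self.downs, self.sadms):
            y = down(feats[-1])
            if sadm is not None:
                y = sadm(y)
            feats.append(y)
        return feats

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        h, w = self.cfg.input_size
        if x.shape[2:] != (h, w):
            raise ValueError(f"expected input {h}x{w}, got {x.shape[2]}x{x.shape[3]}")
        feats = self.encode(x)
        skips, bottom = feats[:-1], feats[-1]
        return {head: dec(bottom, skips) for head, dec in self.decoders.items()}


def build_network(cfg: NetConfig, seed: int = 0) -> AtDUNet:
    """Construct a seeded AtDU-Net for the given configuration."""
    return AtDUNet(cfg, seed=seed)


def dual_forward(net: AtDUNet, image: np.ndarray
                 ) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Run one image (H,W,3, uint8 or [0,1] float) through both heads.

    Returns ``(fissure_prob, cornea_prob)`` as (H,W) float arrays in
    [0, 1]; a disabled head yields ``None``.
    """
    h, w = net.cfg.input_size
    if image.shape[:2] != (h, w) or image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected image {h}x{w}x3, got {image.shape}")
    x = image.astype(np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    x = Tensor(x.transpose(2, 0, 1)[None])
    with ag.no_grad():
        out = net.forward(x)
    probs = {k: v.data[0, 0] for k, v in out.items()}
    return probs.get("fissure"), probs.get("cornea")
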
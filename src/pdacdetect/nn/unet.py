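"""Residual 3D U-Net: one architecture definition for every cascade stage.

The encoder halves resolution per level (average pooling) and the decoder
mirrors it with nearest-neighbour upsampling and skip concatenation; each
level applies a projection convolution (Conv -> InstanceNorm -> ReLU)
followed by a two-convolution pre-activation residual unit.  The per-voxel
head is a 1x1x1 convolution with a sigmoid for single-channel tasks or a
softmax over channels for mutually exclusive multi-label tasks.

The full-scale configuration used for real CT (depth 4; 32, 64, 128 and
256 filters per level) and the small phantom-scale variants share this one
definition — only :class:`NetworkConfig` changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .layers import (Conv3d, InstanceNorm3d, ReLU, avgpool2, avgpool2_backward,
                     upsample2, upsample2_backward)

__all__ = ["NetworkConfig", "UNet3D", "build_model", "predict_proba",
           "save_model", "load_model", "FULL_SCALE_FILTERS"]

FULL_SCALE_FILTERS = (32, 64, 128, 256)


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    out_channels: int = 1
    depth: int = 4
    filters_per_level: tuple[int, ...] = FULL_SCALE_FILTERS
    residual: bool = True

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if len(self.filters_per_level) != self.depth:
            raise ValueError("filters_per_level length must equal depth")
        f = self.filters_per_level
        if any(f[i] >= f[i + 1] for i in range(len(f) - 1)):
            raise ValueError("filters_per_level must be strictly increasing")

    @property
    def head(self) -> str:
        return "sigmoid" if self.out_channels == 1 else "softmax"


class _ResUnit:
    """Pre-activation residual unit: x + Conv(ReLU(IN(Conv(ReLU(IN(x))))))."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.in1, self.r1, self.c1 = InstanceNorm3d(c), ReLU(), Conv3d(c, c, 3, rng)
        self.in2, self.r2, self.c2 = InstanceNorm3d(c), ReLU(), Conv3d(c, c, 3, rng)

    def forward(self, x, cache=False):
        h = self.c1.forward(self.r1.forward(self.in1.forward(x, cache), cache), cache)
        h = self.c2.forward(self.r2.forward(self.in2.forward(h, cache), cache), cache)
        return x + h

    def backward(self, dout):
        dh = self.in2.backward(self.r2.backward(self.c2.backward(dout)))
        dh = self.in1.backward(self.r1.backward(self.c1.backward(dh)))
        return dout + dh

    def layers(self):
        return [self.in1, self.c1, self.in2, self.c2]


class _ConvBlock:
    """Conv -> InstanceNorm -> ReLU projection block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv, self.norm, self.act = Conv3d(cin, cout, 3, rng), InstanceNorm3d(cout), ReLU()

    def forward(self, x, cache=False):
        return self.act.forward(self.norm.forward(self.conv.forward(x, cache), cache), cache)

    def backward(self, dout):
        return self.conv.backward(self.norm.backward(self.act.backward(dout)))

    def layers(self):
        return [self.conv, self.norm]


class UNet3D:
    """Residual 3D encoder-decoder segmentation model (numpy)."""

    def __init__(self, config: NetworkConfig, seed: int = 0, training_meta: dict | None = None):
        self.config = config
        self.seed = int(seed)
        self.training_meta = dict(training_meta or {})
        rng = np.random.default_rng(self.seed)
        f = config.filters_per_level
        L = config.depth
        self.enc_proj = []
        self.enc_res = []
        prev = config.in_channels
        for i in range(L):
            self.enc_proj.append(_ConvBlock(prev, f[i], rng))
            self.enc_res.append(_ResUnit(f[i], rng) if config.residual else None)
            prev = f[i]
        self.dec_proj = []
        self.dec_res = []
        for i in range(L - 2, -1, -1):
            self.dec_proj.append(_ConvBlock(f[i + 1] + f[i], f[i], rng))
            self.dec_res.append(_ResUnit(f[i], rng) if config.residual else None)
        self.head = Conv3d(f[0], config.out_channels, 1, rng)
        self._enc_feats = None

    # ---- plumbing -------------------------------------------------------
    def _all_layers(self):
        out = []
        for blk, res in zip(self.enc_proj, self.enc_res):
            out += blk.layers()
            if res is not None:
                out += res.layers()
        for blk, res in zip(self.dec_proj, self.dec_res):
            out += blk.layers()
            if res is not None:
                out += res.layers()
        out.append(self.head)
        return out

    def params(self):
        out = []
        for layer in self._all_layers():
            out += layer.params()
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError(f"input must be (C, X, Y, Z), got {x.ndim} axes")
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"input has {x.shape[0]} channels, model expects {self.config.in_channels}"
            )
        div = 2 ** (self.config.depth - 1)
        bad = [n for n in x.shape[1:] if n % div]
        if bad:
            raise ValueError(
                f"spatial extents {tuple(x.shape[1:])} must each be divisible by "
                f"{div} (= 2^(depth-1)) for a depth-{self.config.depth} network"
            )

    # ---- forward / backward --------------------------------------------
    def forward_logits(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        self._check_input(np.asarray(x, dtype=float))
        x = np.asarray(x, dtype=float)
        feats = []
        h = x
        for i in range(self.config.depth):
            if i > 0:
                h = avgpool2(h)
            h = self.enc_proj[i].forward(h, cache)
            if self.enc_res[i] is not None:
                h = self.enc_res[i].forward(h, cache)
            feats.append(h)
        d = feats[-1]
        for j, i in enumerate(range(self.config.depth - 2, -1, -1)):
            u = upsample2(d)
            cat = np.concatenate([u, feats[i]], axis=0)
            d = self.dec_proj[j].forward(cat, cache)
            if self.dec_res[j] is not None:
                d = self.dec_res[j].forward(d, cache)
        if cache:
            self._enc_feats = feats
        return self.head.forward(d, cache)

    def backward(self, dlogits: np.ndarray) -> None:
        f = self.config.filters_per_level
        d = self.head.backward(dlogits)
        skip_grads = [None] * self.config.depth
        for j in range(len(self.dec_proj) - 1, -1, -1):
            i = self.config.depth - 2 - j
            if self.dec_res[j] is not None:
                d = self.dec_res[j].backward(d)
            dcat = self.dec_proj[j].backward(d)
            du, dskip = dcat[: f[i + 1]], dcat[f[i + 1]:]
            skip_grads[i] = dskip
            d = upsample2_backward(du)
        # deepest level receives the decoder gradient directly; shallower
        # levels sum the pooled-path gradient with their skip gradient
        g = d
        for i in range(self.config.depth - 1, -1, -1):
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            if self.enc_res[i] is not None:
                g = self.enc_res[i].backward(g)
            g = self.enc_proj[i].backward(g)
            if i > 0:
                g = avgpool2_backward(g, None)

    def activate(self, logits: np.ndarray) -> np.ndarray:
        if self.config.head == "sigmoid":
            return 1.0 / (1.0 + np.exp(-logits))
        z = logits - logits.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-channel probabilities in [0, 1], same spatial shape as input."""
        return self.activate(self.forward_logits(x, cache=False))


def build_model(config: NetworkConfig, seed: int = 0, training_meta: dict | None = None) -> UNet3D:
    """Construct a residual 3D U-Net with deterministic initialization."""
    return UNet3D(config, seed=seed, training_meta=training_meta)


def predict_proba(model, x: np.ndarray) -> np.ndarray:
    return model.predict_proba(x)


def save_model(model: UNet3D, path) -> None:
    """Self-describing checkpoint: parameters + config + fold metadata."""
    arrays = {f"p{i}": p for i, (p, _) in enumerate(model.params())}
    meta = {
        "config": {
            "in_channels": model.config.in_channels,
            "out_channels": model.config.out_channels,
            "depth": model.config.depth,
            "filters_per_level": list(model.config.filters_per_level),
            "residual": model.config.residual,
        },
        "seed": model.seed,
        "training_meta": model.training_meta,
    }
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> UNet3D:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        cfg = meta["config"]
        config = NetworkConfig(
            in_channels=cfg["in_channels"],
            out_channels=cfg["out_channels"],
            depth=cfg["depth"],
            filters_per_level=tuple(cfg["filters_per_level"]),
            residual=cfg["residual"],
        )
        model = UNet3D(config, seed=meta["seed"], training_meta=meta["training_meta"])
        for i, (p, _) in enumerate(model.params()):
            p[...] = z[f"p{i}"]
    return model
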
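"""Inception-style convolutional blocks.

An inception module runs four parallel paths over the same input --
1x1 conv; 1x1 reduce -> 3x3 conv; 1x1 reduce -> 5x5 conv; 3x3 max-pool
-> 1x1 projection -- and concatenates their outputs along channels, so
features at several receptive-field sizes coexist at every spatial
location.  Same-padding everywhere preserves the spatial dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Conv2d, Layer, MaxPool2d, ReLU, Sequential


@dataclass(frozen=True)
class InceptionModuleConfig:
    c1: int = 8            # 1x1 path output channels
    c3_reduce: int = 8
    c3: int = 16           # 3x3 path output channels
    c5_reduce: int = 4
    c5: int = 4            # 5x5 path output channels
    pool_proj: int = 4     # pooled 1x1-projection output channels
    activation: str = "relu"

    def __post_init__(self) -> None:
        for f in ("c1", "c3_reduce", "c3", "c5_reduce", "c5", "pool_proj"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")

    @property
    def out_channels(self) -> int:
        return self.c1 + self.c3 + self.c5 + self.pool_proj

    def scaled(self, factor: float) -> "InceptionModuleConfig":
        """Scale every path width by a common factor (minimum 1)."""
        return InceptionModuleConfig(
            *(max(1, int(round(getattr(self, f) * factor)))
              for f in ("c1", "c3_reduce", "c3", "c5_reduce", "c5",
                        "pool_proj")),
            activation=self.activation)

    def param_count(self, in_channels: int) -> int:
        """Closed-form parameter count (weights + biases over all paths)."""
        c = in_channels
        p1 = c * self.c1 + self.c1
        p3 = (c * self.c3_reduce + self.c3_reduce
              + self.c3_reduce * 9 * self.c3 + self.c3)
        p5 = (c * self.c5_reduce + self.c5_reduce
              + self.c5_reduce * 25 * self.c5 + self.c5)
        pp = c * self.pool_proj + self.pool_proj
        return p1 + p3 + p5 + pp


class MaxPool2dSame(Layer):
    """3x3 max pooling, stride 1, same padding (the inception pool path)."""

    def __init__(self, kernel: int = 3):
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for same padding")
        self.kernel = kernel

    def forward(self, x, train=False):
        k = self.kernel
        p = (k - 1) // 2
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        best = np.full((n, c, h, w), -np.inf)
        which = np.zeros((n, c, h, w), dtype=np.int8)
        for s, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            cand = xp[:, :, i:i + h, j:j + w]
            upd = cand > best
            best = np.where(upd, cand, best)
            which[upd] = s
        self._which = which
        self._shape = (n, c, h, w, p)
        return best

    def backward(self, dy):
        k = self.kernel
        n, c, h, w, p = self._shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for s, (i, j) in enumerate((i, j) for i in range(k) for j in range(k)):
            mask = self._which == s
            dxp[:, :, i:i + h, j:j + w] += np.where(mask, dy, 0.0)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class InceptionModule(Layer):
    def __init__(self, cfg: InceptionModuleConfig, in_channels: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.in_channels = in_channels
        self.p1 = Sequential(Conv2d(in_channels, cfg.c1, 1, rng), ReLU())
        self.p3 = Sequential(Conv2d(in_channels, cfg.c3_reduce, 1, rng), ReLU(),
                             Conv2d(cfg.c3_reduce, cfg.c3, 3, rng), ReLU())
        self.p5 = Sequential(Conv2d(in_channels, cfg.c5_reduce, 1, rng), ReLU(),
                             Conv2d(cfg.c5_reduce, cfg.c5, 5, rng), ReLU())
        self.pp = Sequential(MaxPool2dSame(3),
                             Conv2d(in_channels, cfg.pool_proj, 1, rng), ReLU())

    def params(self):
        out = []
        for name, path in (("p1", self.p1), ("p3", self.p3),
                           ("p5", self.p5), ("pp", self.pp)):
            out.extend((f"{name}.{pn}", p) for pn, p in path.params())
        return out

    def forward(self, x, train=False):
        outs = [path.forward(x, train)
                for path in (self.p1, self.p3, self.p5, self.pp)]
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        cfg = self.cfg
        edges = np.cumsum([0, cfg.c1, cfg.c3, cfg.c5, cfg.pool_proj])
        dx = None
        for path, (a, b) in zip((self.p1, self.p3, self.p5, self.pp),
                                zip(edges[:-1], edges[1:])):
            d = path.backward(dy[:, a:b])
            dx = d if dx is None else dx + d
        return dx


@dataclass(frozen=True)
class BackboneConfig:
    """Width-scalable Inception-v3-style backbone: conv stem followed by
    inception modules with stride-2 max pooling between stages."""
    in_channels: int = 3
    stem_channels: tuple[int, int] = (16, 32)
    stage_scales: tuple[float, ...] = (1.0, 1.5, 2.0)
    width_factor: float = 1.0


class InceptionBackbone(Layer):
    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        s1, s2 = (max(1, int(round(c * cfg.width_factor)))
                  for c in cfg.stem_channels)
        self.stem = Sequential(
            Conv2d(cfg.in_channels, s1, 3, rng, stride=2), ReLU(),
            MaxPool2d(2),
            Conv2d(s1, s2, 3, rng), ReLU(),
        )
        self.stages: list[Layer] = []
        ch = s2
        base = InceptionModuleConfig()
        for scale in cfg.stage_scales:
            mod_cfg = base.scaled(scale * cfg.width_factor)
            self.stages.append(InceptionModule(mod_cfg, ch, rng))
            self.stages.append(MaxPool2d(2))
            ch = mod_cfg.out_channels
        self.out_channels = ch
        self._all = Sequential(self.stem, *self.stages)

    def params(self):
        return self._all.params()

    def forward(self, x, train=False):
        return self._all.forward(x, train)

    def backward(self, dy):
        return self._all.backward(dy)
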
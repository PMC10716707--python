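"""The two-branch chest X-ray classification network.

A global branch (Inception-style convolutional backbone -> global max
pooling -> dense -> dropout) captures image-wide context, while a local
branch (three inception modules -> Vision Transformer) captures
finer-grained structure.  The two branch embeddings are concatenated and
passed through a three-layer head of 64, 32 and 14 units; the final
layer is sigmoid-activated, one unit per finding label, for multilabel
classification.  The activations of those last three layers (widths 64,
32, 14) are exposed by name: they are the latent features handed to the
classical-ML stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn.attention import ViT, ViTConfig
from .nn.inception import (BackboneConfig, InceptionBackbone,
                           InceptionModule, InceptionModuleConfig)

HEAD_WIDTHS = (64, 32, 14)
LATENT_LAYERS = (-1, -2, -3)


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 224
    in_channels: int = 3
    n_labels: int = 14
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    pretrained_backbone: bool = False
    global_dense: int = 256
    global_dropout: float = 0.3
    local_modules: tuple[InceptionModuleConfig, ...] = (
        InceptionModuleConfig(),
        InceptionModuleConfig(),
        InceptionModuleConfig(),
    )
    vit: ViTConfig = field(default_factory=ViTConfig)
    head_widths: tuple[int, int, int] = HEAD_WIDTHS
    use_local_branch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size < 32:
            raise ValueError("input_size must be >= 32")
        if len(self.local_modules) != 3:
            raise ValueError("the local branch uses exactly three inception modules")
        if self.head_widths[-1] != self.n_labels:
            raise ValueError(
                f"last head width {self.head_widths[-1]} must equal "
                f"n_labels {self.n_labels}")

    @classmethod
    def desk_scale(cls, input_size: int = 64, seed: int = 0) -> "ModelConfig":
        """A small profile for CPU-scale experiments and tests."""
        scale = 0.5
        return cls(
            input_size=input_size,
            backbone=BackboneConfig(stem_channels=(8, 16), width_factor=0.5),
            global_dense=64,
            local_modules=tuple(
                InceptionModuleConfig().scaled(scale) for _ in range(3)),
            vit=ViTConfig(patch_size=max(1, input_size // 32), embed_dim=32,
                          depth=2, heads=2, mlp_ratio=2.0, dropout=0.1),
            seed=seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(listify(self.to_dict())))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["backbone"] = BackboneConfig(**{
            **d["backbone"],
            "stem_channels": tuple(d["backbone"]["stem_channels"]),
            "stage_scales": tuple(d["backbone"]["stage_scales"]),
        })
        d["vit"] = ViTConfig(**d["vit"])
        d["local_modules"] = tuple(InceptionModuleConfig(**m)
                                   for m in d["local_modules"])
        d["head_widths"] = tuple(d["head_widths"])
        return cls(**d)


class FusionNet:
    """Two-branch multilabel CXR classifier with named latent taps.

    Taps: layer -1 is the 14-unit sigmoid output, layer -2 the 32-unit
    activation, layer -3 the 64-unit activation.
    """

    def __init__(self, cfg: ModelConfig):
        if cfg.pretrained_backbone:
            raise ValueError(
                "no bundled pretrained backbone weights; construct with "
                "pretrained_backbone=False and pretrain on a multilabel stream")
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed).spawn(1)[0])

        # Global branch
        self.backbone = InceptionBackbone(cfg.backbone, rng)
        self.gmp = nn.GlobalMaxPool2d()
        self.g_dense = nn.Dense(self.backbone.out_channels, cfg.global_dense, rng)
        self.g_act = nn.ReLU()
        self.g_drop = nn.Dropout(cfg.global_dropout, self._dropout_rng)
        fused_width = cfg.global_dense

        # Local branch: three inception modules with stride-2 pooling
        # between them, then a ViT over the final feature map.
        self.local_layers: list[nn.Layer] = []
        if cfg.use_local_branch:
            ch = cfg.in_channels
            side = cfg.input_size
            for mod_cfg in cfg.local_modules:
                self.local_layers.append(InceptionModule(mod_cfg, ch, rng))
                self.local_layers.append(nn.MaxPool2d(2))
                ch = mod_cfg.out_channels
                side //= 2
            self.vit = ViT(cfg.vit, (ch, side, side), rng)
            fused_width += cfg.vit.embed_dim
        else:
            self.vit = None

        w64, w32, w14 = cfg.head_widths
        self.h1 = nn.Dense(fused_width, w64, rng)
        self.a1 = nn.ReLU()
        self.h2 = nn.Dense(w64, w32, rng)
        self.a2 = nn.ReLU()
        self.h3 = nn.Dense(w32, w14, rng)
        self.out_act = nn.Sigmoid()
        self._fused_width = fused_width
        self.activations: dict[int, np.ndarray] = {}

    # ---- parameters -------------------------------------------------
    def params(self) -> list[tuple[str, nn.Param]]:
        groups: list[tuple[str, nn.Layer]] = [
            ("backbone", self.backbone), ("g_dense", self.g_dense)]
        for i, layer in enumerate(self.local_layers):
            groups.append((f"local{i}", layer))
        if self.vit is not None:
            groups.append(("vit", self.vit))
        groups += [("h1", self.h1), ("h2", self.h2), ("h3", self.h3)]
        out = []
        for gname, layer in groups:
            out.extend((f"{gname}.{pn}", p) for pn, p in layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for _, p in self.params())

    # ---- forward / backward ----------------------------------------
    def _prep(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 3:                       # (N, H, W) grayscale
            x = np.repeat(x[:, None, :, :], self.cfg.in_channels, axis=1)
        if x.ndim != 4:
            raise ValueError(f"expected (N,H,W) or (N,C,H,W), got {x.shape}")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}")
        return x

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._prep(images)
        g = self.backbone.forward(x, train)
        g = self.gmp.forward(g, train)
        g = self.g_act.forward(self.g_dense.forward(g, train), train)
        g = self.g_drop.forward(g, train)

        if self.vit is not None:
            l = x
            for layer in self.local_layers:
                l = layer.forward(l, train)
            l = self.vit.forward(l, train)
            if g.shape[0] != l.shape[0]:
                raise ValueError(
                    f"branch concatenation mismatch: global {g.shape} "
                    f"vs local {l.shape}")
            fused = np.concatenate([g, l], axis=1)
        else:
            fused = g

        z64 = self.a1.forward(self.h1.forward(fused, train), train)
        z32 = self.a2.forward(self.h2.forward(z64, train), train)
        self._pre_sigmoid = self.h3.forward(z32, train)
        p = self.out_act.forward(self._pre_sigmoid, train)
        self.activations = {-3: z64, -2: z32, -1: p}
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probabilities) through the network."""
        d = self.out_act.backward(dp)
        d = self.h3.backward(d)
        d = self.h2.backward(self.a2.backward(d))
        d = self.h1.backward(self.a1.backward(d))
        gw = self.cfg.global_dense
        dg, dl = d[:, :gw], d[:, gw:]
        dg = self.g_dense.backward(self.g_act.backward(self.g_drop.backward(dg)))
        self.backbone.backward(self.gmp.backward(dg))
        if self.vit is not None:
            dloc = self.vit.backward(dl)
            for layer in reversed(self.local_layers):
                dloc = layer.backward(dloc)

    # ---- latent extraction -----------------------------------------
    def extract_latent(self, images, layer: int = -1,
                       batch_size: int = 16) -> np.ndarray:
        """Per-image latent vectors from one of the last three layers
        (-1: 14-unit sigmoid output; -2: 32 units; -3: 64 units).
        Inference mode; batching does not affect the result."""
        if layer not in LATENT_LAYERS:
            raise ValueError(f"layer must be one of {LATENT_LAYERS}, got {layer}")
        images = np.asarray(images, dtype=float)
        chunks = []
        for start in range(0, len(images), batch_size):
            self.forward(images[start:start + batch_size], train=False)
            chunks.append(self.activations[layer])
        return np.concatenate(chunks, axis=0)

    # ---- serialization ---------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write parameters as .npz plus a JSON architecture sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {name: p.value for name, p in self.params()}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(
            json.dumps(self.cfg.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FusionNet":
        path = Path(path)
        cfg = ModelConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            for name, p in model.params():
                p.value[...] = data[name]
        return model


def build_model(cfg: ModelConfig | None = None) -> FusionNet:
    return FusionNet(cfg or ModelConfig())
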
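"""Network construction: backbones, CAN heads, CRN and 3-D CNN baselines.

Three families share one volume-batch contract of shape
``(batch, branches, slices, 3, H, W)``:

* ``CAN`` -- a 2-D backbone encodes each axial slice, slice-wise
  attention pools the per-slice features into one descriptor per
  volume, and a fully-connected head classifies.  With several
  time-point branches the backbone and attention are shared (Siamese)
  and the attended features are concatenated before the head.
* ``CRN`` -- same wiring with the attention pooling replaced by a GRU
  over the slice sequence (final hidden state as the volume feature).
* ``CNN3D`` -- the volumetric analogue of the reference backbone
  (3x3x3 kernels, same channel progression, each axis pooled while its
  extent permits), single time point only.

Two backbone specs ship: ``reference_vgg16`` (the standard 13-conv /
5-pool stack; at 64 x 64 input the final pooled map flattens to a
2048-length per-slice feature) and ``tiny_test`` (3 small conv blocks,
feature length 64) which trains on one CPU in minutes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import SliceFeatureMatrix
from .volumes import NoduleVolume, replicate_channels

__all__ = [
    "BackboneSpec",
    "ModelConfig",
    "Backbone",
    "Model",
    "CANModel",
    "CRNModel",
    "CNN3DModel",
    "build_backbone",
    "build_model",
    "build_can",
    "build_crn",
    "build_cnn3d",
    "slice_features",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

# channel progressions; "M" = 2x max-pool, "A4" = 4x average-pool
_BACKBONE_CFGS: dict[str, list] = {
    "reference_vgg16": [64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
                        512, 512, 512, "M", 512, 512, 512, "M"],
    "tiny_test": [8, "M", 16, "M", 16, "A4"],
}
_DEFAULT_INPUT = {"reference_vgg16": 64, "tiny_test": 32}
_DEFAULT_SLICES = {"reference_vgg16": 20, "tiny_test": 10}


_POOL_SIZES = {"M": 2, "M4": 4, "A4": 4}


def _pool_factor(cfg: list) -> int:
    f = 1
    for item in cfg:
        if isinstance(item, str):
            f *= _POOL_SIZES[item]
    return f


def _final_channels(cfg: list) -> int:
    return [c for c in cfg if isinstance(c, int)][-1]


@dataclass(frozen=True)
class BackboneSpec:
    """Which 2-D slice encoder to build and at what input size."""

    name: str = "tiny_test"
    input_size: int | None = None
    pretrained: bool = False
    pretrained_path: str | None = None

    def __post_init__(self):
        if self.name not in _BACKBONE_CFGS:
            raise ValueError(
                f"unsupported backbone {self.name!r}; supported: "
                f"{sorted(_BACKBONE_CFGS)}"
            )
        if self.input_size is None:
            object.__setattr__(self, "input_size", _DEFAULT_INPUT[self.name])
        cfg = _BACKBONE_CFGS[self.name]
        if self.input_size % _pool_factor(cfg) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by the total "
                f"pool factor {_pool_factor(cfg)} of {self.name}"
            )

    @property
    def feature_dim(self) -> int:
        cfg = _BACKBONE_CFGS[self.name]
        side = self.input_size // _pool_factor(cfg)
        return _final_channels(cfg) * side * side


@dataclass
class ModelConfig:
    """Variant + wiring of one classifier.

    ``head_width`` defaults to 128 for a single time point and
    ``2**(6 + M)`` for an M-branch Siamese model; supplying a different
    value is rejected.
    """

    variant: str = "CAN"
    M_branches: int = 1
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    head_width: int | None = None
    rnn_width: int = 128
    init: str = "random"
    volume_shape: tuple[int, int, int] | None = None  # used by CNN3D flattening

    def __post_init__(self):
        if self.variant not in ("CAN", "CRN", "CNN3D"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.M_branches not in (1, 2, 3):
            raise ValueError(f"M_branches must be 1, 2 or 3, got {self.M_branches}")
        if self.variant == "CNN3D" and self.M_branches != 1:
            raise ValueError("CNN3D is defined for a single time point only")
        expected = 128 if self.M_branches == 1 else 2 ** (6 + self.M_branches)
        if self.head_width is None:
            self.head_width = expected
        elif self.head_width != expected:
            raise ValueError(
                f"head_width must be {expected} for M_branches={self.M_branches}, "
                f"got {self.head_width}"
            )
        if self.init not in ("random", "pretrained"):
            raise ValueError(f"init must be 'random' or 'pretrained', got {self.init!r}")
        if self.volume_shape is None:
            s = self.backbone.input_size
            self.volume_shape = (_DEFAULT_SLICES[self.backbone.name], s, s)


class Backbone:
    """Shared 2-D slice encoder: (batch, 3, H, W) -> (batch, D)."""

    #: fixed input standardisation: a lung-windowed crop is mostly
    #: parenchyma (~0.11 after windowing), so recentre and rescale for
    #: healthy activation magnitudes
    INPUT_SHIFT, INPUT_SCALE = 0.125, 4.0

    def __init__(self, spec: BackboneSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nn.Layer] = [nn.InputScale(self.INPUT_SHIFT, self.INPUT_SCALE)]
        c_in = 3
        for item in _BACKBONE_CFGS[spec.name]:
            if item == "M" or item == "M4":
                layers.append(nn.MaxPool2D(_POOL_SIZES[item]))
            elif item == "A4":
                layers.append(nn.AvgPool2D(4))
            else:
                layers.append(nn.Conv2D(c_in, item, rng))
                layers.append(nn.ReLU())
                c_in = item
        layers.append(nn.Flatten())
        self.net = nn.Sequential(layers)
        self.feature_dim = spec.feature_dim
        if spec.pretrained or spec.pretrained_path:
            self.load_weights(spec.pretrained_path)

    def load_weights(self, path: str | None) -> None:
        """Adapter for externally trained weights stored as ``.npz``."""
        if path is None:
            raise ValueError(
                "pretrained backbone requested but no pretrained_path given; "
                "supply an .npz of this backbone's named parameters"
            )
        data = np.load(path)
        params = self.net.named_params()
        for k, v in params.items():
            if k not in data:
                raise ValueError(f"pretrained file {path} lacks parameter {k!r}")
            if data[k].shape != v.shape:
                raise ValueError(
                    f"pretrained parameter {k!r} has shape {data[k].shape}, "
                    f"expected {v.shape}"
                )
            v[...] = data[k]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != 3 or x.shape[2] != self.spec.input_size \
                or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"backbone {self.spec.name!r} expects (batch, 3, "
                f"{self.spec.input_size}, {self.spec.input_size}) slices, got {x.shape}"
            )
        return self.net.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)


class Model:
    """Base classifier: flat parameter access, probabilities, checkpointing."""

    config: ModelConfig

    def _components(self) -> dict[str, object]:
        raise NotImplementedError

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for prefix, comp in self._components().items():
            if isinstance(comp, Backbone):
                out.update(comp.net.named_params(prefix + "."))
            elif isinstance(comp, nn.Sequential):
                out.update(comp.named_params(prefix + "."))
            else:
                for k, v in comp.params.items():
                    out[f"{prefix}.{k}"] = v
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for prefix, comp in self._components().items():
            if isinstance(comp, Backbone):
                out.update(comp.net.named_grads(prefix + "."))
            elif isinstance(comp, nn.Sequential):
                out.update(comp.named_grads(prefix + "."))
            else:
                for k, v in comp.grads.items():
                    out[f"{prefix}.{k}"] = v
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x), axis=-1)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        logits = self.forward(x, train=True)
        loss, dlogits = nn.cross_entropy(logits, y)
        self.backward(dlogits)
        return loss, self.gradients()

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def _check_input(self, x: np.ndarray) -> tuple[int, int, int]:
        if x.ndim != 6:
            raise ValueError(
                "expected input of shape (batch, branches, slices, 3, H, W), "
                f"got {x.shape}"
            )
        B, M, N = x.shape[:3]
        if M != self.config.M_branches:
            raise ValueError(
                f"model has {self.config.M_branches} branches, input has {M}"
            )
        return B, M, N


class CANModel(Model):
    """Convolutional attention network, 1-3 weight-shared branches."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.backbone = Backbone(config.backbone, rng)
        D = self.backbone.feature_dim
        self.attention = nn.SliceAttention(D, rng)
        self.fc1 = nn.Dense(config.M_branches * D, config.head_width, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Dense(config.head_width, 2, rng)

    def _components(self):
        return {"backbone": self.backbone, "attention": self.attention,
                "fc1": self.fc1, "fc2": self.fc2}

    def forward(self, x, train=False):
        B, M, N = self._check_input(x)
        D = self.backbone.feature_dim
        feats = self.backbone.forward(x.reshape(B * M * N, *x.shape[3:]), train=train)
        d = self.attention.forward(feats.reshape(B * M, N, D), train=train)
        self._shape = (B, M, N)
        h = self.relu.forward(self.fc1.forward(d.reshape(B, M * D), train=train),
                              train=train)
        return self.fc2.forward(h, train=train)

    def backward(self, dlogits):
        B, M, N = self._shape
        D = self.backbone.feature_dim
        dh = self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))
        dF = self.attention.backward(dh.reshape(B * M, D))
        self.backbone.backward(dF.reshape(B * M * N, D))

    def attention_map(self, x: np.ndarray) -> np.ndarray:
        """Per-branch attention weights, shape (batch, branches, slices)."""
        B, M, N = self._check_input(x)
        self.forward(x)
        return self.attention.alpha.reshape(B, M, N)


class CRNModel(Model):
    """Convolutional recurrent baseline: GRU over the slice sequence."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.backbone = Backbone(config.backbone, rng)
        D = self.backbone.feature_dim
        self.gru = nn.GRU(D, config.rnn_width, rng)
        self.fc1 = nn.Dense(config.M_branches * config.rnn_width, config.head_width, rng)
        self.relu = nn.ReLU()
        self.fc2 = nn.Dense(config.head_width, 2, rng)

    def _components(self):
        return {"backbone": self.backbone, "gru": self.gru,
                "fc1": self.fc1, "fc2": self.fc2}

    def forward(self, x, train=False):
        B, M, N = self._check_input(x)
        D = self.backbone.feature_dim
        feats = self.backbone.forward(x.reshape(B * M * N, *x.shape[3:]), train=train)
        hN = self.gru.forward(feats.reshape(B * M, N, D), train=train)
        self._shape = (B, M, N)
        h = self.relu.forward(
            self.fc1.forward(hN.reshape(B, M * self.config.rnn_width), train=train),
            train=train,
        )
        return self.fc2.forward(h, train=train)

    def backward(self, dlogits):
        B, M, N = self._shape
        D = self.backbone.feature_dim
        dh = self.fc1.backward(self.relu.backward(self.fc2.backward(dlogits)))
        dF = self.gru.backward(dh.reshape(B * M, self.config.rnn_width))
        self.backbone.backward(dF.reshape(B * M * N, D))


def _pool3d_schedule(cfg: list, shape: tuple[int, int, int]) -> tuple[list, int]:
    """Per-stage 3-D pool sizes (an axis is pooled while its extent >= 2)
    and the resulting flattened feature length."""
    extents = list(shape)
    pools = []
    for item in cfg:
        if isinstance(item, str):
            base = _POOL_SIZES[item]
            p = [min(base, e) if e >= 2 else 1 for e in extents]
            pools.append(tuple(p))
            extents = [e // q for e, q in zip(extents, p)]
    if any(e < 1 for e in extents):
        raise ValueError(f"volume shape {shape} is incompatible with the pooling schedule")
    return pools, _final_channels(cfg) * int(np.prod(extents))


class CNN3DModel(Model):
    """Volumetric analogue of the reference backbone, Glorot-initialised."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        cfg = _BACKBONE_CFGS[config.backbone.name]
        pools, flat_dim = _pool3d_schedule(cfg, config.volume_shape)
        layers: list[nn.Layer] = [
            nn.InputScale(Backbone.INPUT_SHIFT, Backbone.INPUT_SCALE)
        ]
        c_in, stage = 1, 0
        for item in cfg:
            if isinstance(item, str):
                pool_cls = nn.AvgPool3D if item == "A4" else nn.MaxPool3D
                layers.append(pool_cls(pools[stage]))
                stage += 1
            else:
                layers.append(nn.Conv3D(c_in, item, rng))
                layers.append(nn.ReLU())
                c_in = item
        layers.append(nn.Flatten())
        layers.append(nn.Dense(flat_dim, 128, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dense(128, 128, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dense(128, 2, rng))
        self.net = nn.Sequential(layers)

    def _components(self):
        return {"net": self.net}

    def forward(self, x, train=False):
        B, M, N = self._check_input(x)
        if x.shape[2:3] + x.shape[4:] != tuple(self.config.volume_shape):
            raise ValueError(
                f"CNN3D built for volume shape {self.config.volume_shape}, "
                f"got {(x.shape[2], x.shape[4], x.shape[5])}"
            )
        vol = x[:, 0, :, 0][:, None]  # single branch, single channel
        return self.net.forward(vol, train=train)

    def backward(self, dlogits):
        self.net.backward(dlogits)


_VARIANTS = {"CAN": CANModel, "CRN": CRNModel, "CNN3D": CNN3DModel}


def build_backbone(spec: BackboneSpec, rng: np.random.Generator | int = 0) -> Backbone:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return Backbone(spec, rng)


def build_model(config: ModelConfig, rng: np.random.Generator | int = 0) -> Model:
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return _VARIANTS[config.variant](config, rng)


def build_can(config: ModelConfig, rng: np.random.Generator | int = 0) -> CANModel:
    if config.variant != "CAN":
        raise ValueError(f"build_can requires variant='CAN', got {config.variant!r}")
    return build_model(config, rng)


def build_crn(config: ModelConfig, rng: np.random.Generator | int = 0) -> CRNModel:
    if config.variant != "CRN":
        raise ValueError(f"build_crn requires variant='CRN', got {config.variant!r}")
    return build_model(config, rng)


def build_cnn3d(config: ModelConfig, rng: np.random.Generator | int = 0) -> CNN3DModel:
    if config.variant != "CNN3D":
        raise ValueError(f"build_cnn3d requires variant='CNN3D', got {config.variant!r}")
    return build_model(config, rng)


def slice_features(volume: NoduleVolume, backbone: Backbone) -> SliceFeatureMatrix:
    """Encode every axial slice of a preprocessed volume with the shared
    backbone; returns F with one column per slice, slice order preserved."""
    feats = backbone.forward(replicate_channels(volume.voxels))
    return SliceFeatureMatrix(F=feats.T)


def count_parameters(model: Model | Backbone | nn.Layer) -> int:
    """Exact number of trainable scalars (shared weights counted once)."""
    if isinstance(model, Model):
        return int(sum(p.size for p in model.parameters().values()))
    if isinstance(model, Backbone):
        return model.net.param_count()
    return model.param_count()


CHECKPOINT_SCHEMA = 1


def save_checkpoint(model: Model, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(model.config)
    meta = {"schema": CHECKPOINT_SCHEMA, "config": cfg}
    np.savez(path, __meta__=json.dumps(meta), **model.parameters())


def load_checkpoint(path: Path) -> Model:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    if meta.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
    cfg = meta["config"]
    cfg["backbone"] = BackboneSpec(**cfg["backbone"])
    if cfg.get("volume_shape") is not None:
        cfg["volume_shape"] = tuple(cfg["volume_shape"])
    model = build_model(ModelConfig(**cfg), rng=0)
    params = model.parameters()
    for k, v in params.items():
        v[...] = data[k]
    return model
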
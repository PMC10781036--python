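"""Hybrid CVT-ConvMixer classifier for scalogram images.

Two branches extract complementary features from a scalogram:

* a convolutional vision-transformer (CVT) branch: a stack of 3x3
  convolutions (ReLU then batch-norm) with interleaved 2x2 max-pools,
  whose final map is cut into patch tokens, linearly embedded, given
  learned position embeddings, and passed through one transformer
  encoder block before token averaging;
* a ConvMixer branch: a patch-embedding stem (kernel = stride = patch
  size) followed by depthwise-residual + pointwise blocks, a two-path
  batch-normalized fusion (pointwise path and depthwise-residual path,
  channel-concatenated then GELU), multi-head self-attention over
  spatial positions, and global average pooling.

The branch vectors are fused additively with a (optionally learnable)
scalar mixing coefficient alpha, refined by a residual unit and a
squeeze-excitation-style channel attention gate, and classified by an
MLP head with softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn import Tensor
from .nn.autograd import DTYPE

__all__ = [
    "ModelConfig", "FeatureMap", "HybridModel", "build_model",
    "cvt_features", "convmixer_stem", "convmixer_block", "convmixer_features",
    "fuse", "residual_unit", "channel_attention", "classify",
    "desk_config", "paper_full_config",
]


@dataclass(frozen=True)
class ModelConfig:
    profile: str = "desk"
    image_side: int = 64
    patch_size: int = 8            # ConvMixer stem patch p
    hidden_dim: int = 32           # ConvMixer width h
    mixer_depth: int = 4
    mixer_kernel: int = 3
    cvt_conv_layers: int = 6
    cvt_channel_plan: tuple = (8, 16, 16, 32, 32, 64)
    n_pool: int = 3
    n_tokens: int = 4
    token_dim: int = 64
    n_heads: int = 4
    mlp_hidden: int = 128
    n_classes: int = 8
    alpha: float = 1.0
    alpha_learnable: bool = True
    fuse_mode: str = "sum"         # "sum" (additive, alpha-weighted) or "concat"
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.image_side < self.patch_size:
            raise ValueError("image_side must be >= patch_size")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if len(self.cvt_channel_plan) != self.cvt_conv_layers:
            raise ValueError(
                "cvt_channel_plan length must equal cvt_conv_layers "
                f"({len(self.cvt_channel_plan)} vs {self.cvt_conv_layers})"
            )
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        if (2 * self.hidden_dim) % self.n_heads:
            raise ValueError("2*hidden_dim must be divisible by n_heads")
        side = self.image_side
        for _ in range(self.n_pool):
            side //= 2
        if side < 1:
            raise ValueError("n_pool too large for image_side")


def desk_config(n_classes: int = 8, seed: int = 0, **overrides) -> ModelConfig:
    """Small profile sized for single-CPU experiments."""
    return replace(ModelConfig(), n_classes=n_classes, seed=seed, **overrides)


def paper_full_config(n_classes: int = 2, seed: int = 0, **overrides) -> ModelConfig:
    """Full-size profile (VGG-like 17-layer CVT stage, 7-block mixer)."""
    plan = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512,
            512, 512, 512, 512)
    return replace(
        ModelConfig(),
        profile="paper-full", image_side=128, patch_size=5, hidden_dim=32,
        mixer_depth=7, cvt_conv_layers=17, cvt_channel_plan=plan, n_pool=5,
        n_tokens=7, token_dim=1024, n_heads=8, mlp_hidden=2048,
        n_classes=n_classes, seed=seed, **overrides,
    )


@dataclass
class FeatureMap:
    """Role-tagged intermediate activation."""

    values: np.ndarray
    role: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in feature map '{self.role}'")


def _rng(cfg: ModelConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _as_batch(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None]           # (B, 1, H, W)
    return arr


class CVTBranch(nn.Module):
    """Convolutional feature learning + patch-token transformer encoder."""

    def __init__(self, cfg: ModelConfig):
        rng = _rng(cfg, 1)
        self.cfg = cfg
        self.convs = []
        c_in = 1
        for c_out in cfg.cvt_channel_plan:
            self.convs.append(nn.Conv2d(c_in, c_out, 3, rng, pad=1, init="he"))
            c_in = c_out
        self.bns = [nn.BatchNorm2d(c) for c in cfg.cvt_channel_plan]
        L, P = cfg.cvt_conv_layers, cfg.n_pool
        # pools after evenly spaced conv layers
        self.pool_after = {int(np.ceil((i + 1) * L / P)) - 1 for i in range(P)}
        side = cfg.image_side
        for _ in range(P):
            side //= 2
        self.map_side = side
        c_last = cfg.cvt_channel_plan[-1]
        # slice the map into n_tokens horizontal strips (zero-pad rows if needed)
        self.strip_rows = int(np.ceil(side / cfg.n_tokens))
        self.pad_rows = self.strip_rows * cfg.n_tokens - side
        patch_dim = c_last * self.strip_rows * side
        self.embed = nn.Linear(patch_dim, cfg.token_dim, rng, init="xavier")
        self.pos = Tensor(
            rng.normal(0, 0.02, size=(1, cfg.n_tokens, cfg.token_dim)).astype(DTYPE),
            requires_grad=True,
        )
        self.ln1 = nn.LayerNorm(cfg.token_dim)
        self.att = nn.MultiHeadSelfAttention(cfg.token_dim, cfg.n_heads, rng)
        self.ln2 = nn.LayerNorm(cfg.token_dim)
        self.ff1 = nn.Linear(cfg.token_dim, 2 * cfg.token_dim, rng, init="xavier")
        self.ff2 = nn.Linear(2 * cfg.token_dim, cfg.token_dim, rng, init="xavier")

    def forward(self, x: Tensor) -> Tensor:
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns)):
            x = bn(conv(x).relu())
            if i in self.pool_after:
                x = nn.maxpool2d(x, 2)
        B, C, H, W = x.shape
        if self.pad_rows:
            pad = Tensor(np.zeros((B, C, self.pad_rows, W), dtype=DTYPE))
            x = nn.concat([x, pad], axis=2)
        nt, sr = self.cfg.n_tokens, self.strip_rows
        tokens = x.reshape(B, C, nt, sr, W).transpose(0, 2, 1, 3, 4).reshape(
            B, nt, C * sr * W
        )
        t = self.embed(tokens) + self.pos
        t = t + self.att(self.ln1(t))
        t = t + self.ff2(self.ff1(self.ln2(t)).gelu())
        return t.mean(axis=1)        # (B, token_dim)


class MixerBlock(nn.Module):
    """Depthwise-residual block followed by a pointwise convolution."""

    def __init__(self, h: int, kernel: int, rng):
        self.dw = nn.Conv2d(h, h, kernel, rng, pad=kernel // 2, groups=h, init="he")
        self.bn_dw = nn.BatchNorm2d(h)
        self.pw = nn.Conv2d(h, h, 1, rng, init="he")
        self.bn_pw = nn.BatchNorm2d(h)

    def spatial(self, z: Tensor) -> Tensor:
        """Z_l = BNorm(GELU(DepthwiseConv(Z_{l-1}))) + Z_{l-1}"""
        return self.bn_dw(self.dw(z).gelu()) + z

    def forward(self, z: Tensor) -> Tensor:
        zl = self.spatial(z)
        return self.bn_pw(self.pw(zl).gelu())


class ConvMixerBranch(nn.Module):
    def __init__(self, cfg: ModelConfig):
        rng = _rng(cfg, 2)
        self.cfg = cfg
        h, p = cfg.hidden_dim, cfg.patch_size
        self.stem_conv = nn.Conv2d(1, h, p, rng, stride=p, init="he")
        self.stem_bn = nn.BatchNorm2d(h)
        self.blocks = [MixerBlock(h, cfg.mixer_kernel, rng) for _ in range(cfg.mixer_depth)]
        # two-path fused output: pointwise path + depthwise-residual path
        self.fuse_pw = nn.Conv2d(h, h, 1, rng, init="he")
        self.fuse_bn_pw = nn.BatchNorm2d(h)
        self.fuse_bn_conv = nn.BatchNorm2d(h)
        self.att = nn.MultiHeadSelfAttention(2 * h, cfg.n_heads, rng)

    def stem(self, x: Tensor) -> Tensor:
        """Z_0 = BNorm(GELU(Conv_h(X, stride=p, kernel=p)))"""
        return self.stem_bn(self.stem_conv(x).gelu())

    def fused_map(self, x: Tensor) -> Tensor:
        z = self.stem(x)
        for block in self.blocks[:-1]:
            z = block(z)
        f = z                         # input to the last mixer block
        last = self.blocks[-1]
        path_conv = self.fuse_bn_conv(last.spatial(f))
        path_pw = self.fuse_bn_pw(self.fuse_pw(f))
        return nn.concat([path_pw, path_conv], axis=1).gelu()   # (B, 2h, H', W')

    def forward(self, x: Tensor) -> Tensor:
        m = self.fused_map(x)
        B, C, H, W = m.shape
        tokens = m.reshape(B, C, H * W).transpose(0, 2, 1)       # (B, T, 2h)
        att = self.att(tokens)
        return att.mean(axis=1)       # global average pool -> (B, 2h)


class Fuse(nn.Module):
    """Dense_Features_map = P(CVT_map) + alpha * P(ConvMixer_map).

    Linear projections are created only when a branch dimension differs
    from the fusion dimension; otherwise the branch passes through
    unchanged.  In "concat" mode the projected vectors are concatenated
    instead of summed.
    """

    def __init__(self, d_cvt: int, d_cm: int, cfg: ModelConfig):
        rng = _rng(cfg, 3)
        self.mode = cfg.fuse_mode
        self.d = max(d_cvt, d_cm) if self.mode == "sum" else d_cvt + d_cm
        self.proj_cvt = (nn.Linear(d_cvt, self.d, rng, init="xavier")
                         if (self.mode == "sum" and d_cvt != self.d) else None)
        self.proj_cm = (nn.Linear(d_cm, self.d, rng, init="xavier")
                        if (self.mode == "sum" and d_cm != self.d) else None)
        self.alpha = Tensor(np.asarray(cfg.alpha, dtype=DTYPE),
                            requires_grad=cfg.alpha_learnable)

    def forward(self, cvt_vec: Tensor, cm_vec: Tensor) -> Tensor:
        a = self.proj_cvt(cvt_vec) if self.proj_cvt is not None else cvt_vec
        b = self.proj_cm(cm_vec) if self.proj_cm is not None else cm_vec
        if self.mode == "concat":
            return nn.concat([a, b], axis=1)
        if a.shape != b.shape:
            raise ValueError(
                f"fusion dimension mismatch {a.shape} vs {b.shape} with projection disabled"
            )
        return a + self.alpha * b


class ResidualUnit(nn.Module):
    """output = ReLU(x + transform(x)) with a single linear transform."""

    def __init__(self, d: int, cfg: ModelConfig):
        self.lin = nn.Linear(d, d, _rng(cfg, 4), init="xavier")

    def forward(self, x: Tensor) -> Tensor:
        return (x + self.lin(x)).relu()


class ChannelAttention(nn.Module):
    """Squeeze-excitation gate: Features = sigmoid(FC2(ReLU(FC1(pool(x))))) * x."""

    def __init__(self, d: int, cfg: ModelConfig, reduction: int = 4):
        rng = _rng(cfg, 5)
        hidden = max(d // reduction, 1)
        self.fc1 = nn.Linear(d, hidden, rng, init="xavier")
        self.fc2 = nn.Linear(hidden, d, rng, init="xavier")

    def weights(self, x: Tensor) -> Tensor:
        pooled = x if x.ndim == 2 else x.mean(axis=(2, 3))
        return self.fc2(self.fc1(pooled).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        w = self.weights(x)
        if x.ndim == 4:
            B, C = w.shape
            w = w.reshape(B, C, 1, 1)
        return w * x


class Head(nn.Module):
    """MLP head: hidden ReLU layer then class logits."""

    def __init__(self, d: int, cfg: ModelConfig):
        rng = _rng(cfg, 6)
        self.fc1 = nn.Linear(d, cfg.mlp_hidden, rng, init="he")
        self.fc2 = nn.Linear(cfg.mlp_hidden, cfg.n_classes, rng, init="xavier")

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class HybridModel(nn.Module):
    def __init__(self, cfg: ModelConfig, use_convmixer: bool = True):
        self.cfg = cfg
        self.use_convmixer = use_convmixer
        self.cvt = CVTBranch(cfg)
        self.cm = ConvMixerBranch(cfg) if use_convmixer else None
        d_cvt = cfg.token_dim
        d_cm = 2 * cfg.hidden_dim
        self.fusion = Fuse(d_cvt, d_cm, cfg)
        self.res = ResidualUnit(self.fusion.d, cfg)
        self.chatt = ChannelAttention(self.fusion.d, cfg)
        self.head = Head(self.fusion.d, cfg)
        self.eval()

    def logits(self, x: Tensor) -> Tensor:
        cvt_vec = self.cvt(x)
        if self.use_convmixer:
            cm_vec = self.cm(x)
        else:
            B = x.shape[0]
            cm_vec = Tensor(np.zeros((B, 2 * self.cfg.hidden_dim), dtype=DTYPE))
        fused = self.fusion(cvt_vec, cm_vec)
        feat = self.chatt(self.res(fused))
        return self.head(feat)

    def forward(self, images) -> Tensor:
        x = images if isinstance(images, Tensor) else Tensor(_as_batch(images))
        return nn.softmax(self.logits(x), axis=-1)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities in eval mode, batched, as a numpy array."""
        was_training = self.training
        self.eval()
        arr = _as_batch(images)
        out = [self.forward(Tensor(arr[i : i + batch_size])).data
               for i in range(0, arr.shape[0], batch_size)]
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)

    def feature_maps(self, image) -> dict[str, FeatureMap]:
        """Run one image through the network, collecting role-tagged activations."""
        x = Tensor(_as_batch(image))
        cvt_vec = self.cvt(x)
        if self.use_convmixer:
            z0 = self.cm.stem(x)
            cm_vec = self.cm(x)
        else:
            z0 = Tensor(np.zeros((1, self.cfg.hidden_dim, 1, 1), dtype=DTYPE))
            cm_vec = Tensor(np.zeros((1, 2 * self.cfg.hidden_dim), dtype=DTYPE))
        fused = self.fusion(cvt_vec, cm_vec)
        res = self.res(fused)
        w = self.chatt.weights(res)
        feat = self.chatt(res)
        probs = nn.softmax(self.head(feat), axis=-1)
        return {
            "Z0": FeatureMap(z0.data, "Z0"),
            "CVT_map": FeatureMap(cvt_vec.data, "CVT_map"),
            "ConvMixer_map": FeatureMap(cm_vec.data, "ConvMixer_map"),
            "Dense_Features_map": FeatureMap(fused.data, "Dense_Features_map"),
            "Output": FeatureMap(res.data, "Output"),
            "W": FeatureMap(w.data, "W"),
            "Features": FeatureMap(feat.data, "Features"),
            "probabilities": FeatureMap(probs.data, "probabilities"),
        }


def build_model(cfg: ModelConfig, use_convmixer: bool = True) -> HybridModel:
    """Assemble the full network; parameter init is deterministic in cfg.seed."""
    return HybridModel(cfg, use_convmixer=use_convmixer)


# -- functional views of the individual stages (each builds a fresh,
# -- seed-deterministic module unless one is supplied) ---------------------

def cvt_features(image, cfg: ModelConfig, branch: CVTBranch | None = None) -> FeatureMap:
    branch = CVTBranch(cfg) if branch is None else branch
    branch.eval()
    return FeatureMap(branch(Tensor(_as_batch(image))).data, "CVT_map")


def convmixer_stem(image, cfg: ModelConfig,
                   branch: ConvMixerBranch | None = None) -> FeatureMap:
    branch = ConvMixerBranch(cfg) if branch is None else branch
    branch.eval()
    return FeatureMap(branch.stem(Tensor(_as_batch(image))).data, "Z0")


def convmixer_block(z: np.ndarray, cfg: ModelConfig,
                    block: MixerBlock | None = None) -> FeatureMap:
    if np.asarray(z).shape[1] != cfg.hidden_dim:
        raise ValueError(
            f"expected {cfg.hidden_dim} channels, got {np.asarray(z).shape[1]}"
        )
    block = MixerBlock(cfg.hidden_dim, cfg.mixer_kernel, _rng(cfg, 2)) if block is None else block
    block.eval()
    return FeatureMap(block(Tensor(z)).data, "Zl+1")


def convmixer_features(image, cfg: ModelConfig,
                       branch: ConvMixerBranch | None = None) -> FeatureMap:
    branch = ConvMixerBranch(cfg) if branch is None else branch
    branch.eval()
    return FeatureMap(branch(Tensor(_as_batch(image))).data, "ConvMixer_map")


def fuse(cvt_map: np.ndarray, convmixer_map: np.ndarray, cfg: ModelConfig,
         module: Fuse | None = None) -> FeatureMap:
    a, b = np.atleast_2d(cvt_map), np.atleast_2d(convmixer_map)
    module = Fuse(a.shape[1], b.shape[1], cfg) if module is None else module
    return FeatureMap(module(Tensor(a), Tensor(b)).data, "Dense_Features_map")


def residual_unit(x: np.ndarray, cfg: ModelConfig,
                  module: ResidualUnit | None = None) -> FeatureMap:
    x = np.atleast_2d(x)
    module = ResidualUnit(x.shape[1], cfg) if module is None else module
    return FeatureMap(module(Tensor(x)).data, "Output")


def channel_attention(features: np.ndarray, cfg: ModelConfig,
                      module: ChannelAttention | None = None) -> FeatureMap:
    x = np.atleast_2d(features)
    d = x.shape[1]
    module = ChannelAttention(d, cfg) if module is None else module
    return FeatureMap(module(Tensor(x)).data, "Features")


def classify(features: np.ndarray, cfg: ModelConfig,
             module: Head | None = None) -> np.ndarray:
    x = np.atleast_2d(features)
    module = Head(x.shape[1], cfg) if module is None else module
    return nn.softmax(module(Tensor(x)), axis=-1).data
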
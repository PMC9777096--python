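"""The convolutional vision transformer for heart-sound spectrograms.

Architecture (all sizes configurable through :class:`ModelConfig`):

* **Backbone** — a VGG-style stack of 17 3x3 convolutions (stride/pad 1,
  BatchNorm + ReLU after every layer) in six stages; a 2x2 stride-2 max
  pool after each of the first five stages halves the spatial dimension,
  and the channel width doubles after each pool. A 224x224 input yields a
  7x7 map with the final stage width (1024 in the full profile).
* **LBP branch** — the grayscale input's local-binary-pattern code map is
  passed through a small conv stem that mirrors the five poolings, ending
  at the same spatial size and channel count as the backbone output.
* **Attentional selective fusion (ATTSF)** — the two maps are first mixed
  by 1x1 convolutions, ``U = WL*LBP + WC*CNN``; a gate
  ``G = sigmoid(globalContext(U) + localContext(U))`` combines a squeezed
  global descriptor (spatial mean -> bottleneck MLP with reduction 4) with
  a per-pixel 1x1 convolution; the fused output is
  ``G .* (WL*LBP) + (1-G) .* (WC*CNN)``.
* **Tokenizer** — the fused map is split along its width into column
  strips (seven for a 224 input); each strip is flattened and linearly
  projected to the embedding dimension, and learned per-token position
  embeddings are added.
* **Transformer encoder** — pre-norm blocks of 8-head self-attention and
  a feed-forward network, each with a residual connection.
* **MLP head** — mean-pool over tokens, a 2048-wide hidden layer with
  ReLU, a linear output layer, and softmax over the classes.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn.autodiff import Parameter, Tensor, batch_norm, conv2d, max_pool2x2
from .features_lbp import lbp_map, to_gray
from .tfr import SpectroImage


@dataclass
class ModelConfig:
    input_size: int = 224
    stage_widths: tuple[int, ...] = (32, 64, 128, 256, 512, 1024)
    convs_per_stage: tuple[int, ...] = (2, 2, 3, 3, 3, 4)
    embed_dim: int = 1024
    heads: int = 8
    encoder_depth: int = 1
    ffn_hidden: int = 2048
    head_hidden: int = 2048
    num_classes: int = 5
    bottleneck_reduction: int = 4
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if len(self.stage_widths) != 6:
            problems.append("stage_widths must list 6 stages")
        if len(self.convs_per_stage) != len(self.stage_widths):
            problems.append("convs_per_stage must match stage_widths in length")
        if self.input_size % 32 != 0:
            problems.append("input_size must be divisible by 2^5 = 32")
        if self.embed_dim % self.heads != 0:
            problems.append("embed_dim must be divisible by the head count")
        if self.encoder_depth < 1:
            problems.append("encoder_depth must be >= 1")
        if self.num_classes < 2:
            problems.append("num_classes must be >= 2")
        if min(self.stage_widths) // self.bottleneck_reduction < 1:
            problems.append("bottleneck_reduction too large for the narrowest stage")
        if problems:
            raise ValueError("invalid ModelConfig: " + "; ".join(problems))

    @property
    def num_tokens(self) -> int:
        return self.input_size // 32

    @property
    def total_convs(self) -> int:
        return int(sum(self.convs_per_stage))


def paper_profile(**overrides) -> ModelConfig:
    """The published architecture: 224 input, widths 32..1024, 17 convs."""
    return ModelConfig(**overrides)


def test_profile(**overrides) -> ModelConfig:
    """A narrow desk-scale profile (64 input, widths 8..256) for CPU runs."""
    defaults = dict(
        input_size=64,
        stage_widths=(8, 16, 32, 64, 128, 256),
        convs_per_stage=(2, 2, 3, 3, 3, 4),
        embed_dim=256,
        ffn_hidden=512,
        head_hidden=512,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class ConvBNReLU:
    """3x3 (or 1x1) conv, stride 1, same padding, with BatchNorm and ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3,
                 bn: bool = True, relu: bool = True):
        fan_in = cin * k * k
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        )
        self.bias = Parameter(np.zeros(cout))
        self.bn = bn
        self.relu = relu
        if bn:
            self.gamma = Parameter(np.ones(cout))
            self.beta = Parameter(np.zeros(cout))
            self.running_mean = np.zeros(cout, dtype=np.float32)
            self.running_var = np.ones(cout, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        out = conv2d(x, self.weight, self.bias)
        if self.bn:
            out = batch_norm(
                out, self.gamma, self.beta, self.running_mean, self.running_var,
                training=training,
            )
        if self.relu:
            out = out.relu()
        return out

    def parameters(self) -> list[Parameter]:
        ps = [self.weight, self.bias]
        if self.bn:
            ps += [self.gamma, self.beta]
        return ps


class Linear:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 std: float | None = None):
        std = 0.02 if std is None else std
        w = rng.normal(0.0, std, size=(cin, cout))
        # truncate to +-2 std (re-draw outliers)
        bad = np.abs(w) > 2 * std
        while bad.any():
            w[bad] = rng.normal(0.0, std, size=int(bad.sum()))
            bad = np.abs(w) > 2 * std
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]


class LayerNorm:
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class MultiHeadSelfAttention:
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        self.dim, self.heads = dim, heads
        self.head_dim = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.last_attention_: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        n, t, d = x.shape
        h, dh = self.heads, self.head_dim

        def split(y: Tensor) -> Tensor:
            return y.reshape(n, t, h, dh).transpose(0, 2, 1, 3)  # (N,H,T,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        self.last_attention_ = attn.data.copy()
        out = attn @ v  # (N,H,T,dh)
        out = out.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)

    def parameters(self) -> list[Parameter]:
        return sum((m.parameters() for m in (self.wq, self.wk, self.wv, self.wo)), [])


class EncoderBlock:
    """Pre-norm transformer block: MSA + residual, FFN(ReLU) + residual."""

    def __init__(self, dim: int, heads: int, ffn_hidden: int, rng):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, ffn_hidden, rng)
        self.fc2 = Linear(ffn_hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).relu())
        return x

    def parameters(self) -> list[Parameter]:
        return (
            self.norm1.parameters() + self.attn.parameters()
            + self.norm2.parameters() + self.fc1.parameters() + self.fc2.parameters()
        )


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------


class CVTNet:
    """Backbone + LBP stem + ATTSF fusion + tokenizer + encoder + MLP head."""

    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        C = cfg.stage_widths[-1]

        # backbone stages
        self.backbone: list[list[ConvBNReLU]] = []
        cin = 3
        for width, n_convs in zip(cfg.stage_widths, cfg.convs_per_stage):
            stage = []
            for _ in range(n_convs):
                stage.append(ConvBNReLU(cin, width, rng))
                cin = width
            self.backbone.append(stage)

        # LBP stem: five conv+pool blocks then a final conv to full width
        self.lbp_stem: list[ConvBNReLU] = []
        cin = 1
        for width in cfg.stage_widths[:5]:
            self.lbp_stem.append(ConvBNReLU(cin, width, rng))
            cin = width
        self.lbp_stem.append(ConvBNReLU(cin, C, rng))

        # ATTSF fusion
        self.wl = ConvBNReLU(C, C, rng, k=1, bn=False, relu=False)
        self.wc = ConvBNReLU(C, C, rng, k=1, bn=False, relu=False)
        self.local_ctx = ConvBNReLU(C, C, rng, k=1, bn=False, relu=False)
        r = cfg.bottleneck_reduction
        self.global_fc1 = Linear(C, C // r, rng, std=np.sqrt(2.0 / C))
        self.global_fc2 = Linear(C // r, C, rng, std=np.sqrt(2.0 / (C // r)))

        # tokenizer
        h = cfg.num_tokens  # spatial size after five pools
        self.token_proj = Linear(h * C, cfg.embed_dim, rng)
        self.pos_embed = Parameter(
            rng.normal(0.0, 0.02, size=(cfg.num_tokens, cfg.embed_dim))
        )

        # encoder + head
        self.blocks = [
            EncoderBlock(cfg.embed_dim, cfg.heads, cfg.ffn_hidden, rng)
            for _ in range(cfg.encoder_depth)
        ]
        self.final_norm = LayerNorm(cfg.embed_dim)
        self.head_fc1 = Linear(cfg.embed_dim, cfg.head_hidden, rng)
        self.head_fc2 = Linear(cfg.head_hidden, cfg.num_classes, rng)

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[Parameter]:
        ps: list[Parameter] = []
        for stage in self.backbone:
            for layer in stage:
                ps += layer.parameters()
        for layer in self.lbp_stem:
            ps += layer.parameters()
        for m in (self.wl, self.wc, self.local_ctx):
            ps += m.parameters()
        ps += self.global_fc1.parameters() + self.global_fc2.parameters()
        ps += self.token_proj.parameters()
        ps.append(self.pos_embed)
        for blk in self.blocks:
            ps += blk.parameters()
        ps += self.final_norm.parameters()
        ps += self.head_fc1.parameters() + self.head_fc2.parameters()
        return ps

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- components --------------------------------------------------------
    @staticmethod
    def _to_batch(images) -> np.ndarray:
        """SpectroImage(s) or arrays -> (N, H, W, 3) float array."""
        if isinstance(images, SpectroImage):
            images = [images]
        if isinstance(images, (list, tuple)):
            arrs = [
                im.pixels if isinstance(im, SpectroImage) else np.asarray(im)
                for im in images
            ]
            images = np.stack(arrs)
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 3:
            images = images[None]
        return images

    def backbone_forward(self, images, training: bool = False) -> Tensor:
        """RGB batch -> (N, C, S, S) feature map, S = input_size / 32."""
        batch = self._to_batch(images)
        if batch.shape[1] != self.cfg.input_size or batch.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} images, "
                f"got {batch.shape[1]}x{batch.shape[2]}"
            )
        x = Tensor(batch.transpose(0, 3, 1, 2))  # NCHW
        for i, stage in enumerate(self.backbone):
            for layer in stage:
                x = layer(x, training)
            if i < 5:
                x = max_pool2x2(x)
        return x

    def lbp_branch_stem(self, images, training: bool = False) -> Tensor:
        """Grayscale -> LBP code map -> conv stem -> (N, C, S, S)."""
        batch = self._to_batch(images)
        maps = np.stack([lbp_map(to_gray(im)).normalized for im in batch])
        x = Tensor(maps[:, None, :, :])  # (N,1,H,W)
        for i, layer in enumerate(self.lbp_stem[:5]):
            x = layer(x, training)
            x = max_pool2x2(x)
        x = self.lbp_stem[5](x, training)
        return x

    def attsf_fuse(self, cnn_map: Tensor, lbp_features: Tensor,
                   training: bool = False) -> Tensor:
        """Gated fusion of the CNN and LBP feature maps."""
        if cnn_map.shape != lbp_features.shape:
            raise ValueError(
                f"feature map shapes differ: {cnn_map.shape} vs {lbp_features.shape}"
            )
        wl = self.wl(lbp_features, training)
        wc = self.wc(cnn_map, training)
        u = wl + wc
        # global context: spatial mean -> bottleneck MLP, broadcast over pixels
        g_vec = u.mean(axis=(2, 3))  # (N, C)
        g_vec = self.global_fc2(self.global_fc1(g_vec).relu())
        n, c = g_vec.shape
        g_map = g_vec.reshape(n, c, 1, 1)
        # local context: per-pixel 1x1 convolution
        l_map = self.local_ctx(u, training)
        gate = (g_map + l_map).sigmoid()
        return gate * wl + (1.0 - gate) * wc

    def tokenize(self, fmap: Tensor) -> Tensor:
        """Split the fused map into column strips, project, add positions."""
        n, c, h, w = fmap.shape
        strips = fmap.transpose(0, 3, 2, 1).reshape(n, w, h * c)
        tokens = self.token_proj(strips)  # (N, T=w, D)
        return tokens + self.pos_embed

    def transformer_encode(self, tokens: Tensor) -> Tensor:
        for blk in self.blocks:
            tokens = blk(tokens)
        return self.final_norm(tokens)

    def classify_logits(self, tokens: Tensor) -> Tensor:
        pooled = tokens.mean(axis=1)  # (N, D)
        return self.head_fc2(self.head_fc1(pooled).relu())

    def classify(self, tokens: Tensor) -> Tensor:
        """Encoded tokens -> class probability rows (softmax of the head)."""
        return self.classify_logits(tokens).softmax(axis=-1)

    # -- full passes -------------------------------------------------------
    def forward_logits(self, images, training: bool = False) -> Tensor:
        cnn = self.backbone_forward(images, training)
        lbp = self.lbp_branch_stem(images, training)
        fused = self.attsf_fuse(cnn, lbp, training)
        tokens = self.transformer_encode(self.tokenize(fused))
        return self.classify_logits(tokens)

    def forward(self, images, training: bool = False) -> np.ndarray:
        """Probability rows for a batch of images (deterministic in eval)."""
        return self.forward_logits(images, training).softmax(axis=-1).data.copy()

    def predict(self, images) -> np.ndarray:
        """Argmax class indices; ties break toward the lowest index."""
        probs = self.forward(images)
        return probs.argmax(axis=1)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        state = {
            "config": asdict(self.cfg),
            "params": [p.data for p in self.parameters()],
            "running": self._running_stats(),
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)
        return path

    def _bn_layers(self) -> list[ConvBNReLU]:
        layers = [l for stage in self.backbone for l in stage]
        layers += list(self.lbp_stem)
        return [l for l in layers if l.bn]

    def _running_stats(self) -> list[np.ndarray]:
        out = []
        for l in self._bn_layers():
            out += [l.running_mean.copy(), l.running_var.copy()]
        return out

    @classmethod
    def load(cls, path: str | Path) -> "CVTNet":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        cfg = ModelConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in state["config"].items()
        })
        net = cls(cfg)
        for p, data in zip(net.parameters(), state["params"]):
            p.data = np.asarray(data, dtype=np.float32)
        stats = state["running"]
        for i, l in enumerate(net._bn_layers()):
            l.running_mean = np.asarray(stats[2 * i], dtype=np.float32)
            l.running_var = np.asarray(stats[2 * i + 1], dtype=np.float32)
        return net

    def summary(self) -> str:
        lines = [f"CVTNet (input {self.cfg.input_size}, {self.cfg.num_classes} classes)"]
        for i, (w, nc) in enumerate(zip(self.cfg.stage_widths, self.cfg.convs_per_stage)):
            pool = " + maxpool" if i < 5 else ""
            lines.append(f"  stage {i + 1}: {nc} x conv3x3({w}) + BN + ReLU{pool}")
        lines.append(f"  LBP stem: 5 x (conv3x3 + pool) -> conv3x3({self.cfg.stage_widths[-1]})")
        lines.append("  ATTSF fusion (1x1 mixes, global bottleneck + local 1x1 gate)")
        lines.append(
            f"  tokenizer: {self.cfg.num_tokens} tokens x {self.cfg.embed_dim} dims"
        )
        lines.append(
            f"  encoder: {self.cfg.encoder_depth} block(s), {self.cfg.heads} heads, "
            f"FFN {self.cfg.ffn_hidden}"
        )
        lines.append(
            f"  head: {self.cfg.embed_dim} -> {self.cfg.head_hidden} -> "
            f"{self.cfg.num_classes} (softmax)"
        )
        lines.append(f"  parameters: {self.parameter_count():,}")
        return "\n".join(lines)


def build_model(cfg: ModelConfig) -> CVTNet:
    """Construct a seeded, deterministic network from a validated config."""
    return CVTNet(cfg)


def interpolate_pos_embed(pos: np.ndarray, new_tokens: int) -> np.ndarray:
    """Linearly resample position embeddings to a new token count (for the
    224 -> 384 fine-tuning stage, 7 -> 12 tokens)."""
    t, d = pos.shape
    if t == new_tokens:
        return pos.copy()
    xs = np.linspace(0.0, t - 1, new_tokens)
    out = np.empty((new_tokens, d), dtype=pos.dtype)
    for j in range(d):
        out[:, j] = np.interp(xs, np.arange(t), pos[:, j])
    return out
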
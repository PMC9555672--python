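"""UNETR: a vision-transformer encoder with a U-shaped convolutional decoder.

A cubic crop of the scan is cut into non-overlapping cubic patches, each
flattened and linearly projected into an embedding space with a learned
position embedding.  A stack of pre-norm transformer blocks encodes the
token sequence; token grids tapped from intermediate layers are upsampled
by transposed convolutions and merged, U-Net style, with the decoder
stream that rises from the final layer back to full crop resolution.
The head is a 1x1x1 convolution to per-voxel class scores.

Every dimension is configuration-driven, so a CPU-sized network (e.g.
32-voxel window, 64-wide embedding, 2 layers) exists for testing next to
the full-scale configuration (128-voxel window, 768-wide embedding,
12 layers, 12 heads).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Parameter, Tensor

__all__ = [
    "UNETRConfig",
    "UNETR",
    "patchify",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UNETRConfig:
    """Architecture hyper-parameters.

    Defaults are the full-scale configuration: 128-voxel windows cut into
    16-voxel patches (8**3 = 512 tokens), hidden width 768, feed-forward
    width 3072, 12 heads, 12 layers with skips tapped at layers 3/6/9/12,
    base decoder width 16, dropout 0.05, two output classes.
    """

    window_edge: int = 128
    patch_edge: int = 16
    hidden_dim: int = 768
    mlp_dim: int = 3072
    num_heads: int = 12
    num_layers: int = 12
    skip_layers: tuple[int, ...] = (3, 6, 9, 12)
    feature_size: int = 16
    dropout_rate: float = 0.05
    out_channels: int = 2

    def __post_init__(self):
        if self.window_edge % self.patch_edge:
            raise ValueError(
                f"window_edge {self.window_edge} not divisible by patch_edge {self.patch_edge}"
            )
        if self.patch_edge < 2 or (self.patch_edge & (self.patch_edge - 1)):
            raise ValueError("patch_edge must be a power of two >= 2")
        if self.hidden_dim % self.num_heads:
            raise ValueError("hidden_dim must be divisible by num_heads")
        skips = tuple(self.skip_layers)
        if any(b <= a for a, b in zip(skips, skips[1:])) or not skips:
            raise ValueError("skip_layers must be non-empty and strictly increasing")
        if skips[-1] > self.num_layers:
            raise ValueError("skip_layers cannot exceed num_layers")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        object.__setattr__(self, "skip_layers", skips)

    @property
    def tokens_per_axis(self) -> int:
        return self.window_edge // self.patch_edge

    @property
    def n_tokens(self) -> int:
        return self.tokens_per_axis**3

    @property
    def n_levels(self) -> int:
        """Number of 2x upsampling stages between token grid and crop grid."""
        return int(round(math.log2(self.patch_edge)))


def patchify(crop: np.ndarray, patch_edge: int) -> np.ndarray:
    """Cut a cubic crop into flattened non-overlapping cubic patches.

    Returns an array of shape ``((edge / patch_edge)**3, patch_edge**3)``
    in lexicographic patch order; the model projects these rows into the
    embedding space.
    """
    crop = np.asarray(crop)
    if crop.ndim != 3 or len(set(crop.shape)) != 1:
        raise ValueError(f"expected a cubic 3-D crop, got shape {crop.shape}")
    e = crop.shape[0]
    if e % patch_edge:
        raise ValueError(f"crop edge {e} not divisible by patch edge {patch_edge}")
    g = e // patch_edge
    p = patch_edge
    tok = crop.reshape(g, p, g, p, g, p).transpose(0, 2, 4, 1, 3, 5)
    return np.ascontiguousarray(tok.reshape(g**3, p**3))


def _tokens_to_grid(tokens: Tensor, g: int) -> Tensor:
    """(B, g**3, C) token sequence -> (B, g, g, g, C) feature grid."""
    B, n, C = tokens.shape
    return tokens.reshape(B, g, g, g, C)


class UNETR:
    """The network, holding named :class:`~cbctseg.nn.Parameter` arrays."""

    def __init__(self, config: UNETRConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(0)
        self.params: dict[str, Parameter] = {}
        c = config

        def par(name, shape, std=None, fill=None):
            if fill is not None:
                data = np.full(shape, fill, dtype=np.float32)
            else:
                data = rng.normal(0.0, std, size=shape).astype(np.float32)
            p = Parameter(data)
            self.params[name] = p
            return p

        pdim = c.patch_edge**3
        par("embed.w", (pdim, c.hidden_dim), std=math.sqrt(1.0 / pdim))
        par("embed.b", (c.hidden_dim,), fill=0.0)
        par("pos_embed", (c.n_tokens, c.hidden_dim), std=0.02)
        for l in range(c.num_layers):
            pre = f"enc{l}."
            par(pre + "ln1.g", (c.hidden_dim,), fill=1.0)
            par(pre + "ln1.b", (c.hidden_dim,), fill=0.0)
            par(pre + "qkv.w", (c.hidden_dim, 3 * c.hidden_dim), std=math.sqrt(1.0 / c.hidden_dim))
            par(pre + "qkv.b", (3 * c.hidden_dim,), fill=0.0)
            par(pre + "proj.w", (c.hidden_dim, c.hidden_dim), std=math.sqrt(1.0 / c.hidden_dim))
            par(pre + "proj.b", (c.hidden_dim,), fill=0.0)
            par(pre + "ln2.g", (c.hidden_dim,), fill=1.0)
            par(pre + "ln2.b", (c.hidden_dim,), fill=0.0)
            par(pre + "mlp1.w", (c.hidden_dim, c.mlp_dim), std=math.sqrt(2.0 / c.hidden_dim))
            par(pre + "mlp1.b", (c.mlp_dim,), fill=0.0)
            par(pre + "mlp2.w", (c.mlp_dim, c.hidden_dim), std=math.sqrt(1.0 / c.mlp_dim))
            par(pre + "mlp2.b", (c.hidden_dim,), fill=0.0)
        par("ln_f.g", (c.hidden_dim,), fill=1.0)
        par("ln_f.b", (c.hidden_dim,), fill=0.0)

        def conv_par(name, cin, cout, k):
            par(name + ".w", (k, k, k, cin, cout), std=math.sqrt(2.0 / (cin * k**3)))
            par(name + ".b", (cout,), fill=0.0)

        def deconv_par(name, cin, cout):
            par(name + ".w", (cin, 2, 2, 2, cout), std=math.sqrt(2.0 / (cin * 8)))
            par(name + ".b", (cout,), fill=0.0)

        def norm_par(name, ch):
            par(name + ".g", (ch,), fill=1.0)
            par(name + ".b", (ch,), fill=0.0)

        fs = c.feature_size
        ch = [fs * 2**l for l in range(c.n_levels)]  # channels at levels 0..n_levels-1

        # full-resolution encoder on the raw crop
        conv_par("enc_in.c1", 1, ch[0], 3)
        norm_par("enc_in.n1", ch[0])
        conv_par("enc_in.c2", ch[0], ch[0], 3)
        norm_par("enc_in.n2", ch[0])

        # lateral branches from tapped transformer layers, deepest level first
        self._lateral_levels: dict[int, int] = {}
        laterals = list(c.skip_layers[:-1])
        for i, layer in enumerate(reversed(laterals)):
            level = c.n_levels - 1 - i  # target level of this lateral
            if level < 1:
                break
            self._lateral_levels[level] = layer
            cin = c.hidden_dim
            for s in range(c.n_levels - level):
                name = f"lat{level}.s{s}"
                deconv_par(name + ".up", cin, ch[level])
                conv_par(name + ".conv", ch[level], ch[level], 3)
                norm_par(name + ".norm", ch[level])
                cin = ch[level]

        # rising decoder stream
        cin = c.hidden_dim
        for level in range(c.n_levels, 0, -1):
            tgt = ch[level - 1]
            deconv_par(f"dec{level}.up", cin, tgt)
            has_skip = (level - 1) in self._lateral_levels or level - 1 == 0
            conv_par(f"dec{level}.conv", 2 * tgt if has_skip else tgt, tgt, 3)
            norm_par(f"dec{level}.norm", tgt)
            cin = tgt
        conv_par("head", ch[0], c.out_channels, 1)
        # start from the anatomical prior instead of a 50/50 guess: bone
        # occupies ~10% of a head volume, so bias the softmax toward
        # background at init (log-odds of 0.1 split across the two logits)
        if c.out_channels == 2:
            prior = np.log(0.1 / 0.9) / 2.0
            self.params["head.b"].data[:] = (-prior, prior)

    # -- building blocks ------------------------------------------------
    def _p(self, name: str) -> Parameter:
        return self.params[name]

    def _attention(self, x: Tensor, pre: str, train: bool, rng) -> Tensor:
        c = self.config
        B, n, _ = x.shape
        hd = c.hidden_dim // c.num_heads
        qkv = x @ self._p(pre + "qkv.w") + self._p(pre + "qkv.b")
        qkv = qkv.reshape(B, n, 3, c.num_heads, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, heads, n, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, n, c.hidden_dim)
        out = out @ self._p(pre + "proj.w") + self._p(pre + "proj.b")
        return out.dropout(c.dropout_rate, rng, train)

    def _mlp(self, x: Tensor, pre: str, train: bool, rng) -> Tensor:
        c = self.config
        h = (x @ self._p(pre + "mlp1.w") + self._p(pre + "mlp1.b")).gelu()
        h = h.dropout(c.dropout_rate, rng, train)
        h = h @ self._p(pre + "mlp2.w") + self._p(pre + "mlp2.b")
        return h.dropout(c.dropout_rate, rng, train)

    def encode(self, x: Tensor, train: bool, rng) -> list[Tensor]:
        """Run the transformer; return hidden states after each layer."""
        c = self.config
        B = x.shape[0]
        crops = x.data.reshape(B, c.window_edge, c.window_edge, c.window_edge)
        toks = np.stack([patchify(v, c.patch_edge) for v in crops])
        t = Tensor(toks) @ self._p("embed.w") + self._p("embed.b")
        t = t + self._p("pos_embed")
        t = t.dropout(c.dropout_rate, rng, train)
        states = []
        for l in range(c.num_layers):
            pre = f"enc{l}."
            h = nn.layer_norm(t, self._p(pre + "ln1.g"), self._p(pre + "ln1.b"))
            t = t + self._attention(h, pre, train, rng)
            h = nn.layer_norm(t, self._p(pre + "ln2.g"), self._p(pre + "ln2.b"))
            t = t + self._mlp(h, pre, train, rng)
            states.append(t)
        return states

    def forward_logits(
        self,
        x: np.ndarray | Tensor,
        train: bool = False,
        rng: np.random.Generator | None = None,
        channels_last: bool = False,
    ) -> Tensor:
        """Raw per-voxel class scores for a batch of crops.

        ``x``: (B, E, E, E) or (B, 1, E, E, E) with E = window_edge.
        Returns a Tensor of shape (B, out_channels, E, E, E), or
        (B, E, E, E, out_channels) with ``channels_last=True`` (cheaper;
        used by the training loop).
        """
        c = self.config
        if rng is None:
            rng = np.random.default_rng(0)
        xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if xt.data.ndim == 5 and xt.data.shape[1] == 1:
            xt = xt.reshape(xt.shape[0], *xt.shape[2:])
        if xt.data.shape[1:] != (c.window_edge,) * 3:
            raise ValueError(
                f"crop shape {xt.data.shape[1:]} does not match window edge {c.window_edge}"
            )
        xt = xt.reshape(*xt.shape, 1)  # channels-last
        g = c.tokens_per_axis
        states = self.encode(xt, train, rng)

        # full-resolution skip from the raw crop
        h = nn.conv3d(xt, self._p("enc_in.c1.w"), self._p("enc_in.c1.b"), padding=1)
        h = nn.instance_norm(h, self._p("enc_in.n1.g"), self._p("enc_in.n1.b")).relu()
        h = nn.conv3d(h, self._p("enc_in.c2.w"), self._p("enc_in.c2.b"), padding=1)
        enc0 = nn.instance_norm(h, self._p("enc_in.n2.g"), self._p("enc_in.n2.b")).relu()

        # lateral branches
        laterals: dict[int, Tensor] = {}
        for level, layer in self._lateral_levels.items():
            f = _tokens_to_grid(states[layer - 1], g)
            for s in range(c.n_levels - level):
                name = f"lat{level}.s{s}"
                f = nn.conv_transpose3d_2x(f, self._p(name + ".up.w"), self._p(name + ".up.b"))
                f = nn.conv3d(f, self._p(name + ".conv.w"), self._p(name + ".conv.b"), padding=1)
                f = nn.instance_norm(f, self._p(name + ".norm.g"), self._p(name + ".norm.b"))
                f = f.relu()
            laterals[level] = f

        # rising stream from the final transformer layer
        zf = nn.layer_norm(states[-1], self._p("ln_f.g"), self._p("ln_f.b"))
        d = _tokens_to_grid(zf, g)
        for level in range(c.n_levels, 0, -1):
            name = f"dec{level}"
            d = nn.conv_transpose3d_2x(d, self._p(name + ".up.w"), self._p(name + ".up.b"))
            skip = laterals.get(level - 1) if level - 1 >= 1 else enc0
            if skip is not None:
                d = nn.concat([d, skip], axis=4)
            d = nn.conv3d(d, self._p(name + ".conv.w"), self._p(name + ".conv.b"), padding=1)
            d = nn.instance_norm(d, self._p(name + ".norm.g"), self._p(name + ".norm.b"))
            d = d.relu()
        out = nn.conv3d(d, self._p("head.w"), self._p("head.b"), padding=0)
        if channels_last:
            return out  # (B, D, H, W, C)
        return out.transpose(0, 4, 1, 2, 3)  # (B, C, D, H, W)

    def forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        """Per-voxel class probabilities (channels sum to 1) as an ndarray."""
        with nn.no_grad():
            logits = self.forward_logits(x, train=train, rng=rng)
            return logits.softmax(axis=1).data

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise KeyError(f"checkpoint/model parameter mismatch: {sorted(missing)[:5]}")
        for k, p in self.params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32)


def count_parameters(config: UNETRConfig) -> int:
    """Total number of learnable scalars for a configuration."""
    model = UNETR(config, rng=np.random.default_rng(0))
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: UNETR, path: str | os.PathLike, extra: dict | None = None) -> None:
    """Serialize weights with the configuration embedded."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | os.PathLike) -> tuple[UNETR, dict]:
    """Rebuild a model (config + weights) from :func:`save_checkpoint` output."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k.replace("__", "."): data[k] for k in data.files if k != "__meta__"
        }
    cfg = meta["config"]
    cfg["skip_layers"] = tuple(cfg["skip_layers"])
    model = UNETR(UNETRConfig(**cfg))
    model.load_state_dict(state)
    return model, meta.get("extra", {})
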
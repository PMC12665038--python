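"""The two-branch CNN -> MLP -> Transformer-encoder pair classifier.

Each 2000 bp one-hot sequence passes through a single convolutional layer
(128 kernels of length 9 over the 4 base channels), ReLU, and max pooling
that reduces 2000 positions to 500 tokens. A single-layer MLP projects the
pooled features into the token space, tokens from both branches are
concatenated along the position axis, and a Transformer encoder (multi-head
self-attention with a learned relative-position bias, feed-forward network,
layer normalization) integrates them. Two prediction heads pool the left-
and right-branch tokens respectively; their averaged output passes through
a sigmoid to give the interaction probability.

The convolutional branch is shared between the two sequences (siamese) by
default; set ``tied_conv=False`` for independent branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._autodiff import Tensor, concat, layer_norm, maxpool1d, take, unfold

TRANSFORMER_PREFIX = "encoder."


@dataclass
class ModelConfig:
    seq_len: int = 2000
    conv_channels: int = 128
    conv_kernel: int = 9
    pool_factor: int = 4
    mlp_hidden: int = 512          # token dimension fed to the encoder
    n_heads: int = 8
    d_value_total: int = 1024
    d_qk_total: int = 1000
    n_encoder_layers: int = 1
    ffn_dim: int | None = None     # default 4 * d_value_total
    dropout: float = 0.1
    head_hidden: int = 256
    tied_conv: bool = True

    def __post_init__(self) -> None:
        if self.ffn_dim is None:
            self.ffn_dim = 4 * self.d_value_total
        if self.d_value_total % self.n_heads:
            raise ValueError(f"d_value_total={self.d_value_total} not divisible "
                             f"by n_heads={self.n_heads}")
        if self.d_qk_total % self.n_heads:
            raise ValueError(f"d_qk_total={self.d_qk_total} not divisible "
                             f"by n_heads={self.n_heads}")
        if self.seq_len % self.pool_factor:
            raise ValueError(f"seq_len={self.seq_len} not divisible by "
                             f"pool_factor={self.pool_factor}")
        if self.conv_kernel % 2 == 0:
            raise ValueError("conv_kernel must be odd (same-padding convolution)")

    @property
    def tokens_per_side(self) -> int:
        return self.seq_len // self.pool_factor

    def to_yaml_dict(self) -> dict:
        return asdict(self)


def reduced_config(**overrides) -> ModelConfig:
    """A small configuration for desk-scale experiments and tests."""
    base = dict(seq_len=200, conv_channels=16, conv_kernel=9, pool_factor=4,
                mlp_hidden=32, n_heads=2, d_value_total=32, d_qk_total=32,
                n_encoder_layers=1, ffn_dim=64, dropout=0.1, head_hidden=16)
    base.update(overrides)
    return ModelConfig(**base)


class EtnetModel:
    """Trained (or freshly initialized) enhancer-pair classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.params: dict[str, Tensor] = {}

        def par(name: str, shape: tuple[int, ...], fan_in: int) -> Tensor:
            t = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                       requires_grad=True)
            self.params[name] = t
            return t

        def zeros(name: str, shape) -> Tensor:
            t = Tensor(np.zeros(shape), requires_grad=True)
            self.params[name] = t
            return t

        def ones(name: str, shape) -> Tensor:
            t = Tensor(np.ones(shape), requires_grad=True)
            self.params[name] = t
            return t

        kin = c.conv_kernel * 4
        branches = ("conv",) if c.tied_conv else ("conv_left", "conv_right")
        for b in branches:
            par(f"{b}.weight", (kin, c.conv_channels), kin)
            zeros(f"{b}.bias", (c.conv_channels,))
        par("mlp.weight", (c.conv_channels, c.mlp_hidden), c.conv_channels)
        zeros("mlp.bias", (c.mlp_hidden,))

        T = 2 * c.tokens_per_side
        for layer in range(c.n_encoder_layers):
            p = f"{TRANSFORMER_PREFIX}{layer}."
            par(p + "wq", (c.mlp_hidden, c.d_qk_total), c.mlp_hidden)
            zeros(p + "bq", (c.d_qk_total,))
            par(p + "wk", (c.mlp_hidden, c.d_qk_total), c.mlp_hidden)
            zeros(p + "bk", (c.d_qk_total,))
            par(p + "wv", (c.mlp_hidden, c.d_value_total), c.mlp_hidden)
            zeros(p + "bv", (c.d_value_total,))
            par(p + "wo", (c.d_value_total, c.mlp_hidden), c.d_value_total)
            zeros(p + "bo", (c.mlp_hidden,))
            zeros(p + "rel_bias", (c.n_heads, 2 * T - 1))
            ones(p + "ln1.gain", (c.mlp_hidden,))
            zeros(p + "ln1.bias", (c.mlp_hidden,))
            par(p + "ffn.w1", (c.mlp_hidden, c.ffn_dim), c.mlp_hidden)
            zeros(p + "ffn.b1", (c.ffn_dim,))
            par(p + "ffn.w2", (c.ffn_dim, c.mlp_hidden), c.ffn_dim)
            zeros(p + "ffn.b2", (c.mlp_hidden,))
            ones(p + "ln2.gain", (c.mlp_hidden,))
            zeros(p + "ln2.bias", (c.mlp_hidden,))

        for h in ("head_left", "head_right"):
            par(f"{h}.w1", (c.mlp_hidden, c.head_hidden), c.mlp_hidden)
            zeros(f"{h}.b1", (c.head_hidden,))
            par(f"{h}.w2", (c.head_hidden, 1), c.head_hidden)
            zeros(f"{h}.b2", (1,))

        # relative-position index table i - j -> bias column, built once
        pos = np.arange(T)
        self._rel_idx = pos[:, None] - pos[None, :] + T - 1

    # ------------------------------------------------------------------
    def parameter_names(self) -> list[str]:
        return list(self.params)

    def transformer_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k.startswith(TRANSFORMER_PREFIX)}

    def adaptable_parameters(self) -> dict[str, Tensor]:
        """Input, convolutional, and output-head parameters (fine-tuned group)."""
        return {k: v for k, v in self.params.items() if not k.startswith(TRANSFORMER_PREFIX)}

    # ------------------------------------------------------------------
    def _branch(self, x: Tensor, side: str) -> Tensor:
        c = self.config
        b = "conv" if c.tied_conv else f"conv_{side}"
        patches = unfold(x, c.conv_kernel, pad=c.conv_kernel // 2)
        feat = (patches @ self.params[f"{b}.weight"] + self.params[f"{b}.bias"]).relu()
        pooled = maxpool1d(feat, c.pool_factor)
        tokens = (pooled @ self.params["mlp.weight"] + self.params["mlp.bias"]).relu()
        return tokens

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        if rng is None or self.config.dropout <= 0:
            return x
        keep = 1.0 - self.config.dropout
        mask = (rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)

    def _encode(self, tokens: Tensor, rng: np.random.Generator | None,
                collect_attention: bool = False):
        c = self.config
        B, T, D = tokens.shape
        dk = c.d_qk_total // c.n_heads
        dv = c.d_value_total // c.n_heads
        attn_maps = []
        x = tokens
        for layer in range(c.n_encoder_layers):
            p = f"{TRANSFORMER_PREFIX}{layer}."

            def split_heads(t: Tensor, d_head: int) -> Tensor:
                return t.reshape(B, T, c.n_heads, d_head).swapaxes(1, 2)

            q = split_heads(x @ self.params[p + "wq"] + self.params[p + "bq"], dk)
            k = split_heads(x @ self.params[p + "wk"] + self.params[p + "bk"], dk)
            v = split_heads(x @ self.params[p + "wv"] + self.params[p + "bv"], dv)
            logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
            logits = logits + take(self.params[p + "rel_bias"], self._rel_idx)
            attn = logits.softmax(axis=-1)
            if collect_attention:
                attn_maps.append(attn.data.copy())
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, T, c.d_value_total)
            mha = ctx @ self.params[p + "wo"] + self.params[p + "bo"]
            x = layer_norm(x + self._dropout(mha, rng),
                           self.params[p + "ln1.gain"], self.params[p + "ln1.bias"])
            hidden = (x @ self.params[p + "ffn.w1"] + self.params[p + "ffn.b1"]).relu()
            ffn = self._dropout(hidden, rng) @ self.params[p + "ffn.w2"] + self.params[p + "ffn.b2"]
            x = layer_norm(x + ffn,
                           self.params[p + "ln2.gain"], self.params[p + "ln2.bias"])
        return (x, attn_maps) if collect_attention else x

    def forward_logits(self, left, right,
                       rng: np.random.Generator | None = None) -> Tensor:
        """Pre-sigmoid interaction score for a batch of one-hot pairs.

        ``left``/``right`` are (B, seq_len, 4) arrays or Tensors (single
        pairs of shape (seq_len, 4) are promoted). ``rng`` enables dropout
        (training mode); evaluation mode is fully deterministic.
        """
        c = self.config
        left = left if isinstance(left, Tensor) else Tensor(np.asarray(left))
        right = right if isinstance(right, Tensor) else Tensor(np.asarray(right))
        if left.ndim == 2:
            left = left.reshape(1, *left.shape)
        if right.ndim == 2:
            right = right.reshape(1, *right.shape)
        for name, t in (("left", left), ("right", right)):
            if t.shape[1:] != (c.seq_len, 4):
                raise ValueError(f"{name} input has shape {t.shape[1:]}, "
                                 f"expected ({c.seq_len}, 4)")
        tokens = concat([self._branch(left, "left"), self._branch(right, "right")], axis=1)
        x = self._encode(tokens, rng)
        Tside = c.tokens_per_side
        halves = []
        for head, sl in (("head_left", slice(0, Tside)), ("head_right", slice(Tside, None))):
            pooled = x[:, sl, :].mean(axis=1)
            h = (pooled @ self.params[f"{head}.w1"] + self.params[f"{head}.b1"]).relu()
            halves.append(h @ self.params[f"{head}.w2"] + self.params[f"{head}.b2"])
        return (halves[0] + halves[1]) * 0.5  # (B, 1)

    def forward(self, left, right) -> np.ndarray:
        """Interaction probabilities in (0,1) for a batch of one-hot pairs."""
        return self.forward_logits(left, right).sigmoid().data[:, 0]

    def predict(self, left: np.ndarray, right: np.ndarray,
                batch_size: int = 100) -> np.ndarray:
        """Evaluation-mode probabilities, computed in mini-batches."""
        left, right = np.asarray(left), np.asarray(right)
        if left.ndim == 2:
            return self.forward(left, right)
        out = [self.forward(left[i:i + batch_size], right[i:i + batch_size])
               for i in range(0, len(left), batch_size)]
        return np.concatenate(out)

    def attention_maps(self, left, right) -> list[np.ndarray]:
        """Per-layer attention tensors, each (B, n_heads, tokens, tokens)."""
        c = self.config
        left = Tensor(np.asarray(left, dtype=float))
        right = Tensor(np.asarray(right, dtype=float))
        single = left.ndim == 2
        if single:
            left = left.reshape(1, *left.shape)
            right = right.reshape(1, *right.shape)
        tokens = concat([self._branch(left, "left"), self._branch(right, "right")], axis=1)
        _, maps = self._encode(tokens, None, collect_attention=True)
        return [m[0] if single else m for m in maps]

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        missing = set(self.params) ^ set(state)
        if missing:
            raise ValueError(f"checkpoint/model parameter mismatch: {sorted(missing)}")
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def save(self, path) -> None:
        state = {f"param/{k}": v for k, v in self.state_dict().items()}
        np.savez(path, __config__=json.dumps(self.config.to_yaml_dict()), **state)

    @classmethod
    def load(cls, path) -> "EtnetModel":
        with np.load(path, allow_pickle=False) as npz:
            cfg = ModelConfig(**json.loads(str(npz["__config__"])))
            model = cls(cfg, seed=0)
            model.load_state_dict({k[len("param/"):]: npz[k]
                                   for k in npz.files if k.startswith("param/")})
        return model


def build_model(config: ModelConfig, seed: int = 0) -> EtnetModel:
    """Construct a model with seed-reproducible parameter initialization."""
    return EtnetModel(config, seed=seed)
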
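"""Coarse-level sequence models: many-to-many LSTM and seq2seq encoder-decoders.

Three architectures operate on windows of clip features (one fc8-like vector
per clip):

* ``lstm_m2m`` — a stacked LSTM emitting one phase logit row per input clip
  (the conventional recurrent baseline);
* ``lstm_seq2seq`` — an LSTM encoder over the features whose final hidden and
  cell states initialise an LSTM decoder that consumes the embedded target
  label sequence;
* ``transformer_seq2seq`` — a standard encoder-decoder transformer with
  sinusoidal positional encoding, multi-head attention, and (by default)
  causal masking in the decoder self-attention.

Two window geometries are supported.  In the *time-synchronous* configuration
the target, input and output sequences all cover the same ``window_len``
clips.  In the *time-shifted* configuration the target covers the first
``out_len`` clips of the window while the output is supervised against the
last ``out_len`` (a shift of ``window_len - out_len``), which lets whole-video
inference run recursively from only an initial fine-level segment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import ClipLabelSequence, PhaseLabel, ValidationError
from .synthetic import FeatureSequence

__all__ = [
    "SeqModelConfig",
    "LogitSequence",
    "positional_encoding",
    "build_model",
    "m2m_forward",
    "seq2seq_forward",
    "save_checkpoint",
    "load_checkpoint",
    "code_to_class",
    "class_to_code",
    "LABEL_VOCAB_SIZE",
]

ARCHS = ("lstm_m2m", "lstm_seq2seq", "transformer_seq2seq")

#: Embedding vocabulary: label codes 0..6 (non-phase, phases 1-5, transition).
LABEL_VOCAB_SIZE = 7


@dataclass
class SeqModelConfig:
    arch: str = "lstm_seq2seq"
    window_len: int = 100
    out_len: int = 100
    shift: int = 0
    n_classes: int = 6
    feature_dim: int = 1200
    d_model: int = 1200
    lstm_layers: int = 3
    tf_layers: int = 6
    tf_heads: int = 8
    ffn_dim: int = 1000
    label_embed_dim: Optional[int] = None
    causal_decoder: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.arch not in ARCHS:
            raise ValidationError(f"unknown arch {self.arch!r}; one of {ARCHS}")
        if self.out_len + self.shift != self.window_len:
            raise ValidationError(
                f"geometry violated: out_len ({self.out_len}) + shift ({self.shift}) "
                f"!= window_len ({self.window_len})"
            )
        if self.arch == "transformer_seq2seq" and self.d_model % self.tf_heads:
            raise ValidationError("d_model must be divisible by tf_heads")
        if self.n_classes not in (5, 6):
            raise ValidationError("n_classes must be 5 (phases) or 6 (phases+transition)")
        if self.arch == "lstm_m2m" and self.shift:
            raise ValidationError("many-to-many models are time-synchronous only")

    @property
    def embed_dim(self) -> int:
        return self.label_embed_dim or self.d_model

    @property
    def overlap(self) -> int:
        """Clips shared between the target span and the output span."""
        return self.out_len - self.shift

    @classmethod
    def time_synchronous(cls, arch: str = "lstm_seq2seq", window_len: int = 100,
                         **kw) -> "SeqModelConfig":
        return cls(arch=arch, window_len=window_len, out_len=window_len, shift=0, **kw)

    @classmethod
    def time_shifted(cls, arch: str = "transformer_seq2seq", window_len: int = 100,
                     shift: int = 10, **kw) -> "SeqModelConfig":
        return cls(arch=arch, window_len=window_len, out_len=window_len - shift,
                   shift=shift, **kw)


@dataclass
class LogitSequence:
    """Pre-softmax scores, one row per output clip."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("logits contain non-finite values")

    def probabilities(self) -> np.ndarray:
        z = self.matrix - self.matrix.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def labels(self) -> np.ndarray:
        """Argmax class indices mapped back to label codes."""
        return class_to_code(self.matrix.argmax(axis=-1))


def code_to_class(codes: np.ndarray) -> np.ndarray:
    """Label codes (1-5 phases, 6 transition) -> class indices (0-4, 5).

    Non-phase (code 0) maps to -1; it is never a network output class.
    """
    codes = np.asarray(codes)
    out = codes - 1
    out[codes == int(PhaseLabel.NONPHASE)] = -1
    return out


def class_to_code(classes: np.ndarray) -> np.ndarray:
    return np.asarray(classes) + 1


def positional_encoding(length: int, d: int) -> np.ndarray:
    """Sinusoidal positional encoding: PE(t, 2i)=sin(t/10000^(2i/d)), odd=cos."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if d < 2 or d % 2:
        raise ValidationError("encoding dimension must be even and >= 2")
    t = np.arange(length)[:, None]
    freq = np.power(10000.0, -np.arange(0, d, 2) / d)[None, :]
    pe = np.empty((length, d))
    pe[:, 0::2] = np.sin(t * freq)
    pe[:, 1::2] = np.cos(t * freq)
    return pe


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


class _Module:
    """Minimal parameter registry; submodules discovered via attributes."""

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, _Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, _Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> Dict[str, Tensor]:
        named: Dict[str, Tensor] = {}
        for attr, value in vars(self).items():
            key = f"{prefix}{attr}"
            if isinstance(value, Tensor) and value.requires_grad:
                named[key] = value
            elif isinstance(value, _Module):
                named.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, _Module):
                        named.update(item.named_parameters(f"{key}.{i}."))
        return named


class _Linear(_Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.w = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b


class _Embedding(_Module):
    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        self.w = Tensor(rng.normal(0.0, 0.1, size=(vocab, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return ad.embedding(self.w, idx)


class _LayerNorm(_Module):
    def __init__(self, dim: int):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.b = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.g, self.b)


class _LSTMStack(_Module):
    def __init__(self, d_in: int, d_hidden: int, n_layers: int,
                 rng: np.random.Generator):
        self.layers = []
        for layer in range(n_layers):
            din = d_in if layer == 0 else d_hidden
            scale = 1.0 / np.sqrt(d_hidden)
            self.layers.append(_LSTMWeights(
                wx=Tensor(rng.uniform(-scale, scale, size=(din, 4 * d_hidden)),
                          requires_grad=True),
                wh=Tensor(rng.uniform(-scale, scale, size=(d_hidden, 4 * d_hidden)),
                          requires_grad=True),
                b=Tensor(np.zeros(4 * d_hidden), requires_grad=True),
            ))

    def __call__(self, x: Tensor, init_states=None):
        """x: (T, B, D).  Returns (H_top, [(h_T, c_T)] per layer)."""
        states = []
        h = x
        for i, lw in enumerate(self.layers):
            h0 = c0 = None
            if init_states is not None:
                h0, c0 = init_states[i]
            h, hT, cT = ad.lstm_layer(h, lw.wx, lw.wh, lw.b, h0, c0)
            states.append((hT, cT))
        return h, states


class _LSTMWeights(_Module):
    def __init__(self, wx: Tensor, wh: Tensor, b: Tensor):
        self.wx, self.wh, self.b = wx, wh, b


class _MultiHeadAttention(_Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = _Linear(d_model, d_model, rng)
        self.wk = _Linear(d_model, d_model, rng)
        self.wv = _Linear(d_model, d_model, rng)
        self.wo = _Linear(d_model, d_model, rng)

    def __call__(self, q_in: Tensor, kv_in: Tensor,
                 mask: Optional[np.ndarray] = None) -> Tensor:
        B, Tq, D = q_in.shape
        Tk = kv_in.shape[1]
        q = self._split(self.wq(q_in), B, Tq)
        k = self._split(self.wk(kv_in), B, Tk)
        v = self._split(self.wv(kv_in), B, Tk)
        scores = ad.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = ad.softmax(scores, mask=mask)
        ctx = ad.matmul(attn, v)  # (B, h, Tq, d_head)
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(merged)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)


class _FeedForward(_Module):
    def __init__(self, d_model: int, ffn_dim: int, rng: np.random.Generator):
        self.l1 = _Linear(d_model, ffn_dim, rng)
        self.l2 = _Linear(ffn_dim, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())


class _EncoderLayer(_Module):
    def __init__(self, cfg: SeqModelConfig, rng):
        self.attn = _MultiHeadAttention(cfg.d_model, cfg.tf_heads, rng)
        self.ffn = _FeedForward(cfg.d_model, cfg.ffn_dim, rng)
        self.ln1 = _LayerNorm(cfg.d_model)
        self.ln2 = _LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.attn(x, x))
        return self.ln2(x + self.ffn(x))


class _DecoderLayer(_Module):
    def __init__(self, cfg: SeqModelConfig, rng):
        self.self_attn = _MultiHeadAttention(cfg.d_model, cfg.tf_heads, rng)
        self.cross_attn = _MultiHeadAttention(cfg.d_model, cfg.tf_heads, rng)
        self.ffn = _FeedForward(cfg.d_model, cfg.ffn_dim, rng)
        self.ln1 = _LayerNorm(cfg.d_model)
        self.ln2 = _LayerNorm(cfg.d_model)
        self.ln3 = _LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor, memory: Tensor,
                 self_mask: Optional[np.ndarray]) -> Tensor:
        x = self.ln1(x + self.self_attn(x, x, mask=self_mask))
        x = self.ln2(x + self.cross_attn(x, memory))
        return self.ln3(x + self.ffn(x))


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


class ManyToManyLSTM(_Module):
    def __init__(self, cfg: SeqModelConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.lstm = _LSTMStack(cfg.feature_dim, cfg.d_model, cfg.lstm_layers, rng)
        self.head = _Linear(cfg.d_model, cfg.n_classes, rng)

    def forward(self, features: np.ndarray,
                target_codes: Optional[np.ndarray] = None) -> Tensor:
        """features: (B, T, F) -> logits (B, T, n_classes).  Target unused."""
        x = Tensor(np.asarray(features).transpose(1, 0, 2))  # (T, B, F)
        h, _ = self.lstm(x)
        return self.head(h).transpose(1, 0, 2)


class LSTMSeq2Seq(_Module):
    """LSTM encoder-decoder.

    The encoder consumes the feature sequence and its final hidden/cell
    states initialise the decoder.  Decoder step ``k`` consumes the embedded
    target label at position ``k`` concatenated with the feature vector of
    the clip it predicts (position ``k + shift``): the summary state alone is
    too narrow a bottleneck to carry per-clip evidence across a 100-clip
    window, and anchoring each step on its own clip's features keeps the
    recursive time-shifted rollout from drifting.
    """

    def __init__(self, cfg: SeqModelConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = _LSTMStack(cfg.feature_dim, cfg.d_model, cfg.lstm_layers, rng)
        self.embed = _Embedding(LABEL_VOCAB_SIZE, cfg.embed_dim, rng)
        self.decoder = _LSTMStack(cfg.embed_dim + cfg.feature_dim, cfg.d_model,
                                  cfg.lstm_layers, rng)
        self.head = _Linear(cfg.d_model, cfg.n_classes, rng)

    def forward(self, features: np.ndarray, target_codes: np.ndarray) -> Tensor:
        """features: (B, W, F); target_codes: (B, out_len) label codes."""
        feats = np.asarray(features)
        x = Tensor(feats.transpose(1, 0, 2))
        _, enc_states = self.encoder(x)
        emb = self.embed(np.asarray(target_codes).T)  # (out_len, B, E)
        out_feats = feats[:, self.config.shift:, :].transpose(1, 0, 2)
        dec_in = ad.concat([emb, Tensor(out_feats)], axis=-1)
        h, _ = self.decoder(dec_in, init_states=enc_states)
        return self.head(h).transpose(1, 0, 2)


class TransformerSeq2Seq(_Module):
    def __init__(self, cfg: SeqModelConfig):
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.in_proj = _Linear(cfg.feature_dim, cfg.d_model, rng)
        self.embed = _Embedding(LABEL_VOCAB_SIZE, cfg.d_model, rng)
        self.enc_layers = [_EncoderLayer(cfg, rng) for _ in range(cfg.tf_layers)]
        self.dec_layers = [_DecoderLayer(cfg, rng) for _ in range(cfg.tf_layers)]
        self.head = _Linear(cfg.d_model, cfg.n_classes, rng)

    def forward(self, features: np.ndarray, target_codes: np.ndarray) -> Tensor:
        cfg = self.config
        feats = np.asarray(features)
        codes = np.asarray(target_codes)
        x = self.in_proj(Tensor(feats)) + Tensor(positional_encoding(feats.shape[1],
                                                                     cfg.d_model))
        for layer in self.enc_layers:
            x = layer(x)
        y = self.embed(codes) + Tensor(positional_encoding(codes.shape[1], cfg.d_model))
        mask = None
        if cfg.causal_decoder:
            T = codes.shape[1]
            mask = np.triu(np.ones((T, T), dtype=bool), k=1)
        for layer in self.dec_layers:
            y = layer(y, x, self_mask=mask)
        return self.head(y)


_MODEL_CLASSES = {
    "lstm_m2m": ManyToManyLSTM,
    "lstm_seq2seq": LSTMSeq2Seq,
    "transformer_seq2seq": TransformerSeq2Seq,
}


def build_model(cfg: SeqModelConfig):
    cfg.validate()
    return _MODEL_CLASSES[cfg.arch](cfg)


# ---------------------------------------------------------------------------
# single-sequence public forward API
# ---------------------------------------------------------------------------


def m2m_forward(model: ManyToManyLSTM, features: FeatureSequence) -> LogitSequence:
    """One logit row per input clip for the many-to-many baseline."""
    _check_features(model.config, features, model.config.window_len)
    out = model.forward(features.matrix[None, :, :])
    return LogitSequence(matrix=out.data[0])


def seq2seq_forward(model, features: FeatureSequence,
                    target: ClipLabelSequence) -> LogitSequence:
    """Single forward pass: the full target is known, no generation loop."""
    cfg = model.config
    _check_features(cfg, features, cfg.window_len)
    codes = np.asarray(target.labels)
    if codes.size != cfg.out_len:
        raise ValidationError(
            f"target length {codes.size} != expected {cfg.out_len} "
            f"({'time-shifted' if cfg.shift else 'time-synchronous'})"
        )
    out = model.forward(features.matrix[None, :, :], codes[None, :])
    return LogitSequence(matrix=out.data[0])


def _check_features(cfg: SeqModelConfig, features: FeatureSequence, expect: int) -> None:
    if len(features) != expect:
        raise ValidationError(f"expected {expect} feature rows, got {len(features)}")
    if features.feature_dim != cfg.feature_dim:
        raise ValidationError(
            f"feature dim {features.feature_dim} != configured {cfg.feature_dim}"
        )


# ---------------------------------------------------------------------------
# checkpoints: single-file archive with the embedded config
# ---------------------------------------------------------------------------


def save_checkpoint(path, model) -> None:
    named = {k: v.data for k, v in model.named_parameters().items()}
    cfg_json = json.dumps(asdict(model.config))
    with open(path, "wb") as fh:  # file handle: no implicit .npz suffix games
        np.savez(fh, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **named)


def load_checkpoint(path):
    with np.load(path) as archive:
        cfg_json = bytes(archive["__config__"]).decode()
        cfg = SeqModelConfig(**json.loads(cfg_json))
        model = build_model(cfg)
        named = model.named_parameters()
        for key, tensor in named.items():
            tensor.data = archive[key].astype(np.float64)
    return model
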
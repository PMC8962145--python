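"""Encoder-decoder transformer over SMILES + property-change tokens.

The model learns the mapping (source molecule, requested property change)
-> target molecule on mined molecular pairs.  Architecture follows the
standard attention encoder-decoder: token embeddings scaled by sqrt(width)
plus sinusoidal positional encodings, stacks of identical post-norm
encoder/decoder layers with multi-head attention and position-wise
feed-forward sublayers, trained with teacher forcing, Adam and the
inverse-square-root warmup learning-rate schedule.  Generation is
autoregressive multinomial sampling from the full next-token distribution.

The unconditional variant ("Transformer-U") is the identical network trained
on the same pairs with the three property tokens dropped from the source
sequence; its vocabulary therefore contains no property-change tokens.

Defaults are desk-scale (small widths, CPU); every architecture number is a
:class:`ModelConfig` field, so a larger profile is a config away.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from hashlib import sha256
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import (
    Adam,
    Tensor,
    cross_entropy_logits,
    dropout,
    embedding,
    layer_norm,
    linear,
    softmax_last,
)
from .chem_ops import MoleculeError, standardize
from .dataset_builder import MoleculeRecord, MolecularPair, PairDataset
from .property_encoding import PropertyChange
from .tokenizer import END, PAD, START, Vocabulary, assemble_source, assemble_target

NEG_INF = np.float32(-1e9)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters."""

    num_layers: int = 3
    model_width: int = 128
    feedforward_width: int = 256
    num_attention_heads: int = 8
    dropout: float = 0.1
    max_sequence_length: int = 96
    batch_size: int = 128
    warmup_steps: int = 4000
    lr_factor: float = 1.0
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.model_width % self.num_attention_heads:
            raise ValueError("model_width must be divisible by num_attention_heads")
        for name in (
            "num_layers",
            "model_width",
            "feedforward_width",
            "num_attention_heads",
            "max_sequence_length",
            "batch_size",
            "warmup_steps",
            "epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: A smaller profile for fast desk-scale benchmarks and tests.
DESK_CONFIG = ModelConfig(
    num_layers=2,
    model_width=64,
    feedforward_width=128,
    num_attention_heads=4,
    max_sequence_length=64,
    batch_size=64,
    warmup_steps=300,
    lr_factor=2.0,
    epochs=12,
)


@dataclass
class GenerationResult:
    """Unique valid molecules sampled for one (start, constraint) input."""

    start: MoleculeRecord
    constraint: PropertyChange | None
    samples: list[str]  # canonical SMILES, unique, valid, != start
    attempts: int
    exhausted: bool = False  # max_attempts hit before n_unique collected


def positional_encoding(length: int, width: int) -> np.ndarray:
    position = np.arange(length)[:, None].astype(np.float32)
    div = np.exp(np.arange(0, width, 2) * (-np.log(10000.0) / width)).astype(np.float32)
    pe = np.zeros((length, width), dtype=np.float32)
    pe[:, 0::2] = np.sin(position * div)
    pe[:, 1::2] = np.cos(position * div)
    return pe


def _linear_params(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    w = Tensor(rng.uniform(-limit, limit, (fan_in, fan_out)).astype(np.float32), True)
    b = Tensor(np.zeros(fan_out, dtype=np.float32), True)
    return w, b


class _Attention:
    def __init__(self, rng, width, heads):
        self.heads = heads
        self.head_width = width // heads
        self.wq, self.bq = _linear_params(rng, width, width)
        self.wk, self.bk = _linear_params(rng, width, width)
        self.wv, self.bv = _linear_params(rng, width, width)
        self.wo, self.bo = _linear_params(rng, width, width)

    def params(self):
        return [self.wq, self.bq, self.wk, self.bk, self.wv, self.bv, self.wo, self.bo]

    def __call__(self, query: Tensor, kv: Tensor, additive_mask: np.ndarray) -> Tensor:
        b, tq, d = query.shape
        tk = kv.shape[1]
        h, dh = self.heads, self.head_width

        def split(x, t):
            return x.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q = split(linear(query, self.wq, self.bq), tq)
        k = split(linear(kv, self.wk, self.bk), tk)
        v = split(linear(kv, self.wv, self.bv), tk)
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = softmax_last(scores, additive_mask, scale=1.0 / np.sqrt(dh))
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, tq, d)
        return linear(out, self.wo, self.bo)


class _FeedForward:
    def __init__(self, rng, width, hidden):
        self.w1, self.b1 = _linear_params(rng, width, hidden)
        self.w2, self.b2 = _linear_params(rng, hidden, width)

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def __call__(self, x: Tensor) -> Tensor:
        return linear(linear(x, self.w1, self.b1).relu(), self.w2, self.b2)


class _Norm:
    def __init__(self, width):
        self.gamma = Tensor(np.ones(width, dtype=np.float32), True)
        self.beta = Tensor(np.zeros(width, dtype=np.float32), True)

    def params(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)


class _EncoderLayer:
    def __init__(self, rng, cfg: ModelConfig):
        self.attn = _Attention(rng, cfg.model_width, cfg.num_attention_heads)
        self.ff = _FeedForward(rng, cfg.model_width, cfg.feedforward_width)
        self.norm1, self.norm2 = _Norm(cfg.model_width), _Norm(cfg.model_width)

    def params(self):
        return self.attn.params() + self.ff.params() + self.norm1.params() + self.norm2.params()

    def __call__(self, x, src_mask, p, rng, training):
        x = self.norm1(x + dropout(self.attn(x, x, src_mask), p, rng, training))
        return self.norm2(x + dropout(self.ff(x), p, rng, training))


class _DecoderLayer:
    def __init__(self, rng, cfg: ModelConfig):
        self.self_attn = _Attention(rng, cfg.model_width, cfg.num_attention_heads)
        self.cross_attn = _Attention(rng, cfg.model_width, cfg.num_attention_heads)
        self.ff = _FeedForward(rng, cfg.model_width, cfg.feedforward_width)
        self.norm1 = _Norm(cfg.model_width)
        self.norm2 = _Norm(cfg.model_width)
        self.norm3 = _Norm(cfg.model_width)

    def params(self):
        return (
            self.self_attn.params()
            + self.cross_attn.params()
            + self.ff.params()
            + self.norm1.params()
            + self.norm2.params()
            + self.norm3.params()
        )

    def __call__(self, x, memory, causal_mask, src_mask, p, rng, training):
        x = self.norm1(x + dropout(self.self_attn(x, x, causal_mask), p, rng, training))
        x = self.norm2(x + dropout(self.cross_attn(x, memory, src_mask), p, rng, training))
        return self.norm3(x + dropout(self.ff(x), p, rng, training))


class TransformerModel:
    """The network: embeddings, encoder stack, decoder stack, output head."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        d = config.model_width
        scale = d ** -0.5
        self.embed = Tensor(
            rng.normal(0.0, scale, (len(vocab), d)).astype(np.float32), True
        )
        self.enc_layers = [_EncoderLayer(rng, config) for _ in range(config.num_layers)]
        self.dec_layers = [_DecoderLayer(rng, config) for _ in range(config.num_layers)]
        self.wout, self.bout = _linear_params(rng, d, len(vocab))
        self.pe = positional_encoding(config.max_sequence_length, d)
        self._pe_tensor = Tensor(self.pe)

    def params(self) -> list[Tensor]:
        out = [self.embed, self.wout, self.bout]
        for layer in self.enc_layers + self.dec_layers:
            out += layer.params()
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()]

    # -- masks -------------------------------------------------------------

    def _pad_mask(self, ids: np.ndarray) -> np.ndarray:
        # (B, 1, 1, S): -inf at padding key positions
        return np.where(ids == self.vocab.pad, NEG_INF, np.float32(0.0))[:, None, None, :]

    @staticmethod
    def _causal_mask(t: int) -> np.ndarray:
        return np.triu(np.full((t, t), NEG_INF, dtype=np.float32), k=1)[None, None]

    # -- forward -----------------------------------------------------------

    def _embed_ids(self, ids: np.ndarray, p, rng, training) -> Tensor:
        x = embedding(self.embed, ids).scale(np.sqrt(self.config.model_width))
        x = x + Tensor(self.pe[: ids.shape[1]])
        return dropout(x, p, rng, training)

    def encode(self, src_ids: np.ndarray, rng=None, training=False) -> tuple[Tensor, np.ndarray]:
        if src_ids.shape[1] > self.config.max_sequence_length:
            raise ValueError("source sequence exceeds max_sequence_length")
        p = self.config.dropout
        src_mask = self._pad_mask(src_ids)
        x = self._embed_ids(src_ids, p, rng, training)
        for layer in self.enc_layers:
            x = layer(x, src_mask, p, rng, training)
        return x, src_mask

    def decode(
        self, tgt_ids: np.ndarray, memory: Tensor, src_mask: np.ndarray, rng=None, training=False
    ) -> Tensor:
        if tgt_ids.shape[1] > self.config.max_sequence_length:
            raise ValueError("target sequence exceeds max_sequence_length")
        p = self.config.dropout
        t = tgt_ids.shape[1]
        causal = self._causal_mask(t) + self._pad_mask(tgt_ids)
        x = self._embed_ids(tgt_ids, p, rng, training)
        for layer in self.dec_layers:
            x = layer(x, memory, causal, src_mask, p, rng, training)
        return linear(x, self.wout, self.bout)  # (B, T, V) logits

    def step_loss(self, src_ids: np.ndarray, tgt_ids: np.ndarray, rng=None, training=False) -> Tensor:
        """Teacher-forced token cross-entropy (padding excluded)."""
        memory, src_mask = self.encode(src_ids, rng, training)
        logits = self.decode(tgt_ids[:, :-1], memory, src_mask, rng, training)
        b, t, v = logits.shape
        labels = tgt_ids[:, 1:].reshape(-1)
        mask = (labels != self.vocab.pad).astype(np.float32)
        return cross_entropy_logits(logits.reshape(b * t, v), labels, mask)

    def token_accuracy(self, src_ids: np.ndarray, tgt_ids: np.ndarray) -> float:
        memory, src_mask = self.encode(src_ids)
        logits = self.decode(tgt_ids[:, :-1], memory, src_mask)
        pred = logits.data.argmax(axis=-1)
        labels = tgt_ids[:, 1:]
        mask = labels != self.vocab.pad
        return float((pred[mask] == labels[mask]).mean())


# --------------------------------------------------------------------------
# Data preparation and training
# --------------------------------------------------------------------------

def pair_sequences(pair: MolecularPair, conditional: bool) -> tuple[list[str], list[str]]:
    change = pair.change if conditional else None
    return assemble_source(change, pair.source.smiles), assemble_target(pair.target.smiles)


def dataset_vocab(dataset: PairDataset, conditional: bool) -> Vocabulary:
    """Vocabulary over all tokens actually fed to the model (all splits)."""
    tokens: dict[str, None] = {}
    for pair in dataset.all_pairs():
        src, tgt = pair_sequences(pair, conditional)
        for tok in src + tgt:
            if tok not in (START, END, PAD):
                tokens.setdefault(tok)
    if not tokens:
        raise ValueError("empty dataset")
    return Vocabulary(sorted(tokens))


def _encode_split(
    pairs: Sequence[MolecularPair], vocab: Vocabulary, conditional: bool, max_len: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for pair in pairs:
        src, tgt = pair_sequences(pair, conditional)
        if len(src) > max_len or len(tgt) > max_len:
            raise ValueError(
                f"sequence longer than max_sequence_length={max_len}: {pair.source.smiles}"
            )
        out.append((np.array(vocab.encode(src)), np.array(vocab.encode(tgt))))
    return out


def _pad_batch(seqs: list[np.ndarray], pad: int) -> np.ndarray:
    width = max(len(s) for s in seqs)
    out = np.full((len(seqs), width), pad, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, : len(s)] = s
    return out


@dataclass
class TrainedModel:
    model: TransformerModel
    conditional: bool
    loss_trace: list[float] = field(default_factory=list)
    valid_losses: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.model.vocab.save(directory / "vocab.txt")
        vocab_hash = sha256("\n".join(self.model.vocab.tokens).encode()).hexdigest()
        meta = {
            "config": asdict(self.model.config),
            "conditional": self.conditional,
            "vocab_sha256": vocab_hash,
            "loss_trace": self.loss_trace,
            "valid_losses": self.valid_losses,
            "best_epoch": self.best_epoch,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            directory / "weights.npz",
            **{f"p{i}": a for i, a in enumerate(self.model.state_arrays())},
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        vocab = Vocabulary.load(directory / "vocab.txt")
        vocab_hash = sha256("\n".join(vocab.tokens).encode()).hexdigest()
        if vocab_hash != meta["vocab_sha256"]:
            raise ValueError("vocabulary file does not match checkpoint hash")
        model = TransformerModel(ModelConfig(**meta["config"]), vocab)
        with np.load(directory / "weights.npz") as blob:
            for i, p in enumerate(model.params()):
                p.data[...] = blob[f"p{i}"]
        return cls(
            model,
            meta["conditional"],
            meta["loss_trace"],
            meta["valid_losses"],
            meta["best_epoch"],
        )


def train(
    dataset: PairDataset,
    config: ModelConfig = DESK_CONFIG,
    conditional: bool = True,
) -> TrainedModel:
    """Train on the dataset's train split, checkpointing by validation loss.

    ``conditional=False`` trains the unconditional variant (property tokens
    stripped from every source sequence).  Fixed seed implies an identical
    loss trace on identical data and hardware.
    """
    vocab = dataset_vocab(dataset, conditional)
    model = TransformerModel(config, vocab)
    max_len = config.max_sequence_length
    train_data = _encode_split(dataset.train, vocab, conditional, max_len)
    valid_data = _encode_split(dataset.valid, vocab, conditional, max_len)
    if not train_data:
        raise ValueError("empty training split")

    optimizer = Adam(
        model.params(), config.model_width, config.warmup_steps, factor=config.lr_factor
    )
    rng = np.random.default_rng(config.seed + 1)
    trained = TrainedModel(model, conditional)
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]

    def batches(data, shuffle):
        order = rng.permutation(len(data)) if shuffle else np.arange(len(data))
        for lo in range(0, len(order), config.batch_size):
            chunk = [data[i] for i in order[lo : lo + config.batch_size]]
            yield (
                _pad_batch([c[0] for c in chunk], vocab.pad),
                _pad_batch([c[1] for c in chunk], vocab.pad),
            )

    for epoch in range(config.epochs):
        for src, tgt in batches(train_data, shuffle=True):
            optimizer.zero_grad()
            loss = model.step_loss(src, tgt, rng, training=True)
            loss.backward()
            optimizer.step()
            trained.loss_trace.append(float(loss.data))
        if valid_data:
            val = float(
                np.mean([float(model.step_loss(s, t).data) for s, t in batches(valid_data, False)])
            )
        else:
            val = trained.loss_trace[-1]
        trained.valid_losses.append(val)
        if val < best_val:
            best_val = val
            best_state = [a.copy() for a in model.state_arrays()]
            trained.best_epoch = epoch
    for p, a in zip(model.params(), best_state):
        p.data[...] = a
    return trained


def train_unconditional(dataset: PairDataset, config: ModelConfig = DESK_CONFIG) -> TrainedModel:
    """The unconditional baseline: same architecture, no property tokens."""
    return train(dataset, config, conditional=False)


# --------------------------------------------------------------------------
# Sampling (incremental forward-only decoding with cached keys/values)
# --------------------------------------------------------------------------

def _np_ln(x: np.ndarray, norm: _Norm, eps: float = 1e-5) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * norm.gamma.data + norm.beta.data


def _np_heads(x: np.ndarray, heads: int) -> np.ndarray:
    b, t, d = x.shape
    return x.reshape(b, t, heads, d // heads).transpose(0, 2, 1, 3)


def _np_attend(q, k, v, additive_mask=None):
    dh = q.shape[-1]
    scores = q @ k.swapaxes(-1, -2) / np.sqrt(dh)
    if additive_mask is not None:
        scores = scores + additive_mask
    scores -= scores.max(axis=-1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=-1, keepdims=True)
    out = w @ v
    b, h, t, _ = out.shape
    return out.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


class _DecodeState:
    """Per-layer self-attention K/V caches plus precomputed cross K/V."""

    def __init__(self, model: TransformerModel, memory: np.ndarray, src_mask: np.ndarray):
        self.model = model
        h = model.config.num_attention_heads
        self.src_mask = src_mask
        self.self_k: list[np.ndarray | None] = [None] * len(model.dec_layers)
        self.self_v: list[np.ndarray | None] = [None] * len(model.dec_layers)
        self.cross_k = []
        self.cross_v = []
        for layer in model.dec_layers:
            att = layer.cross_attn
            self.cross_k.append(_np_heads(memory @ att.wk.data + att.bk.data, h))
            self.cross_v.append(_np_heads(memory @ att.wv.data + att.bv.data, h))

    def step(self, token_ids: np.ndarray, position: int) -> np.ndarray:
        """Advance one position; returns next-token logits (B, V)."""
        model = self.model
        h = model.config.num_attention_heads
        x = model.embed.data[token_ids][:, None, :] * np.sqrt(model.config.model_width)
        x = x + model.pe[position]
        for i, layer in enumerate(model.dec_layers):
            att = layer.self_attn
            q = _np_heads(x @ att.wq.data + att.bq.data, h)
            k = _np_heads(x @ att.wk.data + att.bk.data, h)
            v = _np_heads(x @ att.wv.data + att.bv.data, h)
            if self.self_k[i] is None:
                self.self_k[i], self.self_v[i] = k, v
            else:
                self.self_k[i] = np.concatenate([self.self_k[i], k], axis=2)
                self.self_v[i] = np.concatenate([self.self_v[i], v], axis=2)
            out = _np_attend(q, self.self_k[i], self.self_v[i])
            x = _np_ln(x + (out @ att.wo.data + att.bo.data), layer.norm1)
            att = layer.cross_attn
            q = _np_heads(x @ att.wq.data + att.bq.data, h)
            out = _np_attend(q, self.cross_k[i], self.cross_v[i], self.src_mask)
            x = _np_ln(x + (out @ att.wo.data + att.bo.data), layer.norm2)
            ff = np.maximum(x @ layer.ff.w1.data + layer.ff.b1.data, 0.0)
            x = _np_ln(x + (ff @ layer.ff.w2.data + layer.ff.b2.data), layer.norm3)
        return (x @ model.wout.data + model.bout.data)[:, 0, :]


def _decode_batch(
    model: TransformerModel, src_ids: np.ndarray, rng: np.random.Generator, max_length: int
) -> list[list[int]]:
    """Multinomial autoregressive decoding of one batch of identical inputs."""
    vocab = model.vocab
    memory, src_mask = model.encode(src_ids)
    state = _DecodeState(model, memory.data, src_mask)
    b = src_ids.shape[0]
    tokens = np.full(b, vocab.start, dtype=np.int64)
    seqs = [tokens]
    finished = np.zeros(b, dtype=bool)
    position = 0
    while position + 1 < max_length and not finished.all():
        logits = state.step(tokens, position)
        z = logits - logits.max(axis=-1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=-1, keepdims=True)
        cdf = probs.cumsum(axis=-1)
        u = rng.random((b, 1))
        nxt = (cdf < u).sum(axis=-1)
        nxt[finished] = vocab.pad
        seqs.append(nxt)
        finished |= nxt == vocab.end
        tokens = nxt
        position += 1
    stacked = np.stack(seqs, axis=1)
    out = []
    for row in stacked:
        ids = []
        for tok in row[1:]:
            if tok == vocab.end or tok == vocab.pad:
                break
            ids.append(int(tok))
        out.append(ids)
    return out


def sample(
    trained: TrainedModel,
    start: MoleculeRecord,
    constraint: PropertyChange | None,
    n_unique: int = 10,
    max_length: int | None = None,
    max_attempts: int | None = None,
    seed: int | np.random.Generator = 0,
) -> GenerationResult:
    """Sample until ``n_unique`` unique valid molecules differ from the start.

    Each sequence is decoded autoregressively, drawing every token from the
    full softmax distribution.  Sampled SMILES that fail to parse, duplicate
    an earlier sample, or canonicalize to the start molecule are discarded
    and sampling continues, up to ``max_attempts`` (default 10 * n_unique)
    decoded sequences; running out is flagged, not an error.
    """
    model = trained.model
    constraint_used = constraint if trained.conditional else None
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_length = max_length or model.config.max_sequence_length
    max_attempts = max_attempts or 10 * n_unique
    src = assemble_source(constraint_used, start.smiles)
    src_row = np.array(model.vocab.encode(src), dtype=np.int64)

    collected: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while attempts < max_attempts and len(collected) < n_unique:
        batch = min(max(n_unique - len(collected), 1) * 2, max_attempts - attempts)
        src_ids = np.tile(src_row, (batch, 1))
        for ids in _decode_batch(model, src_ids, rng, max_length):
            attempts += 1
            smiles = "".join(model.vocab.decode(ids))
            try:
                canonical = standardize(smiles).smiles
            except MoleculeError:
                continue
            if canonical == start.smiles or canonical in seen:
                continue
            seen.add(canonical)
            collected.append(canonical)
            if len(collected) >= n_unique:
                break
    return GenerationResult(
        start=start,
        constraint=constraint,
        samples=collected,
        attempts=attempts,
        exhausted=len(collected) < n_unique,
    )
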
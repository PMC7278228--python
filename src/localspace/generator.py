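"""Character-level LSTM SMILES generator: model, training, sampling.

The model is an autoregressive sequence network over the fixed 37-token
SMILES alphabet: two stacked LSTM layers (forget-gate bias 1.0), inverted
dropout with keep probability 0.8 applied to each layer's upward output
(the recurrent path is never dropped), and a fully connected softmax head.
Training minimizes mean next-token cross-entropy with Adam (learning rate
0.003) under global gradient-norm clipping at 5; recurrent state is carried
across consecutive chunks of each epoch so the network sees the corpus as
one continuous stream.

Everything is plain NumPy.  Each training step backpropagates through one
``n_streams x chunk_len`` chunk (truncated BPTT); the carried state is
treated as a constant at chunk boundaries.

Sampling starts from the "\\n" boundary token and zero state, draws every
next token from the model's softmax distribution (temperature 1) and stops
after exactly ``token_budget`` draws; the run is split at boundary tokens,
a trailing unterminated fragment is discarded, and the remaining sequences
are validity-checked, canonicalized and deduplicated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import chem_prep
from .chem_prep import MoleculeRecord, StandardizationError
from .corpus import (
    TokenStream,
    Vocabulary,
    build_stream,
    decode,
    emit_chunks,
    plan_chunks,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SampleBatch",
    "Generator",
    "build_model",
    "sequence_loss",
    "draw_dropout_mask",
]

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-8
_FORGET_BIAS = 1.0
_LOG_FLOOR = 1e-12  # numerical floor inside log()


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture and optimizer hyperparameters.

    Defaults are the full-scale protocol: 2 stacked LSTM layers, dropout
    keep 0.8, Adam lr 0.003, gradient-norm clip 5, 128 parallel streams of
    64 time steps.  ``hidden_units`` is 256 for directly trained models and
    512 for the pretrained/transfer model.
    """

    n_layers: int = 2
    hidden_units: int = 256
    dropout_keep: float = 0.8
    learning_rate: float = 0.003
    grad_clip_norm: float = 5.0
    n_streams: int = 128
    chunk_len: int = 64
    vocab_size: int = 37
    init_seed: int = 0

    def validate(self) -> None:
        if self.n_layers != 2:
            raise ValueError("the architecture uses exactly 2 stacked LSTM layers")
        if not (0.0 < self.dropout_keep <= 1.0):
            raise ValueError("dropout_keep must be in (0, 1]")
        for name in ("hidden_units", "n_streams", "chunk_len", "vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0 or self.grad_clip_norm <= 0:
            raise ValueError("learning_rate and grad_clip_norm must be positive")


@dataclass
class SampleBatch:
    """Outcome of one token-sampling run after cleanup."""

    raw_token_count: int
    sequences: list[str]  # complete boundary-delimited text fragments
    valid_unique: list[MoleculeRecord]
    n_invalid: int
    n_duplicate: int
    n_trailing_tokens: int = 0  # budget-cut unterminated fragment, discarded


def draw_dropout_mask(
    rng: np.random.Generator, shape: tuple[int, ...], keep: float
) -> np.ndarray:
    """Inverted-dropout mask: Bernoulli(keep) scaled by 1/keep."""
    return (rng.random(shape) < keep).astype(np.float64) / keep


def sequence_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean next-token cross-entropy, -log p(target), over all positions.

    ``probs`` has shape (..., vocab_size); ``targets`` holds the matching
    integer indices.  Probabilities are floored so the loss stays finite.
    """
    p = np.take_along_axis(probs, np.asarray(targets)[..., None], axis=-1)
    return float(-np.log(np.maximum(p, _LOG_FLOOR)).mean())


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


class Generator:
    """Two-layer LSTM language model over SMILES tokens.

    Parameters per layer l: ``Wx_l`` (input->gates), ``Wh_l``
    (hidden->gates), ``b_l``; gates are ordered [input, forget, cell,
    output].  The head is ``Wy``/``by``.  One-hot input times ``Wx`` is
    realized as row selection.
    """

    def __init__(self, config: GeneratorConfig, vocab: Vocabulary | None = None):
        config.validate()
        self.config = config
        self.vocab = vocab or Vocabulary()
        if len(self.vocab) != config.vocab_size:
            raise ValueError("config.vocab_size does not match the vocabulary")
        self.training_log: list[tuple[int, float]] = []  # (global step, loss)
        self._global_step = 0
        rng = np.random.default_rng(config.init_seed)
        H, V = config.hidden_units, config.vocab_size
        self.params: dict[str, np.ndarray] = {}
        for l in range(config.n_layers):
            n_in = V if l == 0 else H
            self.params[f"Wx{l}"] = _glorot(rng, n_in, 4 * H)
            self.params[f"Wh{l}"] = _glorot(rng, H, 4 * H)
            self.params[f"b{l}"] = np.zeros(4 * H)
        self.params["Wy"] = _glorot(rng, H, V)
        self.params["by"] = np.zeros(V)
        # Adam state
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- state ------------------------------------------------------------

    def zero_state(self, batch: int) -> list[tuple[np.ndarray, np.ndarray]]:
        H = self.config.hidden_units
        return [
            (np.zeros((batch, H)), np.zeros((batch, H)))
            for _ in range(self.config.n_layers)
        ]

    # -- forward ----------------------------------------------------------

    def _cell(self, l: int, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        """One LSTM step for layer l.  Returns (h_new, c_new, cache)."""
        p = self.params
        a = x @ p[f"Wx{l}"] + h @ p[f"Wh{l}"] + p[f"b{l}"]
        H = self.config.hidden_units
        i = _sigmoid(a[:, :H])
        f = _sigmoid(a[:, H : 2 * H] + _FORGET_BIAS)
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = _sigmoid(a[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        return h_new, c_new, (x, h, c, i, f, g, o, tanh_c)

    def forward(
        self,
        inputs: np.ndarray,
        state: list[tuple[np.ndarray, np.ndarray]],
        training: bool,
        rng: np.random.Generator | None = None,
    ):
        """Run a (batch, T) index block through the network.

        Returns (probs of shape (batch, T, V), final state, caches).
        Dropout masks are drawn per time step in training mode only.
        """
        cfg = self.config
        B, T = inputs.shape
        keep = cfg.dropout_keep
        state = [(h.copy(), c.copy()) for h, c in state]
        caches: list[list] = [[] for _ in range(cfg.n_layers)]
        masks: list[list] = [[] for _ in range(cfg.n_layers)]
        hs_top = np.empty((B, T, cfg.hidden_units))
        for t in range(T):
            x = self.params["Wx0"][inputs[:, t]]  # one-hot @ Wx0 == row select
            # layer 0 consumes the row-selected projection directly
            a = x + state[0][0] @ self.params["Wh0"] + self.params["b0"]
            H = cfg.hidden_units
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H] + _FORGET_BIAS)
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c_new = f * state[0][1] + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            caches[0].append((inputs[:, t], state[0][0], state[0][1], i, f, g, o, tanh_c))
            state[0] = (h_new, c_new)
            up = h_new
            if training and keep < 1.0:
                m = draw_dropout_mask(rng, up.shape, keep)
                masks[0].append(m)
                up = up * m
            for l in range(1, cfg.n_layers):
                h_new, c_new, cache = self._cell(l, up, state[l][0], state[l][1])
                caches[l].append(cache)
                state[l] = (h_new, c_new)
                up = h_new
                if training and keep < 1.0:
                    m = draw_dropout_mask(rng, up.shape, keep)
                    masks[l].append(m)
                    up = up * m
            hs_top[:, t, :] = up
        logits = hs_top @ self.params["Wy"] + self.params["by"]
        probs = _softmax(logits)
        return probs, state, (caches, masks, hs_top, inputs)

    # -- backward ---------------------------------------------------------

    def _backward(self, probs, targets, cache):
        """Gradients of mean cross-entropy wrt all parameters (one chunk)."""
        caches, masks, hs_top, inputs = cache
        cfg = self.config
        B, T, V = probs.shape
        H = cfg.hidden_units
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}

        dlogits = probs.copy()
        np.put_along_axis(
            dlogits,
            targets[..., None],
            np.take_along_axis(dlogits, targets[..., None], axis=-1) - 1.0,
            axis=-1,
        )
        dlogits /= B * T
        grads["Wy"] = hs_top.reshape(-1, H).T @ dlogits.reshape(-1, V)
        grads["by"] = dlogits.sum(axis=(0, 1))
        dh_up = dlogits @ p["Wy"].T  # (B, T, H): grad wrt top dropped output

        # reverse-time sweep, top layer to bottom
        dh_next = [np.zeros((B, H)) for _ in range(cfg.n_layers)]
        dc_next = [np.zeros((B, H)) for _ in range(cfg.n_layers)]
        dup_below = np.zeros((B, T, H))  # grad flowing into layer below's output
        for l in range(cfg.n_layers - 1, -1, -1):
            from_above = dh_up if l == cfg.n_layers - 1 else dup_below
            dx_acc = np.zeros((B, T, H)) if l > 0 else None
            dh, dc = dh_next[l], dc_next[l]
            for t in range(T - 1, -1, -1):
                dout = from_above[:, t, :]
                if masks[l]:
                    dout = dout * masks[l][t]
                dh_total = dh + dout
                x, h_prev, c_prev, i, f, g, o, tanh_c = caches[l][t]
                do = dh_total * tanh_c
                dc_total = dc + dh_total * o * (1.0 - tanh_c**2)
                di = dc_total * g
                df = dc_total * c_prev
                dg = dc_total * i
                da = np.concatenate(
                    [
                        di * i * (1.0 - i),
                        df * f * (1.0 - f),
                        dg * (1.0 - g**2),
                        do * o * (1.0 - o),
                    ],
                    axis=1,
                )
                if l == 0:
                    np.add.at(grads["Wx0"], x, da)  # x is the index column
                else:
                    grads[f"Wx{l}"] += x.T @ da
                    dx_acc[:, t, :] = da @ p[f"Wx{l}"].T
                grads[f"Wh{l}"] += h_prev.T @ da
                grads[f"b{l}"] += da.sum(axis=0)
                dh = da @ p[f"Wh{l}"].T
                dc = dc_total * f
            dup_below = dx_acc
        return grads

    # -- optimizer --------------------------------------------------------

    def _adam_step(self, grads: dict[str, np.ndarray]) -> float:
        """Clip by global norm, then apply one Adam update.

        Returns the post-clip global gradient norm.
        """
        cfg = self.config
        norm = float(np.sqrt(sum(float((g**2).sum()) for g in grads.values())))
        if norm > cfg.grad_clip_norm:
            scale = cfg.grad_clip_norm / norm
            for g in grads.values():
                g *= scale
            norm = cfg.grad_clip_norm
        self._adam_t += 1
        t = self._adam_t
        lr = cfg.learning_rate
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= _ADAM_BETA1
            m += (1 - _ADAM_BETA1) * g
            v *= _ADAM_BETA2
            v += (1 - _ADAM_BETA2) * g * g
            mhat = m / (1 - _ADAM_BETA1**t)
            vhat = v / (1 - _ADAM_BETA2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + _ADAM_EPS)
        return norm

    # -- training ---------------------------------------------------------

    def train(
        self,
        stream: TokenStream,
        n_epochs: int,
        log_every: int = 200,
        seed: int = 0,
        grad_norm_trace: list | None = None,
    ) -> "Generator":
        """Train on a token stream for ``n_epochs`` passes.

        State starts at zeros each epoch and is carried across chunks.
        The training loss is appended to ``training_log`` every
        ``log_every`` steps.  Fully reproducible for fixed seeds.
        """
        cfg = self.config
        plan = plan_chunks(stream, cfg.n_streams, cfg.chunk_len)
        if plan.n_chunks < 1:
            raise ValueError(
                f"stream of {len(stream)} tokens yields no "
                f"{cfg.n_streams}x{cfg.chunk_len} chunk; reduce n_streams/chunk_len"
            )
        rng = np.random.default_rng(seed)
        for _epoch in range(n_epochs):
            state = self.zero_state(cfg.n_streams)
            for inp, tgt in emit_chunks(stream, plan):
                probs, state, cache = self.forward(inp, state, training=True, rng=rng)
                loss = sequence_loss(probs, tgt)
                grads = self._backward(probs, tgt, cache)
                norm = self._adam_step(grads)
                if grad_norm_trace is not None:
                    grad_norm_trace.append(norm)
                self._global_step += 1
                if self._global_step % log_every == 0:
                    self.training_log.append((self._global_step, loss))
        return self

    def fine_tune(
        self,
        sequences: Sequence[str],
        n_epochs: int,
        sample_every: int = 10,
        tokens_per_sample: int = 200_000,
        seed: int = 0,
        shuffle_seed: int | None = None,
    ) -> list[SampleBatch]:
        """Continue training on new sequences, sampling periodically.

        Trains ``n_epochs`` epochs on the (shuffled, concatenated) new
        corpus and emits one :class:`SampleBatch` after every
        ``sample_every`` epochs — ``floor(n_epochs / sample_every)``
        batches in total, which the screening loop pools.
        """
        stream = build_stream(
            list(sequences), self.vocab,
            shuffle_seed=seed if shuffle_seed is None else shuffle_seed,
        )
        n_batches = n_epochs // sample_every
        if n_batches == 0:
            logger.warning(
                "n_epochs=%d < sample_every=%d: no samples will be drawn",
                n_epochs, sample_every,
            )
        batches: list[SampleBatch] = []
        done = 0
        for b in range(n_batches):
            self.train(stream, sample_every, seed=seed + b)
            done += sample_every
            batches.append(self.sample(tokens_per_sample, seed=seed + 10_000 + b))
        if done < n_epochs:
            self.train(stream, n_epochs - done, seed=seed + n_batches)
        return batches

    # -- sampling ---------------------------------------------------------

    def sample(self, token_budget: int, seed: int = 0) -> SampleBatch:
        """Draw exactly ``token_budget`` tokens autoregressively.

        One continuous run: the boundary token and zero state start the
        chain, each next token is drawn from the softmax distribution, and
        predicted tokens/final states feed the next step.  The run is split
        at boundary tokens; the trailing unterminated fragment is dropped;
        fragments are validity-checked with RDKit, canonicalized and
        deduplicated.
        """
        if token_budget < 1:
            raise ValueError("token_budget must be >= 1")
        cfg = self.config
        rng = np.random.default_rng(seed)
        p = self.params
        H = cfg.hidden_units
        state = [(np.zeros((1, H)), np.zeros((1, H))) for _ in range(cfg.n_layers)]
        token = self.vocab.boundary_index
        drawn = np.empty(token_budget, dtype=np.int64)
        for step in range(token_budget):
            x = p["Wx0"][token][None, :]
            a = x + state[0][0] @ p["Wh0"] + p["b0"]
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H] + _FORGET_BIAS)
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = _sigmoid(a[:, 3 * H :])
            c = f * state[0][1] + i * g
            h = o * np.tanh(c)
            state[0] = (h, c)
            for l in range(1, cfg.n_layers):
                h, c, _ = self._cell(l, h, state[l][0], state[l][1])
                state[l] = (h, c)
            probs = _softmax(h @ p["Wy"] + p["by"])[0]
            # inverse-CDF draw (faster than rng.choice in a tight loop)
            token = int(np.searchsorted(np.cumsum(probs), rng.random()))
            token = min(token, cfg.vocab_size - 1)
            drawn[step] = token
        return self._collect(drawn, token_budget)

    def _collect(self, drawn: np.ndarray, budget: int) -> SampleBatch:
        """Split a token run at boundaries and clean up the fragments."""
        boundary = self.vocab.boundary_index
        sequences: list[str] = []
        start = 0
        for pos in np.flatnonzero(drawn == boundary):
            sequences.append(decode(drawn[start:pos], self.vocab))
            start = pos + 1
        n_trailing = int(drawn.size - start)  # unterminated fragment: dropped
        n_invalid = 0
        seen: set[str] = set()
        valid_unique: list[MoleculeRecord] = []
        n_duplicate = 0
        for smi in sequences:
            if not smi:
                n_invalid += 1
                continue
            try:
                rec = chem_prep.standardize(smi, source_tag="generated")
            except StandardizationError:
                n_invalid += 1
                continue
            if rec.smiles_canonical in seen:
                n_duplicate += 1
                continue
            seen.add(rec.smiles_canonical)
            valid_unique.append(rec)
        return SampleBatch(
            raw_token_count=budget,
            sequences=sequences,
            valid_unique=valid_unique,
            n_invalid=n_invalid,
            n_duplicate=n_duplicate,
            n_trailing_tokens=n_trailing,
        )

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint parameters, config and vocabulary in one .npz file."""
        meta = {"config": asdict(self.config), "tokens": list(self.vocab.tokens),
                "global_step": self._global_step, "training_log": self.training_log}
        np.savez(
            Path(path),
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "Generator":
        data = np.load(Path(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        gen = cls(GeneratorConfig(**meta["config"]), Vocabulary(meta["tokens"]))
        for k in gen.params:
            gen.params[k] = data[k]
        gen._global_step = meta["global_step"]
        gen.training_log = [tuple(x) for x in meta["training_log"]]
        return gen

    def clone(self) -> "Generator":
        """Deep copy (parameters, optimizer state, log)."""
        g = Generator(self.config, self.vocab)
        g.params = {k: v.copy() for k, v in self.params.items()}
        g._adam_m = {k: v.copy() for k, v in self._adam_m.items()}
        g._adam_v = {k: v.copy() for k, v in self._adam_v.items()}
        g._adam_t = self._adam_t
        g._global_step = self._global_step
        g.training_log = list(self.training_log)
        return g


def build_model(config: GeneratorConfig, vocab: Vocabulary | None = None) -> Generator:
    """Construct an untrained generator with seeded initialization."""
    return Generator(config, vocab)
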
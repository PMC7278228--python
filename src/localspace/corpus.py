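"""Tokenization, corpus concatenation and the stream/chunk training layout.

The generator works on a fixed 37-symbol SMILES alphabet.  Training corpora
are shuffled, newline-terminated and concatenated into one token stream with
no padding; the stream is then cut into ``n_streams`` parallel segments and
served to the network as ``n_streams x chunk_len`` blocks whose targets are
the inputs shifted by one token.  Tokens that do not fit the whole number of
blocks are ignored (counted in ``dropped_tail``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "VOCAB_TOKENS",
    "BOUNDARY",
    "Vocabulary",
    "TokenStream",
    "ChunkPlan",
    "TokenizationError",
    "tokenize",
    "detokenize",
    "build_stream",
    "plan_chunks",
    "emit_chunks",
    "one_hot",
]

#: The fixed generator alphabet: organic-subset atoms, ring-closure digits
#: 1-8, bond/branch/charge punctuation, the "\n" sequence terminator and the
#: eight multi-character symbols.  37 tokens total.
VOCAB_TOKENS: tuple[str, ...] = (
    "c", "C", "n", "N", "o", "O", "s", "S", "p", "P", "F", "I",
    "1", "2", "3", "4", "5", "6", "7", "8",
    "-", "+", "[", "]", "(", ")", "=", "#", "\n",
    "[nH]", "[S+]", "[O-]", "[N+]", "[N-]", "Br", "Cl", "Si",
)

BOUNDARY = "\n"


class TokenizationError(ValueError):
    """A SMILES position matched no vocabulary token."""

    def __init__(self, text: str, position: int):
        self.text = text
        self.position = position
        super().__init__(
            f"untokenizable character {text[position]!r} at position "
            f"{position} in {text!r}"
        )


class Vocabulary:
    """Ordered token set with a token<->index bijection."""

    def __init__(self, tokens: Sequence[str] = VOCAB_TOKENS):
        self.tokens: tuple[str, ...] = tuple(tokens)
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        self.index_of: dict[str, int] = {t: i for i, t in enumerate(self.tokens)}
        # longest-match order: multi-character symbols before their prefixes
        self._by_length = sorted(self.tokens, key=len, reverse=True)

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index_of

    @property
    def boundary_index(self) -> int:
        return self.index_of[BOUNDARY]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(list(self.tokens)))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(json.loads(Path(path).read_text()))


@dataclass
class TokenStream:
    """Concatenated encoded corpus; every sequence ends with the boundary."""

    indices: np.ndarray  # 1-D int array of vocabulary indices
    boundary_token: int
    n_sequences: int

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class ChunkPlan:
    """How many full n_streams x chunk_len blocks a stream supports.

    ``n_chunks = floor(len(stream) / (n_streams * chunk_len))``; the stream
    is split into ``n_streams`` contiguous segments of ``n_chunks *
    chunk_len`` tokens and everything past the consumed region is
    ``dropped_tail``.
    """

    n_streams: int
    chunk_len: int
    n_chunks: int
    dropped_tail: int

    @property
    def consumed(self) -> int:
        return self.n_chunks * self.n_streams * self.chunk_len


def tokenize(smiles: str, vocab: Vocabulary | None = None) -> list[str]:
    """Greedy longest-match segmentation; concatenation reproduces input."""
    vocab = vocab or Vocabulary()
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        for tok in vocab._by_length:
            if smiles.startswith(tok, i):
                tokens.append(tok)
                i += len(tok)
                break
        else:
            raise TokenizationError(smiles, i)
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


def encode(smiles: str, vocab: Vocabulary) -> list[int]:
    return [vocab.index_of[t] for t in tokenize(smiles, vocab)]


def decode(indices: Iterable[int], vocab: Vocabulary) -> str:
    return "".join(vocab.tokens[i] for i in indices)


def build_stream(
    sequences: Sequence[str], vocab: Vocabulary, shuffle_seed: int
) -> TokenStream:
    """Shuffle sequences, terminate each with "\\n", concatenate, encode.

    Untokenizable sequences are dropped with a logged count.  Raises
    ``ValueError`` if nothing tokenizable remains.
    """
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(sequences))
    encoded: list[list[int]] = []
    n_dropped = 0
    for j in order:
        try:
            idx = encode(sequences[j], vocab)
        except TokenizationError:
            n_dropped += 1
            continue
        idx.append(vocab.boundary_index)
        encoded.append(idx)
    if n_dropped:
        logger.warning("dropped %d untokenizable sequences", n_dropped)
    if not encoded:
        raise ValueError("no tokenizable sequences; stream would be empty")
    indices = np.concatenate([np.asarray(e, dtype=np.int64) for e in encoded])
    return TokenStream(
        indices=indices, boundary_token=vocab.boundary_index, n_sequences=len(encoded)
    )


def plan_chunks(stream: TokenStream, n_streams: int, chunk_len: int) -> ChunkPlan:
    """Compute the block count and ignored-tail size for a stream."""
    if n_streams < 1 or chunk_len < 1:
        raise ValueError("n_streams and chunk_len must be >= 1")
    length = len(stream)
    n_chunks = length // (n_streams * chunk_len)
    dropped = length - n_chunks * n_streams * chunk_len
    return ChunkPlan(n_streams, chunk_len, n_chunks, dropped)


def emit_chunks(
    stream: TokenStream, plan: ChunkPlan
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (input, target) index blocks of shape (n_streams, chunk_len).

    Stream ``i`` owns the contiguous segment starting at
    ``i * n_chunks * chunk_len``; its chunks are consecutive windows, so
    carrying recurrent state across chunks follows real token order.
    Targets are the inputs shifted forward by one position in the
    concatenated stream; the single position with no successor (the last
    consumed token when the tail is empty) gets the boundary token.
    """
    if plan.n_chunks < 1:
        raise ValueError(
            "corpus too small for this layout; reduce n_streams/chunk_len"
        )
    seg_len = plan.n_chunks * plan.chunk_len
    starts = np.arange(plan.n_streams) * seg_len
    length = len(stream)
    for k in range(plan.n_chunks):
        off = k * plan.chunk_len
        idx = starts[:, None] + off + np.arange(plan.chunk_len)[None, :]
        tgt_idx = idx + 1
        if tgt_idx.max() >= length:  # only possible with dropped_tail == 0
            targets = np.where(
                tgt_idx < length,
                stream.indices[np.minimum(tgt_idx, length - 1)],
                stream.boundary_token,
            )
        else:
            targets = stream.indices[tgt_idx]
        yield stream.indices[idx], targets


def one_hot(indices: np.ndarray, vocab_size: int) -> np.ndarray:
    """Indicator encoding along a trailing axis of length ``vocab_size``."""
    indices = np.asarray(indices)
    if indices.size and (indices.min() < 0 or indices.max() >= vocab_size):
        raise ValueError("index out of range for one-hot encoding")
    out = np.zeros(indices.shape + (vocab_size,), dtype=np.float64)
    np.put_along_axis(out, indices[..., None], 1.0, axis=-1)
    return out


def save_stream(stream: TokenStream, path: str | Path) -> None:
    """Cache a stream as a flat index array plus a JSON sidecar."""
    path = Path(path)
    stream.indices.astype(np.int32).tofile(path)
    sidecar = {
        "boundary_token": stream.boundary_token,
        "n_sequences": stream.n_sequences,
        "length": len(stream),
        "dtype": "int32",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_stream(path: str | Path) -> TokenStream:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    indices = np.fromfile(path, dtype=np.int32).astype(np.int64)
    assert indices.size == meta["length"]
    return TokenStream(indices, meta["boundary_token"], meta["n_sequences"])
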
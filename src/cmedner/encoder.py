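"""Per-character embedding stage.

Two interchangeable encoders produce the embedding matrix consumed by the
downstream feature extractors:

* :class:`FallbackEncoder` — a self-contained trainable character embedding
  table built from the training corpus.  Requires no download and is the
  default for fully offline runs.
* :class:`PretrainedEncoderAdapter` — a thin protocol wrapper around any
  external contextual encoder (e.g. a BERT-family model for Chinese
  biomedical text) exposed as a callable ``chars -> (len+2, dim)`` array
  covering ``[CLS] chars [SEP]``.  No weights ship with this package.

Every sentence is encoded as ``[CLS] c1 .. cn [SEP]`` padded to a common
width; the returned character mask marks the real characters only, so CLS,
SEP and PAD positions are excluded from CRF scoring and evaluation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .autodiff import Tensor, embedding
from .corpus import LabeledSequence

__all__ = [
    "PAD", "UNK", "CLS", "SEP",
    "FallbackEncoder",
    "PretrainedEncoderAdapter",
    "make_fallback_encoder",
    "encode",
]

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
PAD_ID, UNK_ID, CLS_ID, SEP_ID = 0, 1, 2, 3
_N_SPECIAL = 4


class FallbackEncoder:
    """Trainable character-embedding table with UNK/PAD/CLS/SEP rows."""

    mode = "fallback"

    def __init__(self, vocab: dict[str, int], table: Tensor, trainable: bool = True):
        if table.shape[0] != len(vocab) + _N_SPECIAL:
            raise ValueError("embedding table rows must equal vocabulary + specials")
        self.vocab = dict(vocab)
        self.table = table
        self.table.requires_grad = bool(trainable)

    @property
    def dim(self) -> int:
        return self.table.shape[1]

    def lookup(self, ch: str) -> int:
        return self.vocab.get(ch, UNK_ID)

    def parameters(self) -> list[Tensor]:
        return [self.table] if self.table.requires_grad else []

    def ordered_chars(self) -> list[str]:
        """Vocabulary characters in index order (for serialization)."""
        return [ch for ch, _ in sorted(self.vocab.items(), key=lambda kv: kv[1])]


class PretrainedEncoderAdapter:
    """Adapter for an external pretrained contextual encoder.

    ``embed_fn(chars)`` must return a ``(len(chars) + 2, dim)`` float array
    whose first and last rows correspond to CLS and SEP.  ``freeze`` controls
    whether gradients are allowed to flow into the produced embeddings
    (useful when the caller can consume them for fine-tuning).
    """

    mode = "pretrained-adapter"

    def __init__(self, embed_fn: Callable[[Sequence[str]], np.ndarray], dim: int,
                 freeze: bool = True):
        if dim <= 0:
            raise ValueError("dim must be positive")
        self.embed_fn = embed_fn
        self.dim = int(dim)
        self.freeze = bool(freeze)

    def parameters(self) -> list[Tensor]:
        return []


def make_fallback_encoder(
    corpus: Sequence[LabeledSequence], dim: int, seed: int
) -> FallbackEncoder:
    """Build a trainable fallback encoder from the corpus character set.

    The vocabulary is the sorted set of corpus characters (deterministic);
    the table is initialized from a seeded normal(0, 0.1) draw.
    """
    if dim <= 0:
        raise ValueError("dim must be positive")
    chars = sorted({c for seq in corpus for c in getattr(seq, "chars", seq)})
    if not chars:
        raise ValueError("cannot build an encoder from an empty corpus")
    vocab = {ch: i + _N_SPECIAL for i, ch in enumerate(chars)}
    rng = np.random.default_rng(seed)
    table = Tensor(rng.normal(0.0, 0.1, size=(len(vocab) + _N_SPECIAL, dim)),
                   requires_grad=True)
    return FallbackEncoder(vocab, table)


def encode(
    seqs: Sequence[Sequence[str]], enc, max_len: int
) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Embed a batch of character lists.

    Each sentence becomes ``[CLS] chars [SEP]`` right-truncated to
    ``max_len`` positions total and padded to a common width of exactly
    ``max_len``.  Returns ``(embeddings, char_mask, valid_mask)`` where
    ``embeddings`` is ``(batch, max_len, dim)``, ``char_mask`` marks real
    characters and ``valid_mask`` marks everything except PAD.
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3 (CLS + one character + SEP)")
    batch = [list(s)[: max_len - 2] for s in seqs]
    n = len(batch)
    if n == 0:
        return (
            Tensor(np.zeros((0, 0, enc.dim))),
            np.zeros((0, 0), dtype=bool),
            np.zeros((0, 0), dtype=bool),
        )
    width = max_len
    char_mask = np.zeros((n, width), dtype=bool)
    valid_mask = np.zeros((n, width), dtype=bool)
    for b, chars in enumerate(batch):
        char_mask[b, 1 : 1 + len(chars)] = True
        valid_mask[b, : len(chars) + 2] = True

    if isinstance(enc, FallbackEncoder):
        idx = np.full((n, width), PAD_ID, dtype=np.intp)
        for b, chars in enumerate(batch):
            idx[b, 0] = CLS_ID
            for j, ch in enumerate(chars, start=1):
                idx[b, j] = enc.lookup(ch)
            idx[b, len(chars) + 1] = SEP_ID
        emb = embedding(enc.table, idx)
    elif isinstance(enc, PretrainedEncoderAdapter):
        data = np.zeros((n, width, enc.dim))
        for b, chars in enumerate(batch):
            rows = np.asarray(enc.embed_fn(chars), dtype=np.float64)
            if rows.shape != (len(chars) + 2, enc.dim):
                raise ValueError(
                    f"adapter returned shape {rows.shape}, "
                    f"expected {(len(chars) + 2, enc.dim)}"
                )
            data[b, : len(chars) + 2] = rows
        emb = Tensor(data, requires_grad=not enc.freeze)
    else:
        raise TypeError(f"unsupported encoder {type(enc).__name__}")
    return emb, char_mask, valid_mask
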
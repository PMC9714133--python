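"""Shared fixtures: the canonical worked example sentence, small schemes,
and helpers for seeded random corpora and numerical gradient checks."""

from __future__ import annotations

import numpy as np
import pytest

from cmedner.corpus import LabeledSequence, TagScheme
from cmedner.synthetic import EntityProfile, SyntheticCorpusSpec, generate_corpus

# The standard worked record for this corpus dialect:
# "右腕疼痛2小时。" = right wrist pain for 2 hours.
EXAMPLE_CHARS = list("右腕疼痛2小时。")
EXAMPLE_TAGS = ["B-BODY", "I-BODY", "B-SYMPTOM", "I-SYMPTOM", "O", "O", "O", "O"]
EXAMPLE_BIO_TEXT = (
    "右 B-BODY\n腕 I-BODY\n疼 B-SYMPTOM\n痛 I-SYMPTOM\n2 O\n小 O\n时 O\n。 O\n"
)


@pytest.fixture
def example_scheme() -> TagScheme:
    return TagScheme(["BODY", "SYMPTOM"])


@pytest.fixture
def example_sentence() -> LabeledSequence:
    return LabeledSequence(EXAMPLE_CHARS.copy(), EXAMPLE_TAGS.copy())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_corpus(
    n_sentences: int,
    n_types: int = 3,
    seed: int = 0,
    rate: float = 0.6,
    vocab: int = 60,
) -> tuple[SyntheticCorpusSpec, list, list, list]:
    """Small synthetic corpus helper used across test modules."""
    scheme = TagScheme([f"T{i}" for i in range(n_types)])
    spec = SyntheticCorpusSpec(
        scheme=scheme,
        n_sentences=n_sentences,
        vocab=vocab,
        profiles=tuple(EntityProfile(rate=rate, span_range=(2, 3)) for _ in range(n_types)),
        seed=seed,
    )
    train, dev, test = generate_corpus(spec)
    return spec, train, dev, test


def numerical_gradient(f, params, eps: float = 1e-6) -> list[np.ndarray]:
    """Central-difference gradients of a scalar function of Tensor params."""
    grads = []
    for p in params:
        g = np.zeros_like(p.data)
        flat, gf = p.data.ravel(), g.ravel()
        for i in range(flat.size):
            old = flat[i]
            flat[i] = old + eps
            fp = f()
            flat[i] = old - eps
            fm = f()
            flat[i] = old
            gf[i] = (fp - fm) / (2.0 * eps)
        grads.append(g)
    return grads
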
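"""Synthetic imbalanced BIO corpus generator.

Clinical NER corpora such as the CCKS releases are access-restricted, so
this module generates character-level corpora with their statistical
structure: short sentences ending in "。", several entity types whose
mention counts are heavily skewed (roughly 10:1 between frequent and rare
types in CCKS-2017), and contiguous multi-character entity spans.

Each entity type draws its span characters from a dedicated code-point
range disjoint from the background range, mimicking the vocabulary
clustering of medical terms and making types learnable without any real
EMR text.  Per-sentence mention counts are Poisson; spans are placed at
uniformly random non-overlapping positions (a stars-and-bars gap draw).
The generator is fully deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import LabeledSequence, TagScheme

__all__ = [
    "EntityProfile",
    "SyntheticCorpusSpec",
    "generate_corpus",
    "imbalance_experiment",
]

_BACKGROUND_BASE = 0x4E00  # CJK unified ideographs
_TYPE_BASE = 0x5100  # per-type blocks of 0x100 code points, disjoint from background
_TYPE_BLOCK = 0x100
TERMINATOR = "。"  # "。"


@dataclass(frozen=True)
class EntityProfile:
    """Generation parameters for one entity type."""

    rate: float = 0.8  # expected mentions per sentence (Poisson)
    span_range: tuple[int, int] = (2, 4)  # inclusive span length range
    pool_size: int = 20  # dedicated characters for this type

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        lo, hi = self.span_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid span range {self.span_range}")
        if not 1 <= self.pool_size <= _TYPE_BLOCK:
            raise ValueError(f"pool_size must be in [1, {_TYPE_BLOCK}]")


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Conditions for one synthetic corpus draw.

    ``sentence_length`` bounds the number of content characters per
    sentence (the "。" terminator is appended on top).  ``profiles`` align
    with ``scheme.entity_types``; when omitted, every type gets the default
    :class:`EntityProfile`.
    """

    scheme: TagScheme
    n_sentences: int = 1000
    sentence_length: tuple[int, int] = (8, 18)
    vocab: int = 60
    profiles: tuple[EntityProfile, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be >= 1")
        lo, hi = self.sentence_length
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid sentence length range {self.sentence_length}")
        if not 1 <= self.vocab <= (_TYPE_BASE - _BACKGROUND_BASE):
            raise ValueError("background vocabulary size out of range")
        if self.profiles and len(self.profiles) != len(self.scheme.entity_types):
            raise ValueError("profiles must align one-to-one with entity types")

    def resolved_profiles(self) -> tuple[EntityProfile, ...]:
        if self.profiles:
            return self.profiles
        return tuple(EntityProfile() for _ in self.scheme.entity_types)


def _type_pool(type_index: int, size: int) -> list[str]:
    base = _TYPE_BASE + type_index * _TYPE_BLOCK
    return [chr(base + j) for j in range(size)]


def _check_feasible(spec: SyntheticCorpusSpec) -> None:
    profiles = spec.resolved_profiles()
    expected = sum(p.rate * (p.span_range[0] + p.span_range[1]) / 2.0 for p in profiles)
    min_len = spec.sentence_length[0]
    if expected > 0.8 * min_len:
        raise ValueError(
            f"infeasible placement: expected entity occupancy {expected:.1f} characters "
            f"exceeds 80% of the minimum sentence length {min_len}"
        )


def _one_sentence(
    spec: SyntheticCorpusSpec,
    profiles: Sequence[EntityProfile],
    bg_pool: list[str],
    type_pools: list[list[str]],
    rng: np.random.Generator,
) -> LabeledSequence:
    lo, hi = spec.sentence_length
    length = int(rng.integers(lo, hi + 1))
    mentions: list[tuple[int, int]] = []  # (type index, span length)
    for k, prof in enumerate(profiles):
        count = rng.poisson(prof.rate)
        for _ in range(count):
            span = int(rng.integers(prof.span_range[0], prof.span_range[1] + 1))
            mentions.append((k, span))
    if mentions:
        order = rng.permutation(len(mentions))
        mentions = [mentions[i] for i in order]
    # Poisson-thin mentions that cannot fit this sentence.
    while mentions and sum(s for _, s in mentions) > length:
        mentions.pop()
    chars: list[str] = []
    tags: list[str] = []
    free = length - sum(s for _, s in mentions)
    k_gaps = len(mentions) + 1
    gaps = rng.multinomial(free, np.full(k_gaps, 1.0 / k_gaps))
    types = spec.scheme.entity_types
    for g, mention in zip(gaps, list(mentions) + [None]):
        for _ in range(int(g)):
            chars.append(bg_pool[int(rng.integers(len(bg_pool)))])
            tags.append("O")
        if mention is not None:
            k, span = mention
            pool = type_pools[k]
            for j in range(span):
                chars.append(pool[int(rng.integers(len(pool)))])
                tags.append(f"B-{types[k]}" if j == 0 else f"I-{types[k]}")
    chars.append(TERMINATOR)
    tags.append("O")
    return LabeledSequence(chars, tags)


def generate_corpus(
    spec: SyntheticCorpusSpec,
) -> tuple[list[LabeledSequence], list[LabeledSequence], list[LabeledSequence]]:
    """Draw a corpus and split it 80/10/10 by a seeded shuffle.

    Returns ``(train, dev, test)``.  Raises ``ValueError`` when the
    requested mention rates and span lengths cannot fit the sentences.
    """
    _check_feasible(spec)
    profiles = spec.resolved_profiles()
    rng = np.random.default_rng(spec.seed)
    bg_pool = [chr(_BACKGROUND_BASE + j) for j in range(spec.vocab)]
    type_pools = [_type_pool(k, p.pool_size) for k, p in enumerate(profiles)]
    sentences = [
        _one_sentence(spec, profiles, bg_pool, type_pools, rng)
        for _ in range(spec.n_sentences)
    ]
    order = rng.permutation(spec.n_sentences)
    n_train = int(0.8 * spec.n_sentences)
    n_dev = int(0.1 * spec.n_sentences)
    train = [sentences[i] for i in order[:n_train]]
    dev = [sentences[i] for i in order[n_train : n_train + n_dev]]
    test = [sentences[i] for i in order[n_train + n_dev :]]
    return train, dev, test


def imbalance_experiment(
    base_spec: SyntheticCorpusSpec,
    ratios: Sequence[float],
    cfg,
    n_seeds: int,
) -> pd.DataFrame:
    """Measure per-type F1 as the frequent:rare mention-rate ratio varies.

    For each ratio the per-type rates interpolate geometrically from the
    first profile's rate down to ``rate / ratio`` for the last type, so a
    two-type scheme at ratio 10 reproduces the canonical 10:1 skew.  Each
    (ratio, seed) cell generates a fresh corpus, trains a model with
    ``cfg`` and evaluates the test split; rows are
    ``(ratio, seed, type, train_support, precision, recall, f1)``.
    """
    from .training import predict, train  # local import: no module cycle

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    profiles = base_spec.resolved_profiles()
    n_types = len(profiles)
    base_rate = profiles[0].rate
    rows = []
    from .metrics import entity_prf, imbalance_report

    for r_idx, ratio in enumerate(ratios):
        if ratio <= 0:
            raise ValueError("ratios must be positive")
        new_profiles = tuple(
            replace(
                p,
                rate=base_rate
                * ratio ** (-(k / (n_types - 1)) if n_types > 1 else 0.0),
            )
            for k, p in enumerate(profiles)
        )
        for s in range(n_seeds):
            offset = 1000 * r_idx + s
            spec_s = replace(base_spec, profiles=new_profiles, seed=base_spec.seed + offset)
            cfg_s = replace(cfg, seed=cfg.seed + offset)
            tr, dv, te = generate_corpus(spec_s)
            model, _ = train(tr, dv, cfg_s)
            preds = [tags for tags, _ in predict(model, [t.chars for t in te])]
            report = entity_prf(te, preds, base_spec.scheme)
            table = imbalance_report(report, tr)
            for _, row in table.iterrows():
                rows.append(
                    {
                        "ratio": float(ratio),
                        "seed": s,
                        "type": row["type"],
                        "train_support": int(row["train_support"]),
                        "precision": row["precision"],
                        "recall": row["recall"],
                        "f1": row["f1"],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["ratio", "seed", "type", "train_support", "precision", "recall", "f1"],
    )
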
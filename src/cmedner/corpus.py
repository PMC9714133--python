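"""Character-level BIO corpus handling.

The on-disk dialect is the two-column format used for Chinese clinical NER
corpora (CCKS-style): one line per character, ``<char><space><tag>``, a
blank line between sentences, UTF-8 throughout.  Sentences are character
sequences; no word segmentation is performed.  Tags follow the plain BIO
scheme: ``O`` plus ``B-<type>`` / ``I-<type>`` for each entity type.

Offsets are 0-based and half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "TagScheme",
    "LabeledSequence",
    "EntityMention",
    "CorpusFormatError",
    "read_bio_corpus",
    "write_bio_corpus",
    "corpus_to_text",
    "split_record",
    "tags_to_entities",
    "entities_to_tags",
]

SENTENCE_TERMINATORS = (".", "。")  # "." and "。"


class CorpusFormatError(ValueError):
    """Raised when a BIO corpus file violates the two-column dialect."""


class TagScheme:
    """An ordered set of entity types and the derived BIO label inventory.

    The label inventory is ``("O", "B-t1", "I-t1", "B-t2", ...)``; ``O`` is
    always index 0 and the inventory size is ``2 * len(entity_types) + 1``.
    The entity type set is user-supplied per corpus (e.g. CCKS-2017 uses
    BODY / TREATMENT / SIGNS / CHECK / DISEASE).
    """

    def __init__(self, entity_types: Iterable[str]):
        types = tuple(entity_types)
        if not types:
            raise ValueError("a tag scheme needs at least one entity type")
        if len(set(types)) != len(types):
            raise ValueError(f"duplicate entity types in {types!r}")
        for t in types:
            if not t or any(ch.isspace() for ch in t):
                raise ValueError(f"invalid entity type name {t!r}")
        self.entity_types: tuple[str, ...] = types
        self.labels: tuple[str, ...] = ("O",) + tuple(
            lab for t in types for lab in (f"B-{t}", f"I-{t}")
        )
        self.label_index: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.label_index[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in scheme {self.entity_types}") from None

    def label(self, index: int) -> str:
        return self.labels[index]

    def __eq__(self, other) -> bool:
        return isinstance(other, TagScheme) and self.entity_types == other.entity_types

    def __hash__(self) -> int:
        return hash(self.entity_types)

    def __repr__(self) -> str:
        return f"TagScheme({list(self.entity_types)!r})"


@dataclass
class LabeledSequence:
    """A sentence as aligned character and BIO tag lists."""

    chars: list[str]
    tags: list[str]

    def __post_init__(self):
        self.chars = list(self.chars)
        self.tags = list(self.tags)
        if len(self.chars) != len(self.tags):
            raise ValueError(
                f"chars/tags length mismatch: {len(self.chars)} vs {len(self.tags)}"
            )

    @property
    def text(self) -> str:
        return "".join(self.chars)

    def __len__(self) -> int:
        return len(self.chars)

    def validate(self, scheme: TagScheme) -> None:
        for ch in self.chars:
            if len(ch) != 1:
                raise ValueError(f"token {ch!r} is not a single character")
        for tag in self.tags:
            if tag not in scheme.label_index:
                raise ValueError(f"tag {tag!r} not in scheme {scheme.entity_types}")


@dataclass(frozen=True)
class EntityMention:
    """A typed entity span; ``text == chars[start:end]`` of its sentence."""

    type: str
    start: int
    end: int
    text: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.type, self.start, self.end)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_bio_corpus(path, scheme: TagScheme) -> list[LabeledSequence]:
    """Parse a two-column BIO file into sentences, in file order.

    Each non-blank line must be ``<char> <tag>`` with a single space; runs of
    blank lines collapse to a single sentence boundary.  Malformed lines
    raise :class:`CorpusFormatError` naming the line number.  An empty file
    yields an empty list.
    """
    sentences: list[LabeledSequence] = []
    chars: list[str] = []
    tags: list[str] = []

    def flush():
        if chars:
            sentences.append(LabeledSequence(chars.copy(), tags.copy()))
            chars.clear()
            tags.clear()

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line.strip() == "":
                flush()
                continue
            parts = line.split(" ")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected '<char> <tag>', got {line!r}"
                )
            ch, tag = parts
            if len(ch) != 1:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: token {ch!r} is not a single character"
                )
            if tag not in scheme.label_index:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: unknown tag {tag!r} "
                    f"for scheme {scheme.entity_types}"
                )
            chars.append(ch)
            tags.append(tag)
    flush()
    return sentences


def corpus_to_text(corpus: Sequence[LabeledSequence]) -> str:
    """Serialize to the canonical dialect: one blank line between sentences,
    exactly one trailing newline; an empty corpus serializes to an empty string."""
    blocks = [
        "\n".join(f"{c} {t}" for c, t in zip(seq.chars, seq.tags)) for seq in corpus
    ]
    if not blocks:
        return ""
    return "\n\n".join(blocks) + "\n"


def write_bio_corpus(corpus: Sequence[LabeledSequence], path) -> None:
    Path(path).write_text(corpus_to_text(corpus), encoding="utf-8")


def split_record(text: str) -> list[str]:
    """Cut a raw record into sentences after each ``.`` or ``。``.

    The terminator stays with its sentence; empty fragments are dropped.
    Text without a terminator is returned as a single sentence.
    """
    sentences: list[str] = []
    buf: list[str] = []
    for ch in text:
        buf.append(ch)
        if ch in SENTENCE_TERMINATORS:
            sentences.append("".join(buf))
            buf.clear()
    if buf:
        sentences.append("".join(buf))
    return sentences


# ---------------------------------------------------------------------------
# tag <-> span conversion
# ---------------------------------------------------------------------------

def _parse_tag(tag: str) -> tuple[str, str | None]:
    if tag == "O":
        return "O", None
    if tag.startswith("B-") and len(tag) > 2:
        return "B", tag[2:]
    if tag.startswith("I-") and len(tag) > 2:
        return "I", tag[2:]
    raise ValueError(f"malformed BIO tag {tag!r}")


def tags_to_entities(seq: LabeledSequence) -> list[EntityMention]:
    """Extract typed mentions from a BIO tag sequence.

    Maximal B-then-I runs of one type become mentions.  An ``I-`` tag whose
    predecessor is not ``B-``/``I-`` of the same type is repaired to ``B-``
    (CoNLL-style leniency), so every tag sequence is decodable.  Mentions are
    returned sorted by start offset.
    """
    mentions: list[EntityMention] = []
    cur_type: str | None = None
    cur_start = 0

    def close(end: int):
        nonlocal cur_type
        if cur_type is not None:
            mentions.append(
                EntityMention(
                    cur_type, cur_start, end, "".join(seq.chars[cur_start:end])
                )
            )
            cur_type = None

    for i, tag in enumerate(seq.tags):
        kind, etype = _parse_tag(tag)
        if kind == "O":
            close(i)
        elif kind == "B":
            close(i)
            cur_type, cur_start = etype, i
        else:  # "I": continue same-type run, else repair as a new mention
            if etype != cur_type:
                close(i)
                cur_type, cur_start = etype, i
    close(len(seq.tags))
    return mentions


def entities_to_tags(
    chars: Sequence[str], mentions: Sequence[EntityMention], scheme: TagScheme
) -> list[str]:
    """Render non-overlapping mentions back into a BIO tag list.

    Inverse of :func:`tags_to_entities` on well-formed mention sets whose
    same-type mentions are non-adjacent.  Raises ``ValueError`` on
    out-of-bounds or overlapping spans or on types outside the scheme.
    """
    n = len(chars)
    tags = ["O"] * n
    prev_end = -1
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        if m.type not in scheme.entity_types:
            raise ValueError(f"mention type {m.type!r} not in scheme {scheme.entity_types}")
        if not (0 <= m.start < m.end <= n):
            raise ValueError(f"mention span [{m.start}, {m.end}) out of bounds for n={n}")
        if m.start < prev_end:
            raise ValueError(f"overlapping mentions at offset {m.start}")
        tags[m.start] = f"B-{m.type}"
        for i in range(m.start + 1, m.end):
            tags[i] = f"I-{m.type}"
        prev_end = m.end
    return tags
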
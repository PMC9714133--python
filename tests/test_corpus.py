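"""BIO dialect parsing/serialization and tag <-> span conversion."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmedner.corpus import (
    CorpusFormatError,
    EntityMention,
    LabeledSequence,
    TagScheme,
    corpus_to_text,
    entities_to_tags,
    read_bio_corpus,
    split_record,
    tags_to_entities,
    write_bio_corpus,
)

from conftest import EXAMPLE_BIO_TEXT, EXAMPLE_CHARS, EXAMPLE_TAGS, make_corpus


class TestTagScheme:
    def test_label_inventory(self):
        scheme = TagScheme(["BODY", "TREATMENT", "SIGNS", "CHECK", "DISEASE"])
        assert len(scheme.labels) == 2 * 5 + 1
        assert scheme.labels[0] == "O"
        assert scheme.index("O") == 0
        # bijection
        assert sorted(scheme.label_index.values()) == list(range(11))
        for lab, i in scheme.label_index.items():
            assert scheme.label(i) == lab

    @pytest.mark.parametrize("types", [[], ["A", "A"], ["A B"], [""]])
    def test_invalid_type_sets_rejected(self, types):
        with pytest.raises(ValueError):
            TagScheme(types)


class TestReadWrite:
    def test_worked_example_parses(self, tmp_path, example_scheme):
        path = tmp_path / "ex.bio"
        path.write_text(EXAMPLE_BIO_TEXT, encoding="utf-8")
        corpus = read_bio_corpus(path, example_scheme)
        assert len(corpus) == 1
        assert len(corpus[0]) == 8
        assert corpus[0].chars == EXAMPLE_CHARS
        assert corpus[0].tags == EXAMPLE_TAGS

    def test_empty_file_gives_empty_corpus(self, tmp_path, example_scheme):
        path = tmp_path / "empty.bio"
        path.write_text("", encoding="utf-8")
        assert read_bio_corpus(path, example_scheme) == []

    def test_blank_line_runs_collapse(self, tmp_path, example_scheme):
        text = "右 B-BODY\n\n\n\n痛 B-SYMPTOM\n腕 I-SYMPTOM\n\n"
        path = tmp_path / "two.bio"
        path.write_text(text, encoding="utf-8")
        corpus = read_bio_corpus(path, example_scheme)
        assert [len(s) for s in corpus] == [1, 2]

    @pytest.mark.parametrize(
        "line, lineno",
        [
            ("右B-BODY", 1),  # no space
            ("右腕 B-BODY", 2),  # multi-char token
            ("右 B-XXX", 3),  # unknown tag
            ("右  B-BODY", 1),  # double space
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, example_scheme, line, lineno):
        good = "右 B-BODY\n"
        path = tmp_path / "bad.bio"
        path.write_text(good * (lineno - 1) + line + "\n", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match=f"line {lineno}"):
            read_bio_corpus(path, example_scheme)

    def test_round_trip_byte_identity(self, tmp_path, example_scheme):
        path = tmp_path / "rt.bio"
        path.write_text(EXAMPLE_BIO_TEXT, encoding="utf-8")
        corpus = read_bio_corpus(path, example_scheme)
        out = tmp_path / "out.bio"
        write_bio_corpus(corpus, out)
        assert out.read_text(encoding="utf-8") == EXAMPLE_BIO_TEXT

    def test_empty_corpus_writes_empty_file(self, tmp_path):
        out = tmp_path / "empty.bio"
        write_bio_corpus([], out)
        assert out.read_text(encoding="utf-8") == ""

    def test_random_corpora_double_round_trip(self, tmp_path):
        spec, train, dev, test = make_corpus(100, seed=42)
        corpus = train + dev + test
        p1, p2 = tmp_path / "a.bio", tmp_path / "b.bio"
        write_bio_corpus(corpus, p1)
        again = read_bio_corpus(p1, spec.scheme)
        write_bio_corpus(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [s.chars for s in again] == [s.chars for s in corpus]
        assert [s.tags for s in again] == [s.tags for s in corpus]


_char = st.sampled_from([chr(0x4E00 + i) for i in range(40)] + ["。", "2", "右"])
_label = st.sampled_from(["O", "B-BODY", "I-BODY", "B-SYMPTOM", "I-SYMPTOM"])
_sentence = st.lists(st.tuples(_char, _label), min_size=1, max_size=12)


class TestRoundTripProperty:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(_sentence, min_size=0, max_size=6))
    def test_serialize_parse_identity_on_arbitrary_corpora(self, tmp_path_factory, raw):
        scheme = TagScheme(["BODY", "SYMPTOM"])
        corpus = [
            LabeledSequence([c for c, _ in sent], [t for _, t in sent]) for sent in raw
        ]
        text = corpus_to_text(corpus)
        path = tmp_path_factory.mktemp("hyp") / "c.bio"
        path.write_text(text, encoding="utf-8")
        parsed = read_bio_corpus(path, scheme)
        assert [s.chars for s in parsed] == [s.chars for s in corpus]
        assert [s.tags for s in parsed] == [s.tags for s in corpus]
        assert corpus_to_text(parsed) == text


class TestSplitRecord:
    def test_splits_after_terminators(self):
        assert split_record("右腕疼痛2小时。急来我院。") == ["右腕疼痛2小时。", "急来我院。"]

    def test_empty_input(self):
        assert split_record("") == []

    def test_no_terminator_is_one_sentence(self):
        assert split_record("无终止符文本") == ["无终止符文本"]

    def test_ascii_period_also_cuts(self):
        assert split_record("a.b.") == ["a.", "b."]


class TestTagSpanConversion:
    def test_worked_example_mentions(self, example_sentence):
        mentions = tags_to_entities(example_sentence)
        assert [(m.type, m.start, m.end, m.text) for m in mentions] == [
            ("BODY", 0, 2, "右腕"),
            ("SYMPTOM", 2, 4, "疼痛"),
        ]

    def test_all_outside_yields_nothing(self):
        seq = LabeledSequence(list("abc"), ["O"] * 3)
        assert tags_to_entities(seq) == []

    def test_orphan_inside_repaired_to_begin(self):
        seq = LabeledSequence(list("ab"), ["I-SYMPTOM", "I-SYMPTOM"])
        mentions = tags_to_entities(seq)
        assert [(m.type, m.start, m.end) for m in mentions] == [("SYMPTOM", 0, 2)]

    def test_type_switch_inside_starts_new_mention(self):
        seq = LabeledSequence(list("abc"), ["B-BODY", "I-SYMPTOM", "I-SYMPTOM"])
        assert [(m.type, m.start, m.end) for m in tags_to_entities(seq)] == [
            ("BODY", 0, 1),
            ("SYMPTOM", 1, 3),
        ]

    def test_adjacent_same_type_b_runs_stay_distinct(self):
        seq = LabeledSequence(list("abcd"), ["B-BODY", "I-BODY", "B-BODY", "I-BODY"])
        assert [(m.start, m.end) for m in tags_to_entities(seq)] == [(0, 2), (2, 4)]

    def test_inverse_reproduces_worked_tags(self, example_scheme):
        mentions = [
            EntityMention("BODY", 0, 2, "右腕"),
            EntityMention("SYMPTOM", 2, 4, "疼痛"),
        ]
        assert entities_to_tags(EXAMPLE_CHARS, mentions, example_scheme) == EXAMPLE_TAGS

    def test_no_mentions_all_outside(self, example_scheme):
        assert entities_to_tags(list("abc"), [], example_scheme) == ["O"] * 3

    def test_overlapping_mentions_rejected(self, example_scheme):
        mentions = [EntityMention("BODY", 0, 3), EntityMention("SYMPTOM", 2, 4)]
        with pytest.raises(ValueError, match="overlap"):
            entities_to_tags(list("abcd"), mentions, example_scheme)

    def test_out_of_bounds_rejected(self, example_scheme):
        with pytest.raises(ValueError):
            entities_to_tags(list("ab"), [EntityMention("BODY", 1, 5)], example_scheme)

    def test_round_trip_random_nonadjacent_mentions(self, example_scheme):
        rng = np.random.default_rng(7)
        types = example_scheme.entity_types
        for _ in range(50):
            n = int(rng.integers(5, 30))
            chars = [chr(0x4E00 + int(c)) for c in rng.integers(0, 50, n)]
            mentions, pos = [], 0
            while pos < n - 2:
                start = pos + int(rng.integers(1, 4))  # >= 1 gap: never adjacent
                width = int(rng.integers(1, 4))
                if start + width > n:
                    break
                t = types[int(rng.integers(len(types)))]
                mentions.append(
                    EntityMention(t, start, start + width, "".join(chars[start : start + width]))
                )
                pos = start + width
            tags = entities_to_tags(chars, mentions, example_scheme)
            back = tags_to_entities(LabeledSequence(chars, tags))
            assert back == mentions

    def test_mention_text_matches_span(self):
        _, train, _, _ = make_corpus(20, seed=5)
        for seq in train:
            for m in tags_to_entities(seq):
                assert m.text == "".join(seq.chars[m.start : m.end])

    def test_serializer_round_trips_parse(self, example_scheme, tmp_path):
        # parse(serialize(parse(f))) == parse(f) and byte identity
        path = tmp_path / "x.bio"
        path.write_text(EXAMPLE_BIO_TEXT, encoding="utf-8")
        c = read_bio_corpus(path, example_scheme)
        assert corpus_to_text(c) == EXAMPLE_BIO_TEXT
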
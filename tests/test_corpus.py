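"""Corpus data model, TSV I/O, dedup, splitting, vocabulary, encoding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemnmt.corpus import (
    CharVocabulary,
    CorpusError,
    NamePair,
    OOVError,
    ParallelCorpus,
    build_vocabulary,
    deduplicate,
    encode_batch,
    read_parallel_tsv,
    split_corpus,
    write_parallel_tsv,
)


def _corpus(rows, direction="En2Ch"):
    return ParallelCorpus(
        [NamePair(s, t, frozenset(a), direction=direction) for s, t, *a in rows],
        direction,
    )


class TestReadTsv:
    def test_basic_pair(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("ethyl acetate\t乙酸乙酯\n", encoding="utf-8")
        corpus = read_parallel_tsv(p, "En2Ch")
        assert len(corpus) == 1
        assert corpus[0].source_name == "ethyl acetate"
        assert corpus[0].target_name == "乙酸乙酯"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("", encoding="utf-8")
        assert len(read_parallel_tsv(p, "En2Ch")) == 0

    def test_alt_targets_and_tag(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("p-toluene\t对甲苯\tp-甲苯\nmethanol\t甲醇\t\tIUPAC\n", encoding="utf-8")
        corpus = read_parallel_tsv(p, "En2Ch")
        assert corpus[0].alt_targets == frozenset({"p-甲苯"})
        assert corpus[1].naming_system == "IUPAC"

    def test_short_line_names_lineno(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("a\tb\nonly-one-column\n", encoding="utf-8")
        with pytest.raises(CorpusError, match=":2"):
            read_parallel_tsv(p, "En2Ch")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_parallel_tsv(tmp_path / "nope.tsv", "En2Ch")

    def test_write_read_round_trip(self, tmp_path, small_corpus):
        p = tmp_path / "c.tsv"
        write_parallel_tsv(small_corpus, p)
        back = read_parallel_tsv(p, small_corpus.direction)
        assert list(back) == list(small_corpus)

    def test_nfc_normalization(self, tmp_path):
        # e + combining acute vs precomposed é must compare equal after read
        p = tmp_path / "c.tsv"
        p.write_text("cafféine\t咖啡因\n", encoding="utf-8")
        corpus = read_parallel_tsv(p, "En2Ch")
        assert corpus[0].source_name == "cafféine"


class TestNamePair:
    def test_empty_name_rejected(self):
        with pytest.raises(CorpusError):
            NamePair("  ", "甲醇")

    def test_primary_removed_from_alts(self):
        p = NamePair("methanol", "甲醇", frozenset({"甲醇", "木醇"}))
        assert p.alt_targets == frozenset({"木醇"})

    def test_direction_mismatch_rejected(self):
        with pytest.raises(CorpusError):
            ParallelCorpus([NamePair("a", "b", direction="Ch2En")], "En2Ch")


class TestDeduplicate:
    def test_exact_duplicate_dropped(self):
        c = deduplicate(_corpus([("a", "b"), ("a", "b")]))
        assert len(c) == 1

    def test_different_targets_kept(self):
        c = deduplicate(_corpus([("a", "b"), ("a", "c")]))
        assert len(c) == 2

    def test_alt_targets_merged_into_survivor(self):
        c = deduplicate(_corpus([("a", "b", "x"), ("a", "b", "y")]))
        assert c[0].alt_targets == frozenset({"x", "y"})

    def test_idempotent(self, small_corpus):
        doubled = ParallelCorpus(
            list(small_corpus) + list(small_corpus), small_corpus.direction
        )
        once = deduplicate(doubled)
        assert list(deduplicate(once)) == list(once)


class TestSplit:
    @pytest.mark.parametrize(
        "n,frac,expected_test",
        [(30394, 0.2, 6079), (37207, 0.2, 7441), (10, 0.2, 2)],
    )
    def test_exact_test_size(self, n, frac, expected_test):
        """The held-out partition has exactly round(n * fraction) pairs."""
        pairs = [NamePair(f"s{i}", f"t{i}") for i in range(n)]
        corpus = ParallelCorpus(pairs)
        train, test = split_corpus(corpus, frac, seed=0)
        assert len(test) == expected_test
        assert len(train) + len(test) == n

    def test_deterministic_and_disjoint(self, small_corpus):
        a = split_corpus(small_corpus, 0.2, seed=3)
        b = split_corpus(small_corpus, 0.2, seed=3)
        assert [p.source_name for p in a[1]] == [p.source_name for p in b[1]]
        train_sources = {p.source_name for p in a[0]}
        test_sources = {p.source_name for p in a[1]}
        assert not train_sources & test_sources

    def test_seed_changes_partition(self, small_corpus):
        _, t1 = split_corpus(small_corpus, 0.2, seed=1)
        _, t2 = split_corpus(small_corpus, 0.2, seed=2)
        assert [p.source_name for p in t1] != [p.source_name for p in t2]

    def test_bad_fraction(self, small_corpus):
        with pytest.raises(ValueError):
            split_corpus(small_corpus, 1.5, seed=0)


class TestVocabulary:
    def test_sorted_unique_chars(self):
        v = build_vocabulary(_corpus([("ab", "xy"), ("ba", "yx")]))
        assert v.source_chars == ("a", "b")
        assert v.target_chars == ("x", "y")

    def test_alt_targets_contribute_characters(self):
        v = build_vocabulary(_corpus([("ab", "xy", "z")]))
        assert "z" in v.target_chars

    def test_order_insensitive(self, small_corpus):
        shuffled = ParallelCorpus(
            list(reversed(small_corpus.pairs)), small_corpus.direction
        )
        assert build_vocabulary(small_corpus) == build_vocabulary(shuffled)

    def test_empty_corpus_rejected(self):
        with pytest.raises(CorpusError):
            build_vocabulary(ParallelCorpus([], "En2Ch"))

    def test_json_round_trip(self, vocab3000):
        assert CharVocabulary.from_json(vocab3000.to_json()) == vocab3000

    def test_reserved_symbols_at_final_indices(self, vocab3000):
        assert vocab3000.pad_tgt == vocab3000.n_target - 3
        assert vocab3000.sos_tgt == vocab3000.n_target - 2
        assert vocab3000.eos_tgt == vocab3000.n_target - 1


class TestEncodeBatch:
    def test_teacher_forcing_offset(self):
        corpus = _corpus([("ab", "XY")])
        v = build_vocabulary(corpus)
        b = encode_batch(corpus.pairs, v, 4, 4)
        assert b.decoder_input[0, 0] == v.sos_tgt
        # decoder_input shifted left equals decoder_target on real positions
        assert b.decoder_input[0, 1] == b.decoder_target[0, 0]
        assert b.decoder_input[0, 2] == b.decoder_target[0, 1]
        assert b.decoder_target[0, 2] == v.eos_tgt

    def test_shift_invariant_holds_everywhere(self, small_corpus, vocab3000):
        max_s = max(len(p.source_name) for p in small_corpus)
        max_t = max(len(p.target_name) for p in small_corpus)
        b = encode_batch(small_corpus.pairs, vocab3000, max_s, max_t)
        pad = vocab3000.pad_tgt
        live = (b.decoder_target[:, :-1] != pad) & (
            b.decoder_target[:, :-1] != vocab3000.eos_tgt
        )
        assert (b.decoder_input[:, 1:][live] == b.decoder_target[:, :-1][live]).all()

    def test_round_trip_decoding(self, small_corpus, vocab3000):
        max_s = max(len(p.source_name) for p in small_corpus)
        max_t = max(len(p.target_name) for p in small_corpus)
        b = encode_batch(small_corpus.pairs, vocab3000, max_s, max_t)
        for i, p in enumerate(small_corpus):
            assert vocab3000.decode_source(b.encoder_input[i]) == p.source_name
            assert vocab3000.decode_target(b.decoder_target[i]) == p.target_name

    def test_oov_character_error_names_offender(self, vocab3000):
        pair = NamePair("Ωmethanol", "甲醇")
        with pytest.raises(OOVError, match="Ω"):
            encode_batch([pair], vocab3000, 20, 20)


@settings(derandomize=True, max_examples=50)
@given(
    rows=st.lists(
        st.tuples(st.text("abc", min_size=1, max_size=4), st.text("xyz", min_size=1, max_size=4)),
        min_size=1,
        max_size=10,
    )
)
def test_dedup_idempotent_property(rows):
    corpus = _corpus(rows)
    once = deduplicate(corpus)
    assert list(deduplicate(once)) == list(once)
    keys = [(p.source_name, p.target_name) for p in once]
    assert len(keys) == len(set(keys))
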
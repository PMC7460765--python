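"""Parallel corpora of chemical name pairs.

A corpus is an ordered list of :class:`NamePair` records, all sharing one
translation direction (``En2Ch`` or ``Ch2En``).  Each pair carries one
primary reference translation and an optional set of accepted alternative
translations, because a chemical name frequently has more than one
conventional rendering in the other language ("p-toluene" is 对甲苯 but
p-甲苯 is also accepted).  This module provides tab-separated I/O,
deduplication, deterministic train/test splitting, character-vocabulary
construction, and the integer tensor encoding used for teacher-forced
seq2seq training.

All strings are normalized to Unicode NFC on construction so that
full-width/half-width punctuation and combining marks compare stably.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

DIRECTIONS = ("En2Ch", "Ch2En")
NAMING_SYSTEMS = ("IUPAC", "CAS", "trivial", "unknown")

# Reserved symbols from the Unicode private-use area: chemical names never
# contain them, so corpus text can never collide with the control symbols.
PAD = ""
SOS = ""
EOS = ""
RESERVED = (PAD, SOS, EOS)


class CorpusError(ValueError):
    """Malformed corpus input (bad line, bad direction, empty corpus)."""


class OOVError(KeyError):
    """A string contains a character absent from the vocabulary."""

    def __init__(self, char: str, where: str):
        super().__init__(f"out-of-vocabulary character {char!r} in {where!r}")
        self.char = char
        self.where = where


def normalize(text: str) -> str:
    return unicodedata.normalize("NFC", text).strip()


@dataclass(frozen=True)
class NamePair:
    """One source name with its reference translation(s)."""

    source_name: str
    target_name: str
    alt_targets: frozenset[str] = frozenset()
    naming_system: str = "unknown"
    direction: str = "En2Ch"

    def __post_init__(self):
        object.__setattr__(self, "source_name", normalize(self.source_name))
        object.__setattr__(self, "target_name", normalize(self.target_name))
        alts = frozenset(normalize(a) for a in self.alt_targets) - {self.target_name, ""}
        object.__setattr__(self, "alt_targets", alts)
        if not self.source_name or not self.target_name:
            raise CorpusError("source and target names must be non-empty")
        if self.naming_system not in NAMING_SYSTEMS:
            raise CorpusError(f"unknown naming system tag {self.naming_system!r}")
        if self.direction not in DIRECTIONS:
            raise CorpusError(f"unknown direction {self.direction!r}")

    @property
    def references(self) -> frozenset[str]:
        """All accepted translations: primary plus alternatives."""
        return self.alt_targets | {self.target_name}


@dataclass
class ParallelCorpus:
    """Ordered list of name pairs sharing one translation direction."""

    pairs: list[NamePair]
    direction: str = "En2Ch"

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise CorpusError(f"unknown direction {self.direction!r}")
        for p in self.pairs:
            if p.direction != self.direction:
                raise CorpusError(
                    f"pair direction {p.direction} does not match corpus {self.direction}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[NamePair]:
        return iter(self.pairs)

    def __getitem__(self, i) -> NamePair:
        return self.pairs[i]

    def source_characters(self) -> list[str]:
        chars: set[str] = set()
        for p in self.pairs:
            chars.update(p.source_name)
        return sorted(chars)

    def target_characters(self) -> list[str]:
        chars: set[str] = set()
        for p in self.pairs:
            chars.update(p.target_name)
            for a in p.alt_targets:
                chars.update(a)
        return sorted(chars)

    def stats(self) -> dict:
        """Record count and per-language unique character counts."""
        return {
            "direction": self.direction,
            "n_pairs": len(self.pairs),
            "n_unique_source_chars": len(self.source_characters()),
            "n_unique_target_chars": len(self.target_characters()),
        }


def read_parallel_tsv(
    path: str | Path, direction: str, header: bool = False
) -> ParallelCorpus:
    """Read a UTF-8 TSV of (source, target[, alt..., tag]) into a corpus.

    Columns beyond the first two are treated as alternative translations,
    except that a trailing column equal to a naming-system tag (IUPAC, CAS,
    trivial, unknown) is read as the tag.  Blank lines are skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: list[NamePair] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise CorpusError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            extras = [c for c in cols[2:] if c.strip()]
            tag = "unknown"
            if extras and extras[-1] in NAMING_SYSTEMS:
                tag = extras.pop()
            pairs.append(
                NamePair(
                    source_name=cols[0],
                    target_name=cols[1],
                    alt_targets=frozenset(extras),
                    naming_system=tag,
                    direction=direction,
                )
            )
    return ParallelCorpus(pairs, direction)


def write_parallel_tsv(corpus: ParallelCorpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for p in corpus:
            cols = [p.source_name, p.target_name, *sorted(p.alt_targets)]
            if p.naming_system != "unknown":
                cols.append(p.naming_system)
            fh.write("\t".join(cols) + "\n")


def deduplicate(corpus: ParallelCorpus) -> ParallelCorpus:
    """Drop repeated (source, target) records, keeping first occurrences.

    Alternative translations of dropped duplicates are merged into the
    surviving record so the one-to-many translation information is kept.
    """
    survivors: dict[tuple[str, str], int] = {}
    out: list[NamePair] = []
    for p in corpus:
        key = (p.source_name, p.target_name)
        if key in survivors:
            i = survivors[key]
            merged = out[i].alt_targets | p.alt_targets
            if merged != out[i].alt_targets:
                out[i] = replace(out[i], alt_targets=merged)
        else:
            survivors[key] = len(out)
            out.append(p)
    return ParallelCorpus(out, corpus.direction)


def split_corpus(
    corpus: ParallelCorpus, test_fraction: float, seed: int
) -> tuple[ParallelCorpus, ParallelCorpus]:
    """Deterministic disjoint train/test partition.

    The test set has exactly ``round(n * test_fraction)`` pairs; the
    partition depends only on (corpus order, fraction, seed).  Within each
    side the original corpus order is preserved.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(corpus)
    n_test = round(n * test_fraction)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [p for i, p in enumerate(corpus) if i not in test_idx]
    test = [p for i, p in enumerate(corpus) if i in test_idx]
    return (
        ParallelCorpus(train, corpus.direction),
        ParallelCorpus(test, corpus.direction),
    )


@dataclass(frozen=True)
class CharVocabulary:
    """Character inventories for both languages with bijective index maps.

    Characters are ordered by code point so that a vocabulary (and hence
    all model shapes) is a reproducible function of the corpus content
    alone.  The reserved pad/start/end symbols occupy the three final
    indices on each side.
    """

    source_chars: tuple[str, ...]
    target_chars: tuple[str, ...]

    def __post_init__(self):
        for ch in RESERVED:
            if ch in self.source_chars or ch in self.target_chars:
                raise CorpusError("reserved symbol present in corpus text")

    # --- index maps -----------------------------------------------------
    @property
    def source_symbols(self) -> tuple[str, ...]:
        return self.source_chars + RESERVED

    @property
    def target_symbols(self) -> tuple[str, ...]:
        return self.target_chars + RESERVED

    @property
    def n_source(self) -> int:
        return len(self.source_symbols)

    @property
    def n_target(self) -> int:
        return len(self.target_symbols)

    def source_index(self, ch: str) -> int:
        try:
            return self._src_map[ch]
        except KeyError:
            raise OOVError(ch, "source side") from None

    def target_index(self, ch: str) -> int:
        try:
            return self._tgt_map[ch]
        except KeyError:
            raise OOVError(ch, "target side") from None

    @property
    def _src_map(self) -> dict[str, int]:
        m = self.__dict__.get("_src_map_cache")
        if m is None:
            m = {c: i for i, c in enumerate(self.source_symbols)}
            object.__setattr__(self, "_src_map_cache", m)
        return m

    @property
    def _tgt_map(self) -> dict[str, int]:
        m = self.__dict__.get("_tgt_map_cache")
        if m is None:
            m = {c: i for i, c in enumerate(self.target_symbols)}
            object.__setattr__(self, "_tgt_map_cache", m)
        return m

    # special indices
    @property
    def pad_src(self) -> int:
        return self.n_source - 3

    @property
    def pad_tgt(self) -> int:
        return self.n_target - 3

    @property
    def sos_tgt(self) -> int:
        return self.n_target - 2

    @property
    def eos_tgt(self) -> int:
        return self.n_target - 1

    # --- encoding helpers ----------------------------------------------
    def encode_source(self, text: str) -> list[int]:
        return [self.source_index(c) for c in text]

    def encode_target(self, text: str) -> list[int]:
        return [self.target_index(c) for c in text]

    def decode_target(self, ids: Iterable[int]) -> str:
        syms = self.target_symbols
        out = []
        for i in ids:
            ch = syms[i]
            if ch == EOS:
                break
            if ch not in (PAD, SOS):
                out.append(ch)
        return "".join(out)

    def decode_source(self, ids: Iterable[int]) -> str:
        syms = self.source_symbols
        return "".join(syms[i] for i in ids if syms[i] not in RESERVED)

    # --- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "source_chars": list(self.source_chars),
                "target_chars": list(self.target_chars),
                "reserved": {"pad": PAD, "sos": SOS, "eos": EOS},
            },
            ensure_ascii=False,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CharVocabulary":
        doc = json.loads(text)
        return cls(tuple(doc["source_chars"]), tuple(doc["target_chars"]))


def build_vocabulary(corpus: ParallelCorpus) -> CharVocabulary:
    """Character vocabulary over all source and target (incl. alt) strings."""
    if len(corpus) == 0:
        raise CorpusError("cannot build a vocabulary from an empty corpus")
    return CharVocabulary(
        tuple(corpus.source_characters()), tuple(corpus.target_characters())
    )


@dataclass
class EncodedBatch:
    """Integer tensors for teacher-forced training.

    ``decoder_input`` is the target prefixed with the start symbol;
    ``decoder_target`` is the target suffixed with the end symbol — i.e.
    the same sequence offset by one timestep, so at step t the decoder
    predicts ``decoder_target[t]`` from the true prefix
    ``decoder_input[:t+1]``.
    """

    encoder_input: np.ndarray  # (n, Ts) int32
    decoder_input: np.ndarray  # (n, Tt+1)
    decoder_target: np.ndarray  # (n, Tt+1)
    source_lengths: np.ndarray  # (n,)
    target_lengths: np.ndarray  # (n,) length incl. the EOS step

    def __len__(self) -> int:
        return self.encoder_input.shape[0]


def encode_batch(
    pairs: Sequence[NamePair],
    vocab: CharVocabulary,
    max_source_len: int,
    max_target_len: int,
) -> EncodedBatch:
    """Encode pairs into padded index matrices for teacher forcing.

    ``max_target_len`` counts target characters excluding SOS/EOS; the
    decoder matrices have one extra column for the shifted symbol.  Raises
    :class:`OOVError` naming the offending character and pair if any
    character is missing from the vocabulary.
    """
    n = len(pairs)
    enc = np.full((n, max_source_len), vocab.pad_src, dtype=np.int32)
    dec_in = np.full((n, max_target_len + 1), vocab.pad_tgt, dtype=np.int32)
    dec_tgt = np.full((n, max_target_len + 1), vocab.pad_tgt, dtype=np.int32)
    src_len = np.zeros(n, dtype=np.int32)
    tgt_len = np.zeros(n, dtype=np.int32)
    for i, p in enumerate(pairs):
        try:
            s = vocab.encode_source(p.source_name)
            t = vocab.encode_target(p.target_name)
        except OOVError as e:
            raise OOVError(e.char, f"pair {p.source_name!r} -> {p.target_name!r}") from None
        if len(s) > max_source_len or len(t) > max_target_len:
            raise CorpusError(
                f"pair {p.source_name!r} exceeds maximum lengths "
                f"({len(s)}>{max_source_len} or {len(t)}>{max_target_len})"
            )
        enc[i, : len(s)] = s
        dec_in[i, 0] = vocab.sos_tgt
        dec_in[i, 1 : len(t) + 1] = t
        dec_tgt[i, : len(t)] = t
        dec_tgt[i, len(t)] = vocab.eos_tgt
        src_len[i] = len(s)
        tgt_len[i] = len(t) + 1
    return EncodedBatch(enc, dec_in, dec_tgt, src_len, tgt_len)
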
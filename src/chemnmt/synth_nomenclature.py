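"""Seeded generator of paired English/Chinese chemical-style names.

A deliberately small nomenclature grammar (about forty morphemes: ten
chain stems, four halogens, benzene, a handful of suffixes and
multipliers) whose locant combinatorics nevertheless yield several
thousand distinct names, so corpora large enough to train the seq2seq
models can be generated without any external data.  The grammar
reproduces the string-level phenomena that make real chemical-name
translation hard:

* Chinese names have no word boundaries, English ones do;
* ester names reverse word order between languages
  (``ethyl acetate`` ↔ 乙酸乙酯);
* the hydroxyl suffix translates context-dependently — 醇 on aliphatic
  parents, 酚 on aromatic rings (``benzene-1,2,4-triol`` ↔ 苯-1,2,4-三酚);
* locants and their punctuation are copied verbatim between languages;
* a fraction of pairs carries alternative accepted translations, so
  string-matching and data-matching accuracy measurably diverge;
* esters can surface in an inverted "…ic acid, …yl ester" form, tagged
  CAS, while everything else is tagged IUPAC.

Chemical correctness of generated names (locant validity, substitution
feasibility) is not claimed; the generator targets string structure only.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .corpus import NamePair, ParallelCorpus

STEMS_EN = ("meth", "eth", "prop", "but", "pent", "hex", "hept", "oct", "non", "dec")
STEMS_CH = ("甲", "乙", "丙", "丁", "戊", "己", "庚", "辛", "壬", "癸")

HALO_EN = ("chloro", "bromo", "fluoro", "iodo")
HALO_CH = ("氯", "溴", "氟", "碘")

MULTIPLIERS_EN = {2: "di", 3: "tri"}
MULTIPLIERS_CH = {2: "二", 3: "三"}

PRODUCTION_KINDS = (
    "alkane",
    "alcohol",
    "amine",
    "acid",
    "ester",
    "aromatic_polyol",
    "diol",
)


class CapacityError(RuntimeError):
    """The grammar cannot yield the requested number of unique pairs."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"grammar exhausted: {achieved} unique pairs achievable, {requested} requested"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class GeneratedName:
    """One bilingual production with optional alternative renderings."""

    english: str
    chinese: str
    kind: str
    naming_system: str = "IUPAC"
    alt_english: tuple[str, ...] = ()
    alt_chinese: tuple[str, ...] = ()


def _substituent(j: int) -> tuple[str, str]:
    """Substituent j: 0-1 are methyl/ethyl, 2-5 the four halogens."""
    if j < 2:
        return STEMS_EN[j] + "yl", STEMS_CH[j] + "基"
    return HALO_EN[j - 2], HALO_CH[j - 2]


@dataclass(frozen=True)
class SyntheticGrammar:
    """Toy bilingual nomenclature grammar with a configured production mixture.

    ``production_weights`` is the categorical distribution over production
    families; ``p_alt`` the probability that a pair carries an alternative
    translation (where the production admits one); ``p_cas`` the
    probability that a simple ester surfaces in the inverted CAS comma
    form (English-source direction only).
    """

    production_weights: tuple[tuple[str, float], ...] = (
        ("alkane", 0.27),
        ("alcohol", 0.20),
        ("amine", 0.015),
        ("acid", 0.065),
        ("ester", 0.36),
        ("aromatic_polyol", 0.01),
        ("diol", 0.08),
    )
    p_alt: float = 0.10
    p_cas: float = 0.15
    direction: str = "En2Ch"
    seed: int = 0

    def __post_init__(self):
        kinds = [k for k, _ in self.production_weights]
        if sorted(kinds) != sorted(set(kinds)) or not set(kinds) <= set(PRODUCTION_KINDS):
            raise ValueError("production_weights must name distinct known kinds")
        if any(w < 0 for _, w in self.production_weights):
            raise ValueError("production weights must be non-negative")
        for p in (self.p_alt, self.p_cas):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    # --- serialization -------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "production_weights": [[k, w] for k, w in self.production_weights],
                "p_alt": self.p_alt,
                "p_cas": self.p_cas,
                "direction": self.direction,
                "seed": self.seed,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticGrammar":
        doc = yaml.safe_load(text)
        return cls(
            production_weights=tuple((k, float(w)) for k, w in doc["production_weights"]),
            p_alt=float(doc["p_alt"]),
            p_cas=float(doc["p_cas"]),
            direction=doc["direction"],
            seed=int(doc["seed"]),
        )

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:16]

    # ------------------------------------------------------------------
    # deterministic production constructors (stem indices are 1-based
    # chain lengths, mirroring the meth/eth/prop… series)
    # ------------------------------------------------------------------
    @staticmethod
    def _stem(i: int) -> tuple[str, str]:
        return STEMS_EN[i - 1], STEMS_CH[i - 1]

    @staticmethod
    def _acylate_en(i: int) -> str:
        # trivial acyl names for the two shortest chains, as in common usage
        if i == 1:
            return "formate"
        if i == 2:
            return "acetate"
        return STEMS_EN[i - 1] + "anoate"

    def make_alkane(self, i: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}ane", f"{c}烷", "alkane")

    def make_substituted_alkane(
        self, sub: int, parent: int, locants: tuple[int, ...]
    ) -> GeneratedName:
        se, sc = _substituent(sub)
        pe, pc = self._stem(parent)
        locs = ",".join(str(l) for l in locants)
        mult_en = MULTIPLIERS_EN.get(len(locants), "")
        mult_ch = MULTIPLIERS_CH.get(len(locants), "")
        return GeneratedName(
            f"{locs}-{mult_en}{se}{pe}ane", f"{locs}-{mult_ch}{sc}{pc}烷", "alkane"
        )

    def make_alcohol(self, i: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}anol", f"{c}醇", "alcohol")

    def make_positional_alcohol(self, i: int, loc: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}an-{loc}-ol", f"{c}-{loc}-醇", "alcohol")

    def make_substituted_alcohol(
        self, sub: int, parent: int, l1: int, l2: int
    ) -> GeneratedName:
        """Substituted alcohol, e.g. 2-methylhexan-1-ol ↔ 2-甲基己-1-醇."""
        se, sc = _substituent(sub)
        pe, pc = self._stem(parent)
        english = f"{l1}-{se}{pe}an-{l2}-ol"
        chinese = f"{l1}-{sc}{pc}-{l2}-醇"
        alt_ch = (f"{l1}-{sc.rstrip('基')}{pc}-{l2}-醇",) if sc.endswith("基") else ()
        return GeneratedName(
            english,
            chinese,
            "alcohol",
            alt_english=(f"{l1}-{se}-{pe}an-{l2}-ol",),
            alt_chinese=alt_ch,
        )

    def make_amine(self, i: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}ylamine", f"{c}胺", "amine")

    def make_positional_amine(self, i: int, loc: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}an-{loc}-amine", f"{c}-{loc}-胺", "amine")

    def make_acid(self, i: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(f"{e}anoic acid", f"{c}酸", "acid")

    def make_substituted_acid(self, sub: int, parent: int, loc: int) -> GeneratedName:
        se, sc = _substituent(sub)
        pe, pc = self._stem(parent)
        return GeneratedName(
            f"{loc}-{se}{pe}anoic acid", f"{loc}-{sc}{pc}酸", "acid"
        )

    def make_ester(self, acyl: int, alkyl: int, cas_form: bool = False) -> GeneratedName:
        """Ester of acid chain ``acyl`` with alcohol chain ``alkyl``.

        The English IUPAC form puts the alkyl group first, the Chinese the
        acid first — the word-order reversal that defeats word-by-word
        translation.
        """
        ae, ac = self._stem(acyl)
        ke, kc = self._stem(alkyl)
        chinese = f"{ac}酸{kc}酯"
        alt_ch = (f"{ac}酸{kc}基酯",)
        if cas_form:
            english = f"{ae}anoic acid, {ke}yl ester"
            return GeneratedName(
                english, chinese, "ester", naming_system="CAS", alt_chinese=alt_ch
            )
        english = f"{ke}yl {self._acylate_en(acyl)}"
        alt_en = (f"{ae}anoic acid, {ke}yl ester",)
        return GeneratedName(
            english, chinese, "ester", alt_english=alt_en, alt_chinese=alt_ch
        )

    def make_halo_ester(
        self, halo: int, acyl: int, loc: int, alkyl: int
    ) -> GeneratedName:
        """Halogen-substituted ester, e.g. ethyl 2-chlorohexanoate ↔ 2-氯己酸乙酯."""
        he, hc = HALO_EN[halo], HALO_CH[halo]
        ae, ac = self._stem(acyl)
        ke, kc = self._stem(alkyl)
        english = f"{ke}yl {loc}-{he}{ae}anoate"
        chinese = f"{loc}-{hc}{ac}酸{kc}酯"
        return GeneratedName(
            english, chinese, "ester", alt_chinese=(f"{loc}-{hc}{ac}酸{kc}基酯",)
        )

    def make_aromatic_polyol(self, locants: tuple[int, ...]) -> GeneratedName:
        """Hydroxyls on a benzene ring: the suffix becomes 酚, not 醇."""
        m = len(locants)
        if m not in MULTIPLIERS_EN:
            raise ValueError("aromatic polyol takes 2 or 3 locants")
        locs = ",".join(str(l) for l in locants)
        return GeneratedName(
            f"benzene-{locs}-{MULTIPLIERS_EN[m]}ol",
            f"苯-{locs}-{MULTIPLIERS_CH[m]}酚",
            "aromatic_polyol",
        )

    def make_diol(self, i: int, l1: int, l2: int) -> GeneratedName:
        e, c = self._stem(i)
        return GeneratedName(
            f"{e}ane-{l1},{l2}-diol", f"{c}烷-{l1},{l2}-二醇", "diol"
        )

    # ------------------------------------------------------------------
    def sample(self, rng: np.random.Generator) -> GeneratedName:
        kinds = [k for k, _ in self.production_weights]
        weights = np.array([w for _, w in self.production_weights], dtype=float)
        kind = kinds[int(rng.choice(len(kinds), p=weights / weights.sum()))]
        stem = lambda: int(rng.integers(1, 11))
        parent = lambda: int(rng.integers(3, 11))
        sub = lambda: int(rng.integers(0, 6))
        halo = lambda: int(rng.integers(0, 4))
        loc = lambda lo=2, hi=8: int(rng.integers(lo, hi))
        if kind == "alkane":
            u = rng.random()
            if u < 0.02:
                return self.make_alkane(stem())
            if u < 0.45:
                return self.make_substituted_alkane(sub(), parent(), (loc(),))
            m = int(rng.integers(2, 4))
            locants = tuple(sorted(rng.choice(np.arange(1, 7), size=m, replace=False).tolist()))
            return self.make_substituted_alkane(sub(), parent(), locants)
        if kind == "alcohol":
            u = rng.random()
            if u < 0.02:
                return self.make_alcohol(stem())
            if u < 0.10:
                return self.make_positional_alcohol(parent(), loc(1, 7))
            return self.make_substituted_alcohol(
                sub(), parent(), loc(), int(rng.integers(1, 4))
            )
        if kind == "amine":
            if rng.random() < 0.2:
                return self.make_amine(stem())
            return self.make_positional_amine(parent(), loc(1, 7))
        if kind == "acid":
            if rng.random() < 0.05:
                return self.make_acid(stem())
            return self.make_substituted_acid(sub(), parent(), loc())
        if kind == "ester":
            if rng.random() < 0.10:
                cas = self.direction == "En2Ch" and rng.random() < self.p_cas
                return self.make_ester(stem(), stem(), cas_form=cas)
            return self.make_halo_ester(halo(), parent(), loc(), stem())
        if kind == "aromatic_polyol":
            m = int(rng.integers(2, 4))
            locants = tuple(sorted(rng.choice(np.arange(1, 7), size=m, replace=False).tolist()))
            return self.make_aromatic_polyol(locants)
        if kind == "diol":
            i = stem()
            l1, l2 = sorted(rng.choice(np.arange(1, 10), size=2, replace=False).tolist())
            return self.make_diol(i, l1, l2)
        raise AssertionError(kind)


def generate_pair(grammar: SyntheticGrammar, rng: np.random.Generator) -> NamePair:
    """Draw one grammatical bilingual pair in the grammar's direction."""
    prod = grammar.sample(rng)
    attach_alt = rng.random() < grammar.p_alt
    if grammar.direction == "En2Ch":
        source, target = prod.english, prod.chinese
        alts = frozenset(prod.alt_chinese) if attach_alt else frozenset()
    else:
        source, target = prod.chinese, prod.english
        alts = frozenset(prod.alt_english) if attach_alt else frozenset()
    return NamePair(
        source_name=source,
        target_name=target,
        alt_targets=alts,
        naming_system=prod.naming_system,
        direction=grammar.direction,
    )


def generate_corpus(
    grammar: SyntheticGrammar, n: int, seed: int | None = None
) -> ParallelCorpus:
    """Generate ``n`` unique pairs, deterministic in (grammar, n, seed).

    Duplicate (source, target) draws are rejected and re-drawn up to an
    attempt cap; if the grammar is too small to supply ``n`` unique pairs
    a :class:`CapacityError` reports the achievable count.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if seed is None:
        seed = grammar.seed
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, str]] = set()
    pairs: list[NamePair] = []
    attempts = 0
    cap = 200 * n + 1000
    while len(pairs) < n:
        attempts += 1
        if attempts > cap:
            raise CapacityError(n, len(pairs))
        p = generate_pair(grammar, rng)
        key = (p.source_name, p.target_name)
        if key in seen:
            continue
        seen.add(key)
        pairs.append(p)
    return ParallelCorpus(pairs, grammar.direction)


def production_fractions(corpus: ParallelCorpus) -> dict[str, float]:
    """Empirical production-family mixture of a corpus, keyed by kind.

    Classification is by Chinese surface form (ester marker 酯, aromatic
    苯, diol 二醇, …) and is exact for generator output.
    """
    counts = dict.fromkeys(PRODUCTION_KINDS, 0)
    for p in corpus:
        ch = p.target_name if p.direction == "En2Ch" else p.source_name
        if "酯" in ch:
            kind = "ester"
        elif "苯" in ch:
            kind = "aromatic_polyol"
        elif "二醇" in ch:
            kind = "diol"
        elif ch.endswith("烷"):
            kind = "alkane"
        elif ch.endswith("醇"):
            kind = "alcohol"
        elif ch.endswith("胺"):
            kind = "amine"
        elif ch.endswith("酸"):
            kind = "acid"
        else:
            kind = "aromatic_polyol"
        counts[kind] += 1
    n = max(len(corpus), 1)
    return {k: v / n for k, v in counts.items()}


def reverse_direction(corpus: ParallelCorpus) -> ParallelCorpus:
    """Swap source and target names and flip the direction tag.

    Name translation is not symmetric — a reference English→Chinese pair
    is not automatically a good Chinese→English training record (β-苯乙醇
    back-translates more naturally as "β-phenylethyl alcohol" than as the
    original "β-phenethylol") — so a warning is emitted whenever a corpus
    is reversed rather than natively compiled.  Alternative translations
    are carried along unchanged; after reversal they are alternative
    renderings of the new *source* side.
    """
    new_dir = "Ch2En" if corpus.direction == "En2Ch" else "En2Ch"
    warnings.warn(
        "Reversing a parallel corpus: chemical-name translation is not "
        "symmetric; a reversed corpus may be unsuitable for training the "
        "opposite direction.",
        UserWarning,
        stacklevel=2,
    )
    pairs = [
        NamePair(
            source_name=p.target_name,
            target_name=p.source_name,
            alt_targets=p.alt_targets,
            naming_system=p.naming_system,
            direction=new_dir,
        )
        for p in corpus
    ]
    return ParallelCorpus(pairs, new_dir)
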
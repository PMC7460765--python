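"""Rule-based chemical name translation: disassembly → translation → reassembly.

The baseline translator works in three stages over an editable rule set:

1. **Segmentation (disassembly)** — greedy longest-match, leftmost-first
   over a fragment lexicon.  Chinese names carry no word boundaries, so
   segmentation is where such systems most often fail; an input with an
   unmatched position is reported uncovered, not raised.
2. **Fragment translation** — each (fragment, role) is looked up in a
   dictionary, optionally context-sensitive: an aromatic parent anywhere
   in the name switches hydroxyl suffixes from 醇 to 酚, and an ester
   marker switches alkyl substituents to their ester reading.
3. **Reassembly** — the first matching reorder template rewrites the role
   sequence (esters swap acyl/alkyl order between the two languages);
   otherwise fragments are emitted in input order.

Failures at any stage become :class:`TranslationResult` values with the
stage named, so downstream evaluation can attribute error causes.  A demo
rule set per direction ships with the package
(``chemnmt/data/rules_en2ch.yaml`` and ``rules_ch2en.yaml``); it encodes
the same toy nomenclature as :mod:`chemnmt.synth_nomenclature` and makes
no claim of covering real-world corpora.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .corpus import normalize
from .results import TranslationResult

ROLES = (
    "parent",
    "substituent",
    "suffix",
    "ester_acyl",
    "ester_alkyl",
    "locant",
    "punctuation",
    "multiplier",
)

_LOCANT_RE = re.compile(r"[0-9]+(?:,[0-9]+)*")


class RuleSetError(ValueError):
    """Malformed rule-set document."""


class FragmentLookupError(KeyError):
    """A segmented fragment has no dictionary entry."""

    def __init__(self, fragment: str, role: str, context: str):
        super().__init__(
            f"no dictionary entry for fragment {fragment!r} (role={role}, context={context})"
        )
        self.fragment = fragment
        self.role = role
        self.context = context


@dataclass(frozen=True)
class Template:
    """Reorder rule: a role sequence pattern and its output recipe.

    ``match`` is compared against the non-punctuation role sequence of a
    segmentation.  ``output`` items are either integer indices into the
    matched fragments or literal strings to splice in.
    """

    match: tuple[str, ...]
    output: tuple[int | str, ...]


@dataclass
class RuleSet:
    """Lexicon, context-sensitive fragment dictionary and reorder templates."""

    direction: str
    lexicon: list[tuple[str, str]]  # (fragment text, role), declaration order = priority
    dictionary: dict[tuple[str, str, str], str]  # (text, role, context) -> translation
    templates: list[Template] = field(default_factory=list)
    aromatic_parents: frozenset[str] = frozenset()
    ester_triggers: frozenset[str] = frozenset()
    builtin_locants: bool = True

    def __post_init__(self):
        roles_by_text: dict[str, list[str]] = {}
        for text, role in self.lexicon:
            if not text:
                raise RuleSetError("lexicon fragments must be non-empty")
            if role not in ROLES:
                raise RuleSetError(f"unknown role {role!r} for fragment {text!r}")
            roles_by_text.setdefault(text, []).append(role)
        for (text, role, context) in self.dictionary:
            if role not in ROLES:
                raise RuleSetError(f"dictionary entry with unknown role {role!r}")
            if context not in ("default", "aromatic", "ester"):
                raise RuleSetError(f"unknown context {context!r}")
        for text, role in self.lexicon:
            if not any(k[0] == text and k[1] == role for k in self.dictionary):
                raise RuleSetError(f"lexicon entry ({text!r}, {role}) has no dictionary entry")
        for t in self.templates:
            if not set(t.match) <= set(ROLES):
                raise RuleSetError(f"template references undeclared roles: {t.match}")
        # longest-match index: texts sorted by length desc, ties by declaration
        self._by_prefix = sorted(
            range(len(self.lexicon)),
            key=lambda i: (-len(self.lexicon[i][0]), i),
        )

    def lookup(self, text: str, role: str, context: str) -> str:
        for ctx in (context, "default"):
            key = (text, role, ctx)
            if key in self.dictionary:
                return self.dictionary[key]
        raise FragmentLookupError(text, role, context)


@dataclass(frozen=True)
class Segmentation:
    """Disassembly of one name into (text, role) fragments."""

    input: str
    fragments: tuple[tuple[str, str], ...]
    covered: bool


def load_rules(path: str | Path) -> RuleSet:
    """Load a rule set from its YAML document."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return _rules_from_dict(doc)


def demo_rules(direction: str) -> RuleSet:
    """The packaged demonstration rule set for one direction."""
    fname = {"En2Ch": "rules_en2ch.yaml", "Ch2En": "rules_ch2en.yaml"}[direction]
    text = resources.files("chemnmt").joinpath("data", fname).read_text(encoding="utf-8")
    return _rules_from_dict(yaml.safe_load(text))


def _rules_from_dict(doc: dict) -> RuleSet:
    try:
        lexicon = [(e["text"], e["role"]) for e in doc["lexicon"]]
        dictionary = {
            (e["text"], e["role"], e.get("context", "default")): e["translation"]
            for e in doc["dictionary"]
        }
        templates = [
            Template(tuple(t["match"]), tuple(t["output"]))
            for t in doc.get("templates", [])
        ]
    except (KeyError, TypeError) as e:
        raise RuleSetError(f"malformed rule set document: {e}") from e
    return RuleSet(
        direction=doc.get("direction", "En2Ch"),
        lexicon=lexicon,
        dictionary=dictionary,
        templates=templates,
        aromatic_parents=frozenset(doc.get("aromatic_parents", [])),
        ester_triggers=frozenset(doc.get("ester_triggers", [])),
        builtin_locants=bool(doc.get("builtin_locants", True)),
    )


def segment(name: str, rules: RuleSet) -> Segmentation:
    """Greedy longest-match, leftmost-first disassembly.

    At each position the longest lexicon fragment (declaration order breaks
    length ties between roles) or, when enabled, a maximal locant run
    (digits and commas, e.g. ``1,2,4``) is consumed.  An unmatched
    position yields ``covered=False`` with the fragments found so far.
    """
    name = normalize(name)
    fragments: list[tuple[str, str]] = []
    i = 0
    n = len(name)
    while i < n:
        if rules.builtin_locants and name[i].isdigit():
            m = _LOCANT_RE.match(name, i)
            assert m is not None
            fragments.append((m.group(), "locant"))
            i = m.end()
            continue
        best: tuple[str, str] | None = None
        for idx in rules._by_prefix:
            text, role = rules.lexicon[idx]
            if name.startswith(text, i):
                best = (text, role)
                break
        if best is None:
            return Segmentation(name, tuple(fragments), False)
        fragments.append(best)
        i += len(best[0])
    return Segmentation(name, tuple(fragments), True)


def _contexts(seg: Segmentation, rules: RuleSet) -> tuple[bool, bool]:
    texts = {t for t, _ in seg.fragments}
    aromatic = bool(texts & rules.aromatic_parents)
    ester = bool(texts & rules.ester_triggers)
    return aromatic, ester


def translate_fragments(seg: Segmentation, rules: RuleSet) -> list[tuple[str, str]]:
    """Map each fragment through the dictionary under the name's context.

    Context precedence per fragment: ester override, then aromatic
    override, then the default entry.  Locants pass through verbatim.
    Raises :class:`FragmentLookupError` on a missing entry.
    """
    if not seg.covered:
        raise ValueError("cannot translate an uncovered segmentation")
    aromatic, ester = _contexts(seg, rules)
    out: list[tuple[str, str]] = []
    for text, role in seg.fragments:
        if role == "locant":
            out.append((text, role))
            continue
        translated: str | None = None
        if ester:
            translated = rules.dictionary.get((text, role, "ester"))
        if translated is None and aromatic:
            translated = rules.dictionary.get((text, role, "aromatic"))
        if translated is None:
            translated = rules.dictionary.get((text, role, "default"))
        if translated is None:
            ctx = "ester" if ester else ("aromatic" if aromatic else "default")
            raise FragmentLookupError(text, role, ctx)
        out.append((translated, role))
    return out


def reassemble(translated: list[tuple[str, str]], rules: RuleSet) -> str:
    """Apply the first matching reorder template, else keep input order.

    Template patterns are matched against the sequence of non-punctuation
    roles; when a template applies, punctuation fragments are dropped and
    the template's literals supply target-language separators.  With no
    match, fragments are concatenated in order (the fragment dictionary
    supplies any separators, e.g. the English space or the empty Chinese
    boundary).
    """
    content = [(t, r) for t, r in translated if r != "punctuation"]
    roles = tuple(r for _, r in content)
    for tpl in rules.templates:
        if roles == tpl.match:
            parts: list[str] = []
            for item in tpl.output:
                parts.append(content[item][0] if isinstance(item, int) else item)
            return "".join(parts)
    return "".join(t for t, _ in translated)


def rule_translate(name: str, rules: RuleSet) -> TranslationResult:
    """Full three-stage translation of one name; failures are values."""
    seg = segment(name, rules)
    if not seg.covered:
        return TranslationResult(
            input=normalize(name), succeeded=False, failure_stage="segmentation"
        )
    try:
        translated = translate_fragments(seg, rules)
    except FragmentLookupError:
        return TranslationResult(
            input=seg.input, succeeded=False, failure_stage="dictionary"
        )
    return TranslationResult(input=seg.input, output=reassemble(translated, rules))


def translate_file(
    names: list[str], rules: RuleSet
) -> list[TranslationResult]:
    """Batch mode: translate a list of names, one result per name."""
    return [rule_translate(n, rules) for n in names if n.strip()]
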
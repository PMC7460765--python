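"""Translation quality metrics for chemical nomenclature.

Three headline figures, all with the full input count as denominator
(a failed translation can never match, so failures lower every metric):

* **success rate** — fraction of inputs for which any output was produced;
* **string matching accuracy** — exact match against the single primary
  reference translation (after NFC normalization and trimming,
  case-sensitive);
* **data matching accuracy** — exact match against the full accepted set,
  primary plus alternative translations; since the accepted set contains
  the primary, data match ≥ string match always.

Also provided: stratified reports (by naming system tag or by
Chinese-name length, with 6 characters as the conventional demarcation)
and blinded spot-check sampling, which withholds system identity into a
separate key table so a human checker cannot tell which system produced
which output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corpus import NamePair, normalize
from .results import TranslationResult

LENGTH_DEMARCATION = 6  # Chinese characters


@dataclass(frozen=True)
class EvaluationReport:
    """Counts and rates for one result set (plus optional strata)."""

    n_total: int
    n_succeeded: int
    n_string_match: int
    n_data_match: int
    strata: tuple[tuple[str, str, "EvaluationReport"], ...] = ()
    notes: tuple[str, ...] = (
        "denominator includes failed translations",
        "comparison is exact string match after NFC normalization",
    )

    def __post_init__(self):
        if not (
            0 <= self.n_string_match <= self.n_data_match <= self.n_succeeded <= self.n_total
        ):
            raise ValueError(
                "metric counts must satisfy string <= data <= succeeded <= total"
            )

    @property
    def success_rate(self) -> float:
        return self.n_succeeded / self.n_total if self.n_total else 0.0

    @property
    def string_match_accuracy(self) -> float:
        return self.n_string_match / self.n_total if self.n_total else 0.0

    @property
    def data_match_accuracy(self) -> float:
        return self.n_data_match / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        d = {
            "n_total": self.n_total,
            "n_succeeded": self.n_succeeded,
            "n_string_match": self.n_string_match,
            "n_data_match": self.n_data_match,
            "success_rate": self.success_rate,
            "string_match_accuracy": self.string_match_accuracy,
            "data_match_accuracy": self.data_match_accuracy,
            "notes": list(self.notes),
        }
        if self.strata:
            d["strata"] = [
                {"label": label, "predicate": desc, **rep.to_dict()}
                for label, desc, rep in self.strata
            ]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), ensure_ascii=False, indent=1)

    def to_table(self) -> str:
        """Plain-text table with the conventional field names."""
        rows = [
            ("Success Rate", self.success_rate),
            ("String Matching Accuracy", self.string_match_accuracy),
            ("Data Matching Accuracy", self.data_match_accuracy),
        ]
        lines = [f"{name:<28s}{100 * value:6.2f}%  (n={self.n_total})" for name, value in rows]
        for label, _, rep in self.strata:
            lines.append(f"[{label}]")
            lines.extend("  " + l for l in rep.to_table().splitlines())
        return "\n".join(lines)


def evaluate(
    results: list[TranslationResult],
    references: list[NamePair],
    strata: dict[str, list[int]] | None = None,
) -> EvaluationReport:
    """Score results against their aligned reference pairs.

    ``results[i]`` must carry the same input name as ``references[i]``;
    misalignment is an error, not a silent zero.  Optional ``strata``
    (label → row indices, e.g. from :func:`stratify`) add per-stratum
    sub-reports.
    """
    if len(results) != len(references):
        raise ValueError(
            f"results ({len(results)}) and references ({len(references)}) differ in length"
        )
    for i, (res, ref) in enumerate(zip(results, references)):
        if normalize(res.input) != ref.source_name:
            raise ValueError(
                f"row {i}: result input {res.input!r} does not match reference "
                f"source {ref.source_name!r}"
            )
    def count(indices) -> tuple[int, int, int, int]:
        n = n_succ = n_str = n_data = 0
        for i in indices:
            res, ref = results[i], references[i]
            n += 1
            if not res.succeeded:
                continue
            n_succ += 1
            out = normalize(res.output)
            if out == ref.target_name:
                n_str += 1
            if out in ref.references:
                n_data += 1
        return n, n_succ, n_str, n_data

    sub: list[tuple[str, str, EvaluationReport]] = []
    if strata:
        for label, idx in strata.items():
            n, s, st, dm = count(idx)
            sub.append((label, label, EvaluationReport(n, s, st, dm)))
    n, s, st, dm = count(range(len(results)))
    return EvaluationReport(n, s, st, dm, strata=tuple(sub))


def stratify(references: list[NamePair], mode: str) -> dict[str, list[int]]:
    """Partition reference indices for stratified evaluation.

    ``length_zh`` splits on the Chinese-side name length (all characters,
    locant digits and punctuation included) at the 6-character
    demarcation; ``naming_system`` groups by tag, dropping untagged pairs
    into an ``"excluded (untagged)"`` stratum that callers may report or
    ignore.
    """
    out: dict[str, list[int]] = {}
    if mode == "length_zh":
        le = f"length <= {LENGTH_DEMARCATION}"
        gt = f"length > {LENGTH_DEMARCATION}"
        out[le], out[gt] = [], []
        for i, ref in enumerate(references):
            zh = ref.target_name if ref.direction == "En2Ch" else ref.source_name
            (out[le] if len(zh) <= LENGTH_DEMARCATION else out[gt]).append(i)
        return out
    if mode == "naming_system":
        for i, ref in enumerate(references):
            label = ref.naming_system if ref.naming_system != "unknown" else "excluded (untagged)"
            out.setdefault(label, []).append(i)
        return out
    raise ValueError(f"unknown stratification mode {mode!r}")


def spot_check_sample(
    results: list[TranslationResult],
    n: int,
    seed: int,
    system_labels: list[str] | None = None,
) -> tuple[list[dict], list[dict]]:
    """Draw a blinded sample for manual checking.

    Returns ``(blinded_rows, key_rows)``: the blinded table carries only a
    row id, the input and the produced output; the key table maps row ids
    back to the original result index and the generating system, so the
    checker never sees which system produced what.  Deterministic in
    ``seed``.
    """
    if n > len(results):
        raise ValueError(f"cannot sample {n} rows from {len(results)} results")
    if system_labels is not None and len(system_labels) != len(results):
        raise ValueError("system_labels must align with results")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(results), size=n, replace=False)
    blinded, key = [], []
    for row_id, idx in enumerate(chosen.tolist()):
        res = results[idx]
        blinded.append({"row": row_id, "input": res.input, "output": res.output or ""})
        key.append(
            {
                "row": row_id,
                "result_index": idx,
                "system": system_labels[idx] if system_labels else "unknown",
            }
        )
    return blinded, key
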
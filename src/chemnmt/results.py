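"""Shared translation result record.

Both the neural translators and the rule-based baseline report per-name
outcomes through this type, so the evaluation metrics (success rate,
string/data matching accuracy) can be computed uniformly.  Failures are
values, never exceptions: a rule-based system can fail at segmentation or
dictionary lookup, a neural system only on characters it has never seen.
"""

from __future__ import annotations

from dataclasses import dataclass

FAILURE_REASONS = ("none", "oov_character", "internal_error")
FAILURE_STAGES = ("none", "segmentation", "dictionary")


@dataclass(frozen=True)
class TranslationResult:
    input: str
    output: str | None = None
    succeeded: bool = True
    failure_reason: str = "none"
    failure_stage: str = "none"

    def __post_init__(self):
        if self.failure_reason not in FAILURE_REASONS:
            raise ValueError(f"unknown failure reason {self.failure_reason!r}")
        if self.failure_stage not in FAILURE_STAGES:
            raise ValueError(f"unknown failure stage {self.failure_stage!r}")
        ok = self.output is not None
        if self.succeeded != ok:
            raise ValueError("succeeded must mirror output presence")
        if self.succeeded != (self.failure_reason == "none" and self.failure_stage == "none"):
            raise ValueError("failure fields must be 'none' exactly when succeeded")

    def to_row(self) -> tuple[str, str, str, str]:
        stage = self.failure_stage if self.failure_stage != "none" else self.failure_reason
        return (self.input, self.output or "", "1" if self.succeeded else "0", stage)
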
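"""LA reservoir strain (LAS_r) augmented variants of the guideline engine.

Three Step-2 modifications plus one Step-1 augmentation:

* **model1** — TR peak velocity replaced by LAS_r below cutoff among the
  additional criteria, so the poll becomes {E/e'_mean, LAS_r, LAVi}.
* **model2** — the base algorithm, except that when exactly one of the
  three additional criteria is unevaluable and the two evaluable ones
  conflict (one positive, one negative), LAS_r stands in for the missing
  one and the two-of-three majority is applied.  This only ever converts
  indeterminate calls into determinate ones.
* **model3** — LAS_r added as a fourth additional criterion; elevated if
  more than half of the four (3 or 4) are positive, otherwise normal;
  at least three of the four must be evaluable for a determinate call.
* **step1_plus_lasr** — LAS_r below cutoff as a fifth Step-1 parameter;
  with five voters an exact tie is impossible, so the indeterminate
  grade disappears.

The default LAS_r cutoff is 18% (the models' operating point); 21% and
23% are the other cutoffs exposed for sensitivity sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .algorithm import (
    CRITERIA,
    DEFAULT_ADDITIONAL,
    ClassificationResult,
    Criterion,
    FillingPressureClass,
    GateThresholds,
    Step1Grade,
    TriState,
    _gate,
    evaluate_criterion,
    evaluate_step1,
    evaluate_step2,
    grade_from_votes,
    lasr_criterion,
)
from .cohort import EchoMeasurements

__all__ = [
    "AlgorithmSpec",
    "MODEL_LABELS",
    "build_model_spec",
    "evaluate_model2",
    "evaluate_model3",
    "evaluate_step1_with_lasr",
]

MODEL_LABELS = ("base", "model1", "model2", "model3", "step1_base", "step1_plus_lasr")


class ModelConfigError(ValueError):
    """Unknown model label or invalid model configuration."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named, configured decision rule.

    ``additional`` is the Step-2 poll for majority-style labels; the
    Step-1 labels ignore it.  Gate thresholds are overridable so that
    non-default operating points remain expressible.
    """

    label: str
    lasr_cutoff: float = 18.0
    gate: GateThresholds = field(default_factory=GateThresholds)
    additional: tuple[Criterion, ...] = DEFAULT_ADDITIONAL

    def __post_init__(self) -> None:
        if self.label not in MODEL_LABELS:
            raise ModelConfigError(
                f"unknown algorithm label {self.label!r}; expected one of {MODEL_LABELS}"
            )
        if self.lasr_cutoff <= 0:
            raise ModelConfigError("lasr_cutoff must be > 0")

    def classify_echo(
        self, echo: EchoMeasurements
    ) -> tuple[Step1Grade | None, FillingPressureClass | None, tuple]:
        """Dispatch to the configured evaluator; ratios must be derived."""
        if self.label == "step1_base":
            grade, trace = evaluate_step1(echo)
            return grade, None, trace
        if self.label == "step1_plus_lasr":
            grade, trace = evaluate_step1_with_lasr(echo, self.lasr_cutoff)
            return grade, None, trace
        if self.label == "model2":
            cls, trace = evaluate_model2(echo, self.lasr_cutoff, self.gate)
            return None, cls, trace
        if self.label == "model3":
            cls, trace = evaluate_model3(echo, self.lasr_cutoff, self.gate)
            return None, cls, trace
        # base and model1 share the plain majority evaluator
        cls, trace = evaluate_step2(echo, self.additional, self.gate)
        return None, cls, trace


def build_model_spec(label: str, lasr_cutoff: float = 18.0) -> AlgorithmSpec:
    """Construct the canonical spec for a model label."""
    if label not in MODEL_LABELS:
        raise ModelConfigError(
            f"unknown algorithm label {label!r}; expected one of {MODEL_LABELS}"
        )
    if label == "model1":
        additional = (
            CRITERIA["e_over_e_prime_high"],
            lasr_criterion(lasr_cutoff),
            CRITERIA["lavi_high"],
        )
    elif label == "model3":
        additional = DEFAULT_ADDITIONAL + (lasr_criterion(lasr_cutoff),)
    else:
        additional = DEFAULT_ADDITIONAL
    return AlgorithmSpec(label=label, lasr_cutoff=float(lasr_cutoff), additional=additional)


def evaluate_model2(
    echo: EchoMeasurements,
    lasr_cutoff: float = 18.0,
    gate: GateThresholds = GateThresholds(),
) -> tuple[FillingPressureClass, tuple]:
    """Base Step 2 with conditional LAS_r stand-in.

    When exactly one of {E/e'_mean, TR, LAVi} is unevaluable and the two
    evaluable ones conflict, LAS_r at the configured cutoff replaces the
    missing criterion and the two-of-three majority decides; if LAS_r is
    itself missing the class stays indeterminate.  In every other
    situation the result is identical to the base algorithm.
    """
    cls, trace = evaluate_step2(echo, DEFAULT_ADDITIONAL, gate)
    states = [s for name, s in trace if name != "e_a_gate"]
    if not states:  # gate decided
        return cls, trace
    missing = [s for s in states if s is TriState.MISSING]
    n_pos = sum(s is TriState.POSITIVE for s in states)
    n_neg = sum(s is TriState.NEGATIVE for s in states)
    if len(missing) == 1 and n_pos == 1 and n_neg == 1:
        lasr = lasr_criterion(lasr_cutoff)
        s = evaluate_criterion(echo.las_r, lasr)
        trace = trace + ((lasr.name, s),)
        if s is TriState.POSITIVE:
            cls = FillingPressureClass.ELEVATED
        elif s is TriState.NEGATIVE:
            cls = FillingPressureClass.NORMAL
        # still missing -> indeterminate, unchanged
    return cls, trace


def evaluate_model3(
    echo: EchoMeasurements,
    lasr_cutoff: float = 18.0,
    gate: GateThresholds = GateThresholds(),
) -> tuple[FillingPressureClass, tuple]:
    """Four-criterion variant with a fixed denominator of four.

    Past the gate, elevated requires more than half of the four
    additional criteria (3 or 4 positive); 0-2 positive is normal.  A
    determinate call requires at least 3 of the 4 to be evaluable.
    """
    gated, trace = _gate(echo, gate)
    if gated is not None:
        return gated, tuple(trace)
    criteria = DEFAULT_ADDITIONAL + (lasr_criterion(lasr_cutoff),)
    states = []
    for crit in criteria:
        s = evaluate_criterion(getattr(echo, crit.variable), crit)
        trace.append((crit.name, s))
        states.append(s)
    n_eval = sum(s is not TriState.MISSING for s in states)
    n_pos = sum(s is TriState.POSITIVE for s in states)
    if n_eval < 3:
        return FillingPressureClass.INDETERMINATE, tuple(trace)
    if n_pos >= 3:
        return FillingPressureClass.ELEVATED, tuple(trace)
    return FillingPressureClass.NORMAL, tuple(trace)


def evaluate_step1_with_lasr(
    echo: EchoMeasurements, lasr_cutoff: float = 18.0
) -> tuple[Step1Grade, tuple]:
    """Step 1 with LAS_r as a fifth parameter; all five must be evaluable.

    Three or more of five positive is dysfunction, two or fewer normal;
    an exact 50% split cannot occur with five voters.
    """
    return evaluate_step1(echo, extra=(lasr_criterion(lasr_cutoff),))
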
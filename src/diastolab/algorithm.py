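"""Two-step guideline engine for diastolic function and filling pressure.

Implements the 2016 ASE/EACVI two-step assessment as an explicit
decision engine with tri-state criterion evaluation:

* **Step 1** grades diastolic function from four parameters — annular
  e' velocity (septal and/or lateral), E/e'_mean, TR peak velocity and
  indexed LA volume — as *normal* (<50% positive), *indeterminate*
  (exactly 50%) or *dysfunction* (>50%).  Step 1 requires all four
  parameters to be evaluable; otherwise the grade is *not assessable*.
  The e' parameter is evaluable when at least one wall's velocity is
  present, positive if any present side is below its cutoff.

* **Step 2** classifies left ventricular filling pressure.  A gate on
  transmitral inflow first: E/A <= 0.8 together with E <= 50 cm/s is
  *normal*; E/A >= 2.0 is *elevated*.  Otherwise three additional
  criteria (E/e'_mean > 14, TR > 2.8 m/s, LAVi > 34 mL/m^2) are polled
  and a strict majority of the evaluable ones decides; a tie is
  *indeterminate*, and fewer than two evaluable criteria cannot
  determine the class.  A missing, non-derivable E/A makes Step 2 *not
  assessable*.

Every classification carries a per-criterion trace (positive /
negative / missing) in evaluation order, so that downstream feasibility
accounting can reconcile exactly which inputs drove each call.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .cohort import Cohort, EchoMeasurements, derive_ratios

__all__ = [
    "TriState",
    "Step1Grade",
    "FillingPressureClass",
    "Criterion",
    "GateThresholds",
    "ClassificationResult",
    "CRITERIA",
    "lasr_criterion",
    "evaluate_criterion",
    "evaluate_step1",
    "evaluate_step2",
    "classify_cohort",
]


class TriState(enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    MISSING = "missing"


class Step1Grade(enum.Enum):
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"
    DYSFUNCTION = "dysfunction"
    NOT_ASSESSABLE = "not_assessable"


class FillingPressureClass(enum.Enum):
    NORMAL = "normal"
    INDETERMINATE = "indeterminate"
    ELEVATED = "elevated"
    NOT_ASSESSABLE = "not_assessable"


@dataclass(frozen=True)
class Criterion:
    """A single-variable threshold rule.

    ``direction`` is ``">"`` or ``"<"`` (strict) or ``">="``
    (non-strict, used only for the E/A >= 2.0 rule as printed in the
    guideline cutoff table).
    """

    name: str
    variable: str  # EchoMeasurements field name
    cutoff: float
    direction: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in {">", "<", ">="}:
            raise ValueError(f"invalid direction {self.direction!r}")
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


def evaluate_criterion(value: float | None, criterion: Criterion) -> TriState:
    """Tri-state evaluation: missing input propagates to MISSING.

    Boundary equality under a strict direction is NEGATIVE.
    """
    if value is None:
        return TriState.MISSING
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {value!r} for {criterion.name}")
    if criterion.direction == ">":
        hit = value > criterion.cutoff
    elif criterion.direction == "<":
        hit = value < criterion.cutoff
    else:  # ">="
        hit = value >= criterion.cutoff
    return TriState.POSITIVE if hit else TriState.NEGATIVE


#: Canonical guideline criteria registry.
CRITERIA: dict[str, Criterion] = {
    "e_a_high": Criterion("e_a_high", "e_a_ratio", 2.0, ">=", ""),
    "septal_e_prime_low": Criterion("septal_e_prime_low", "septal_e_prime", 7.0, "<", "cm/s"),
    "lateral_e_prime_low": Criterion("lateral_e_prime_low", "lateral_e_prime", 10.0, "<", "cm/s"),
    "e_over_e_prime_high": Criterion("e_over_e_prime_high", "e_over_e_prime_mean", 14.0, ">", ""),
    "tr_high": Criterion("tr_high", "tr_peak_vel", 2.8, ">", "m/s"),
    "lavi_high": Criterion("lavi_high", "la_volume_index", 34.0, ">", "mL/m2"),
}


def lasr_criterion(cutoff: float = 18.0) -> Criterion:
    """LA reservoir strain below ``cutoff`` percent flags dysfunction."""
    if cutoff <= 0:
        raise ValueError("LA strain cutoff must be positive")
    return Criterion(f"lasr_lt_{cutoff:g}", "las_r", float(cutoff), "<", "%")


@dataclass(frozen=True)
class GateThresholds:
    """Step-2 transmitral gate (overridable; guideline defaults)."""

    ea_normal_max: float = 0.8    # E/A at/below -> normal branch (with E check)
    e_normal_max: float = 50.0    # cm/s, required for the normal branch
    ea_elevated_min: float = 2.0  # E/A at/above -> elevated


@dataclass(frozen=True)
class ClassificationResult:
    patient_id: str
    algorithm: str
    step1: Step1Grade | None = None
    step2: FillingPressureClass | None = None
    trace: tuple[tuple[str, TriState], ...] = ()


# ---------------------------------------------------------------------------
# Step 1

def _e_prime_parameter(echo: EchoMeasurements) -> TriState:
    """Combined annular e' parameter ('septal and/or lateral').

    Evaluable when at least one side is present; positive if any present
    side is below its cutoff, negative only if all present sides are at
    or above cutoff.
    """
    states = [
        evaluate_criterion(echo.septal_e_prime, CRITERIA["septal_e_prime_low"]),
        evaluate_criterion(echo.lateral_e_prime, CRITERIA["lateral_e_prime_low"]),
    ]
    present = [s for s in states if s is not TriState.MISSING]
    if not present:
        return TriState.MISSING
    if TriState.POSITIVE in present:
        return TriState.POSITIVE
    return TriState.NEGATIVE


def step1_parameters(echo: EchoMeasurements) -> list[tuple[str, TriState]]:
    """The four Step-1 parameter states in canonical order."""
    return [
        ("e_prime_low", _e_prime_parameter(echo)),
        ("e_over_e_prime_high",
         evaluate_criterion(echo.e_over_e_prime_mean, CRITERIA["e_over_e_prime_high"])),
        ("tr_high", evaluate_criterion(echo.tr_peak_vel, CRITERIA["tr_high"])),
        ("lavi_high", evaluate_criterion(echo.la_volume_index, CRITERIA["lavi_high"])),
    ]


def grade_from_votes(n_positive: int, n_total: int) -> Step1Grade:
    """Majority grading: <50% normal, =50% indeterminate, >50% dysfunction."""
    frac = n_positive / n_total
    if frac < 0.5:
        return Step1Grade.NORMAL
    if frac == 0.5:
        return Step1Grade.INDETERMINATE
    return Step1Grade.DYSFUNCTION


def evaluate_step1(
    echo: EchoMeasurements, extra: Sequence[Criterion] = ()
) -> tuple[Step1Grade, tuple[tuple[str, TriState], ...]]:
    """Grade diastolic function; returns (grade, criterion trace).

    All consulted parameters (the four guideline ones plus any ``extra``
    criteria, e.g. LA reservoir strain) must be evaluable, else
    NOT_ASSESSABLE.
    """
    params = step1_parameters(echo)
    for crit in extra:
        params.append((crit.name, evaluate_criterion(getattr(echo, crit.variable), crit)))
    trace = tuple(params)
    states = [s for _, s in params]
    if TriState.MISSING in states:
        return Step1Grade.NOT_ASSESSABLE, trace
    n_pos = sum(s is TriState.POSITIVE for s in states)
    return grade_from_votes(n_pos, len(states)), trace


# ---------------------------------------------------------------------------
# Step 2

DEFAULT_ADDITIONAL: tuple[Criterion, ...] = (
    CRITERIA["e_over_e_prime_high"],
    CRITERIA["tr_high"],
    CRITERIA["lavi_high"],
)


def _majority_class(n_positive: int, n_evaluable: int) -> FillingPressureClass:
    """Strict-majority poll over the evaluable additional criteria."""
    if n_evaluable <= 1:
        return FillingPressureClass.INDETERMINATE
    frac = n_positive / n_evaluable
    if frac > 0.5:
        return FillingPressureClass.ELEVATED
    if frac < 0.5:
        return FillingPressureClass.NORMAL
    return FillingPressureClass.INDETERMINATE


def _gate(
    echo: EchoMeasurements, gate: GateThresholds
) -> tuple[FillingPressureClass | None, list[tuple[str, TriState]]]:
    """Transmitral gate; returns (class or None to continue, trace)."""
    trace: list[tuple[str, TriState]] = []
    if echo.e_a_ratio is None:
        trace.append(("e_a_gate", TriState.MISSING))
        return FillingPressureClass.NOT_ASSESSABLE, trace
    if echo.e_a_ratio >= gate.ea_elevated_min:
        trace.append(("e_a_gate", TriState.POSITIVE))
        return FillingPressureClass.ELEVATED, trace
    trace.append(("e_a_gate", TriState.NEGATIVE))
    if (
        echo.e_a_ratio <= gate.ea_normal_max
        and echo.mitral_e_vel is not None
        and echo.mitral_e_vel <= gate.e_normal_max
    ):
        return FillingPressureClass.NORMAL, trace
    return None, trace


def evaluate_step2(
    echo: EchoMeasurements,
    additional_criteria: Sequence[Criterion] = DEFAULT_ADDITIONAL,
    gate: GateThresholds = GateThresholds(),
) -> tuple[FillingPressureClass, tuple[tuple[str, TriState], ...]]:
    """Classify filling pressure; returns (class, criterion trace).

    Assumes ratios have been derived (:func:`derive_ratios`); evaluates
    the echo fields as given.
    """
    gated, trace = _gate(echo, gate)
    if gated is not None:
        return gated, tuple(trace)
    states = []
    for crit in additional_criteria:
        s = evaluate_criterion(getattr(echo, crit.variable), crit)
        trace.append((crit.name, s))
        states.append(s)
    n_eval = sum(s is not TriState.MISSING for s in states)
    n_pos = sum(s is TriState.POSITIVE for s in states)
    return _majority_class(n_pos, n_eval), tuple(trace)


# ---------------------------------------------------------------------------
# Cohort-level application

def classify_cohort(cohort: Cohort, spec) -> list[ClassificationResult]:
    """Apply an algorithm spec to every record, order preserved.

    ``spec`` is an :class:`diastolab.models.AlgorithmSpec` (or anything
    exposing ``label`` and ``classify_echo``).  Ratios are derived
    first; missing data flow to NOT_ASSESSABLE / INDETERMINATE, never an
    exception.
    """
    results = []
    for rec in cohort:
        echo = derive_ratios(rec.echo)
        step1, step2, trace = spec.classify_echo(echo)
        results.append(
            ClassificationResult(rec.patient_id, spec.label, step1, step2, trace)
        )
    return results
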
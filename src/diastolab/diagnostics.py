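"""Diagnostic-accuracy statistics against the invasive reference.

Validates categorical algorithms or continuous markers against elevated
invasive PCWP: confusion matrices with explicit handling of
indeterminate / not-assessable outcomes, the standard proportions
(sensitivity, specificity, PPV, NPV, accuracy, feasibility), Cohen's
kappa with qualitative agreement bands, ROC analysis with DeLong
standard errors, the paired DeLong test for correlated AUCs, Pearson
correlation, and standardized-coefficient multiple linear regression.

AUC here is the tie-corrected Mann-Whitney pair statistic: the mean over
all diseased x non-diseased pairs of 1 for a correctly ordered pair and
1/2 for a tie, computed via midranks.  For a binary (determinate
algorithm) marker this reduces exactly to (sensitivity+specificity)/2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .algorithm import (
    ClassificationResult,
    Criterion,
    FillingPressureClass,
    Step1Grade,
    TriState,
    evaluate_criterion,
)
from .cohort import FIELD_TO_COLUMN, Cohort, derive_ratios

__all__ = [
    "IndeterminatePolicy",
    "ConfusionMatrix",
    "PerformanceSummary",
    "RocResult",
    "DelongComparison",
    "binary_outcomes",
    "confusion",
    "performance",
    "cohen_kappa",
    "kappa_band",
    "roc_auc",
    "delong_compare",
    "algorithm_auc",
    "pearson_r",
    "standardized_ols",
    "cutoff_table",
]


class IndeterminatePolicy(enum.Enum):
    """How indeterminate calls enter the 2x2 table.

    ``EXCLUDE`` removes them from the matrix (they still count in the
    feasibility denominator); ``AS_POSITIVE`` / ``AS_NEGATIVE`` force
    them to a test result.  Not-assessable calls (required inputs
    missing) are always excluded from the matrix: they are a
    feasibility deficit, not a borderline test result.
    """

    EXCLUDE = "exclude"
    AS_POSITIVE = "as_positive"
    AS_NEGATIVE = "as_negative"


class AlignmentError(ValueError):
    """Classification results and reference truth do not align."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int
    n_indeterminate: int = 0
    n_not_assessable: int = 0
    n_missing_reference: int = 0
    policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_excluded(self) -> int:
        return self.n_indeterminate + self.n_not_assessable


@dataclass(frozen=True)
class PerformanceSummary:
    """Proportions in [0, 1]; ``None`` marks an undefined (0/0) metric."""

    feasibility: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    kappa: float | None = None
    kappa_band: str | None = None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class RocResult:
    auc: float
    se: float
    ci: tuple[float, float]
    n_diseased: int
    n_non_diseased: int
    orientation: str = "higher"
    n_excluded_missing: int = 0


@dataclass(frozen=True)
class DelongComparison:
    auc_a: float
    auc_b: float
    diff: float
    se_diff: float
    z: float
    p: float
    n: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Confusion matrices and summary metrics

def binary_outcomes(
    results: Sequence[ClassificationResult], stage: str = "step2"
) -> dict[str, str]:
    """Map classifications to test outcomes per patient.

    Returns patient_id -> "positive" | "negative" | "indeterminate" |
    "not_assessable".  For ``stage="step2"`` elevated is positive; for
    ``stage="step1"`` dysfunction is positive.
    """
    out: dict[str, str] = {}
    for r in results:
        if stage == "step2":
            label = r.step2
            if label is None:
                raise ValueError(f"result for {r.patient_id} has no filling-pressure class")
            mapping = {
                FillingPressureClass.ELEVATED: "positive",
                FillingPressureClass.NORMAL: "negative",
                FillingPressureClass.INDETERMINATE: "indeterminate",
                FillingPressureClass.NOT_ASSESSABLE: "not_assessable",
            }
        elif stage == "step1":
            label = r.step1
            if label is None:
                raise ValueError(f"result for {r.patient_id} has no diastolic grade")
            mapping = {
                Step1Grade.DYSFUNCTION: "positive",
                Step1Grade.NORMAL: "negative",
                Step1Grade.INDETERMINATE: "indeterminate",
                Step1Grade.NOT_ASSESSABLE: "not_assessable",
            }
        else:
            raise ValueError(f"unknown stage {stage!r}")
        out[r.patient_id] = mapping[label]
    return out


def confusion(
    outcomes: Mapping[str, str],
    truth: Mapping[str, bool],
    policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE,
) -> ConfusionMatrix:
    """Cross-tabulate test outcomes against the reference flag.

    ``outcomes`` as produced by :func:`binary_outcomes`.  Patients with
    missing reference (absent from ``truth`` or mapped to ``None``) are
    dropped and counted.  Not-assessable outcomes follow the same policy
    as indeterminate ones but are tallied separately.
    """
    if not outcomes:
        raise ValueError("confusion requires at least one classification result")
    tp = fp = fn = tn = n_ind = n_na = n_missing_ref = 0
    for pid, outcome in outcomes.items():
        if pid not in truth:
            raise AlignmentError(f"no reference truth for patient {pid!r}")
        ref = truth[pid]
        if ref is None:
            n_missing_ref += 1
            continue
        o = outcome
        if o == "not_assessable":
            n_na += 1
            continue
        if o == "indeterminate":
            n_ind += 1
            if policy is IndeterminatePolicy.EXCLUDE:
                continue
            o = "positive" if policy is IndeterminatePolicy.AS_POSITIVE else "negative"
        if o == "positive":
            tp += ref
            fp += not ref
        elif o == "negative":
            fn += ref
            tn += not ref
        else:
            raise ValueError(f"unknown outcome {outcome!r} for patient {pid!r}")
    return ConfusionMatrix(tp, fp, fn, tn, n_ind, n_na, n_missing_ref, policy)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def performance(cm: ConfusionMatrix, total_n: int | None = None) -> PerformanceSummary:
    """Standard-definition proportions; 0/0 metrics are ``None``.

    ``total_n`` is the feasibility denominator (patients with known
    reference); defaults to matrix total + excluded calls.
    """
    counted = cm.n + cm.n_not_assessable + (
        cm.n_indeterminate if cm.policy is IndeterminatePolicy.EXCLUDE else 0
    )
    if total_n is None:
        total_n = counted
    if total_n < counted:
        raise ValueError(f"total_n={total_n} smaller than accounted patients ({counted})")
    kap = cohen_kappa(cm) if cm.n else None
    return PerformanceSummary(
        feasibility=_ratio(cm.n, total_n),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        kappa=kap,
        kappa_band=kappa_band(kap) if kap is not None else None,
    )


def cohen_kappa(cm: ConfusionMatrix) -> float | None:
    """Chance-corrected agreement between test and reference.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginals;
    undefined (None) when p_e = 1.
    """
    n = cm.n
    if n == 0:
        raise ValueError("cohen_kappa requires a non-empty matrix")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / n**2
    if pe == 1:
        return None
    return (po - pe) / (1 - pe)


#: Qualitative agreement bands, left-closed at the printed boundaries:
#: a kappa of exactly 0.20 is still "slight".
_KAPPA_BANDS = ((0.2, "slight"), (0.4, "fair"), (0.6, "moderate"), (0.8, "good"))


def kappa_band(kappa: float) -> str:
    for upper, label in _KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "excellent"


# ---------------------------------------------------------------------------
# ROC / DeLong

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(diseased: np.ndarray, non_diseased: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-subject placement values (structural components)."""
    m, n = len(diseased), len(non_diseased)
    allv = np.concatenate([diseased, non_diseased])
    tz = _midrank(allv)
    tx = _midrank(diseased)
    ty = _midrank(non_diseased)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return float(auc), v10, v01


def roc_auc(
    marker: Sequence[float | None],
    truth: Sequence[bool],
    orientation: str = "higher",
) -> RocResult:
    """Tie-corrected Mann-Whitney AUC with DeLong standard error.

    ``orientation="lower"`` means lower marker values indicate disease
    (e.g. LA reservoir strain); the marker is negated before ranking.
    Pairs with missing marker are excluded (counted).  95% CI by normal
    approximation, clipped to [0, 1].
    """
    if orientation not in ("higher", "lower"):
        raise ValueError("orientation must be 'higher' or 'lower'")
    x = np.array([np.nan if v is None else float(v) for v in marker], dtype=float)
    y = np.asarray(truth, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("marker and truth must align")
    keep = np.isfinite(x)
    n_excluded = int((~keep).sum())
    x, y = x[keep], y[keep]
    if orientation == "lower":
        x = -x
    diseased, non_diseased = x[y], x[~y]
    if len(diseased) == 0 or len(non_diseased) == 0:
        raise ValueError("roc_auc requires both classes present")
    auc, v10, v01 = _placements(diseased, non_diseased)
    m, n = len(diseased), len(non_diseased)
    var = 0.0
    if m > 1:
        var += float(np.var(v10, ddof=1)) / m
    if n > 1:
        var += float(np.var(v01, ddof=1)) / n
    se = math.sqrt(var)
    half = 1.959963984540054 * se
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return RocResult(auc, se, ci, m, n, orientation, n_excluded)


def delong_compare(
    marker_a: Sequence[float],
    marker_b: Sequence[float],
    truth: Sequence[bool],
    orientation_a: str = "higher",
    orientation_b: str = "higher",
) -> DelongComparison:
    """Paired DeLong test for two correlated AUCs on shared patients.

    Covariance of the two AUCs estimated from per-subject placement
    values; two-sided p by normal approximation.  With (numerically)
    identical placements the variance degenerates: z = 0, p = 1,
    flagged.
    """
    a = np.asarray(marker_a, dtype=float)
    b = np.asarray(marker_b, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("paired markers and truth must align")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b, y = a[keep], b[keep], y[keep]
    if orientation_a == "lower":
        a = -a
    if orientation_b == "lower":
        b = -b
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("delong_compare requires both classes present")
    auc_a, v10_a, v01_a = _placements(a[y], a[~y])
    auc_b, v10_b, v01_b = _placements(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        return DelongComparison(auc_a, auc_b, diff, 0.0, 0.0, 1.0, m + n, degenerate=True)
    se = math.sqrt(var)
    z = diff / se
    p = 2 * stats.norm.sf(abs(z))
    return DelongComparison(auc_a, auc_b, diff, se, float(z), float(p), m + n)


def algorithm_auc(
    outcomes: Mapping[str, str],
    truth: Mapping[str, bool],
    policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE,
) -> RocResult:
    """ROC of a categorical algorithm as a two-valued marker.

    Applies the indeterminate policy, codes positive=1 / negative=0 and
    runs :func:`roc_auc`; for such a binary marker the AUC equals
    (sensitivity + specificity) / 2 exactly.
    """
    marker: list[float] = []
    flags: list[bool] = []
    for pid, outcome in outcomes.items():
        if pid not in truth:
            raise AlignmentError(f"no reference truth for patient {pid!r}")
        ref = truth[pid]
        if ref is None:
            continue
        o = outcome
        if o == "not_assessable":
            continue
        if o == "indeterminate":
            if policy is IndeterminatePolicy.EXCLUDE:
                continue
            o = "positive" if policy is IndeterminatePolicy.AS_POSITIVE else "negative"
        marker.append(1.0 if o == "positive" else 0.0)
        flags.append(bool(ref))
    return roc_auc(marker, flags)


# ---------------------------------------------------------------------------
# Correlation and regression

def pearson_r(
    x: Sequence[float | None], y: Sequence[float | None]
) -> tuple[float, float]:
    """Product-moment correlation with pairwise deletion; two-sided p."""
    xa = np.array([np.nan if v is None else float(v) for v in x], dtype=float)
    ya = np.array([np.nan if v is None else float(v) for v in y], dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must align")
    keep = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[keep], ya[keep]
    if len(xa) < 3:
        raise ValueError("pearson_r requires at least 3 complete pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("pearson_r undefined for a zero-variance vector")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


class SingularityError(ValueError):
    """Predictor matrix is rank deficient."""


def standardized_ols(
    outcome: Sequence[float], predictors: pd.DataFrame
) -> tuple[dict[str, float], float, int]:
    """OLS on z-scored variables: standardized betas, r^2, n used.

    Complete-case deletion across outcome and predictors.  For a single
    predictor the standardized coefficient equals the Pearson r.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=predictors.index)
    frame = predictors.astype(float).copy()
    frame["__outcome__"] = y
    frame = frame.dropna()
    cols = [c for c in frame.columns if c != "__outcome__"]
    n = len(frame)
    if n < len(cols) + 2:
        raise ValueError(
            f"standardized_ols requires at least {len(cols) + 2} complete rows, got {n}"
        )
    xmat = frame[cols].to_numpy()
    if np.linalg.matrix_rank(xmat - xmat.mean(axis=0)) < len(cols):
        # name the offending columns for the caller
        bad = []
        for i, c in enumerate(cols):
            others = np.delete(np.arange(len(cols)), i)
            sub = xmat[:, others] - xmat[:, others].mean(axis=0)
            target = xmat[:, i] - xmat[:, i].mean()
            if len(others) and np.linalg.matrix_rank(np.column_stack([sub, target])) == np.linalg.matrix_rank(sub):
                bad.append(c)
            elif np.ptp(xmat[:, i]) == 0:
                bad.append(c)
        raise SingularityError(f"collinear or constant predictors: {bad or cols}")
    z = (frame - frame.mean()) / frame.std(ddof=1)
    model = sm.OLS(z["__outcome__"].to_numpy(), z[cols].to_numpy()).fit()
    betas = {c: float(b) for c, b in zip(cols, model.params)}
    return betas, float(model.rsquared), n


# ---------------------------------------------------------------------------
# Single-cutoff performance tables

def cutoff_table(
    cohort: Cohort,
    cutoffs: Sequence[Criterion],
    policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE,
    pcwp_threshold: float = 15.0,
    subgroup: str | None = None,
) -> pd.DataFrame:
    """Per-criterion diagnostic performance against PCWP >= threshold.

    Each single-variable criterion classifies each patient on its own
    (criterion positive -> test positive; missing input -> excluded as
    not assessable).  ``subgroup`` is an optional pandas-query style
    predicate over canonical CSV column names, e.g. ``"lv_gls_pct >=
    16"``.  Rows whose metrics are undefined carry NaN.
    """
    if not cutoffs:
        raise ValueError("cutoff_table requires at least one criterion")
    records = [r for r in cohort if r.pcwp is not None]
    if subgroup:
        df = Cohort(records).to_dataframe()
        keep = df.query(subgroup).index
        records = [records[i] for i in keep]
    rows = []
    for crit in cutoffs:
        outcomes: dict[str, str] = {}
        truth: dict[str, bool] = {}
        for rec in records:
            echo = derive_ratios(rec.echo)
            state = evaluate_criterion(getattr(echo, crit.variable), crit)
            outcomes[rec.patient_id] = {
                TriState.POSITIVE: "positive",
                TriState.NEGATIVE: "negative",
                TriState.MISSING: "not_assessable",
            }[state]
            truth[rec.patient_id] = rec.pcwp >= pcwp_threshold
        if outcomes:
            cm = confusion(outcomes, truth, policy)
            perf = performance(cm, total_n=len(records))
        else:
            perf = PerformanceSummary(None, None, None, None, None, None)
        rows.append(
            {
                "criterion": crit.name,
                "variable": crit.variable,
                "direction": crit.direction,
                "cutoff": crit.cutoff,
                "n": len(records),
                "feasibility": perf.feasibility,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "ppv": perf.ppv,
                "npv": perf.npv,
                "accuracy": perf.accuracy,
            }
        )
    return pd.DataFrame(rows)
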
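"""Patient-level echocardiographic data model and CSV I/O.

A cohort is an ordered collection of patients, each carrying a set of
echocardiographic measurements (any of which may be missing) and, where
available, an invasively measured pulmonary capillary wedge pressure
(PCWP, mmHg) serving as the reference standard for elevated left
ventricular filling pressure.

Units are fixed by the schema: mitral inflow and annular tissue
velocities in cm/s, tricuspid regurgitation (TR) peak velocity in m/s,
indexed left atrial volume (LAVi) in mL/m^2, strains (LA reservoir
strain, LV global longitudinal strain) as positive percentages, ejection
fraction in percent, PCWP in mmHg.  Guideline cutoff values are only
meaningful in these units.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "EchoMeasurements",
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "CohortFormatError",
    "CohortParseError",
    "ECHO_FIELDS",
    "CSV_COLUMNS",
    "FIELD_TO_COLUMN",
    "derive_ratios",
    "read_cohort_csv",
    "write_cohort_csv",
    "summarize_cohort",
]


class CohortFormatError(ValueError):
    """The file does not conform to the cohort CSV schema."""


class CohortParseError(ValueError):
    """A cell could not be parsed as a number."""


@dataclass(frozen=True)
class EchoMeasurements:
    """One patient's echocardiographic variables; every field optional.

    ``e_a_ratio`` and ``e_over_e_prime_mean`` may either be provided
    (independently measured) or derived from the base velocities with
    :func:`derive_ratios`.  Strains follow the positive-magnitude
    convention.
    """

    mitral_e_vel: float | None = None      # cm/s
    mitral_a_vel: float | None = None      # cm/s
    e_a_ratio: float | None = None
    septal_e_prime: float | None = None    # cm/s
    lateral_e_prime: float | None = None   # cm/s
    e_over_e_prime_mean: float | None = None
    tr_peak_vel: float | None = None       # m/s
    la_volume_index: float | None = None   # mL/m^2
    las_r: float | None = None             # %
    lv_gls: float | None = None            # %, magnitude
    lvef: float | None = None              # %

    def validate(self, rtol: float = 1e-9) -> list[str]:
        """Warning-level consistency checks; returns a list of messages.

        Positivity/finiteness of present values, and agreement of
        provided ratios with their base velocities.  Violations are
        reported, never raised: real exports sometimes carry
        independently measured ratios.
        """
        problems: list[str] = []
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not math.isfinite(v):
                problems.append(f"{f.name} is not finite: {v!r}")
            elif v <= 0:
                problems.append(f"{f.name} must be > 0, got {v!r}")
        if None not in (self.mitral_e_vel, self.mitral_a_vel, self.e_a_ratio):
            if self.mitral_a_vel > 0:
                expect = self.mitral_e_vel / self.mitral_a_vel
                if not math.isclose(self.e_a_ratio, expect, rel_tol=rtol):
                    problems.append(
                        f"e_a_ratio {self.e_a_ratio} inconsistent with E/A = {expect}"
                    )
        if None not in (
            self.mitral_e_vel,
            self.septal_e_prime,
            self.lateral_e_prime,
            self.e_over_e_prime_mean,
        ):
            mean_ep = (self.septal_e_prime + self.lateral_e_prime) / 2.0
            if mean_ep > 0:
                expect = self.mitral_e_vel / mean_ep
                if not math.isclose(self.e_over_e_prime_mean, expect, rel_tol=rtol):
                    problems.append(
                        f"e_over_e_prime_mean {self.e_over_e_prime_mean} "
                        f"inconsistent with E/e'_mean = {expect}"
                    )
        return problems


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    echo: EchoMeasurements = field(default_factory=EchoMeasurements)
    pcwp: float | None = None  # mmHg, invasive reference


@dataclass
class Cohort:
    """Ordered, deterministic collection of patient records."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Canonical wide table, one row per patient (NaN = missing)."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {"patient_id": rec.patient_id}
            for name in ECHO_FIELDS:
                row[FIELD_TO_COLUMN[name]] = getattr(rec.echo, name)
            row["pcwp_mmhg"] = rec.pcwp
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "Cohort":
        records = []
        for _, row in df.iterrows():
            echo_kwargs = {}
            for name in ECHO_FIELDS:
                v = row.get(FIELD_TO_COLUMN[name])
                echo_kwargs[name] = None if v is None or pd.isna(v) else float(v)
            pcwp = row.get("pcwp_mmhg")
            pcwp = None if pcwp is None or pd.isna(pcwp) else float(pcwp)
            records.append(
                PatientRecord(str(row["patient_id"]), EchoMeasurements(**echo_kwargs), pcwp)
            )
        return cls(records, provenance=provenance)


ECHO_FIELDS: tuple[str, ...] = tuple(f.name for f in fields(EchoMeasurements))

FIELD_TO_COLUMN: dict[str, str] = {
    "mitral_e_vel": "mitral_e_vel_cm_s",
    "mitral_a_vel": "mitral_a_vel_cm_s",
    "e_a_ratio": "e_a_ratio",
    "septal_e_prime": "septal_e_prime_cm_s",
    "lateral_e_prime": "lateral_e_prime_cm_s",
    "e_over_e_prime_mean": "e_over_e_prime_mean",
    "tr_peak_vel": "tr_peak_vel_m_s",
    "la_volume_index": "la_volume_index_ml_m2",
    "las_r": "las_r_pct",
    "lv_gls": "lv_gls_pct",
    "lvef": "lvef_pct",
}
COLUMN_TO_FIELD = {v: k for k, v in FIELD_TO_COLUMN.items()}

CSV_COLUMNS: tuple[str, ...] = (
    "patient_id",
    *(FIELD_TO_COLUMN[name] for name in ECHO_FIELDS),
    "pcwp_mmhg",
)

#: CSV cells treated as missing (case-insensitive).
MISSING_SENTINELS = {"", "na"}


def _format_cell(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def _parse_cell(text: str, row: int, column: str) -> float | None:
    if text.strip().lower() in MISSING_SENTINELS:
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(
            f"non-numeric value {text!r} in column {column!r}, data row {row}"
        ) from None


def read_cohort_csv(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> Cohort:
    """Read a cohort from CSV.

    Empty cells and ``NA`` (case-insensitive) become missing values.
    Derived ratios are taken as-is and never auto-filled; apply
    :func:`derive_ratios` downstream if desired.

    ``column_map`` optionally maps file column names to canonical schema
    names (e.g. ``{"id": "patient_id"}``).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file, header row required") from None
        if column_map:
            header = [column_map.get(h, h) for h in header]
        if "patient_id" not in header:
            raise CohortFormatError(f"{path}: required column 'patient_id' missing")
        idx = {name: header.index(name) for name in header}
        records = []
        for rownum, row in enumerate(reader, start=1):
            pid = row[idx["patient_id"]]
            echo_kwargs = {}
            for name in ECHO_FIELDS:
                col = FIELD_TO_COLUMN[name]
                if col in idx and idx[col] < len(row):
                    echo_kwargs[name] = _parse_cell(row[idx[col]], rownum, col)
            pcwp = None
            if "pcwp_mmhg" in idx and idx["pcwp_mmhg"] < len(row):
                pcwp = _parse_cell(row[idx["pcwp_mmhg"]], rownum, "pcwp_mmhg")
            records.append(PatientRecord(pid, EchoMeasurements(**echo_kwargs), pcwp))
    return Cohort(records, provenance=str(path))


def write_cohort_csv(cohort: Cohort, path: str | Path) -> Path:
    """Write the cohort in canonical column order; missing cells empty.

    Float cells use shortest round-trip representation, so writing the
    same cohort twice produces byte-identical files.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for rec in cohort:
            row = [rec.patient_id]
            row.extend(_format_cell(getattr(rec.echo, name)) for name in ECHO_FIELDS)
            row.append(_format_cell(rec.pcwp))
            writer.writerow(row)
    return path


def derive_ratios(echo: EchoMeasurements) -> EchoMeasurements:
    """Fill E/A and E/e'_mean from base velocities where missing.

    Never overwrites a provided ratio.  An A velocity of exactly 0 is
    division-degenerate: the ratio is left missing and a warning issued.
    Idempotent.
    """
    updates: dict[str, float] = {}
    if echo.e_a_ratio is None and None not in (echo.mitral_e_vel, echo.mitral_a_vel):
        if echo.mitral_a_vel == 0:
            warnings.warn(
                "mitral A velocity is 0; E/A left missing", RuntimeWarning, stacklevel=2
            )
        else:
            updates["e_a_ratio"] = echo.mitral_e_vel / echo.mitral_a_vel
    if echo.e_over_e_prime_mean is None and None not in (
        echo.mitral_e_vel,
        echo.septal_e_prime,
        echo.lateral_e_prime,
    ):
        mean_ep = (echo.septal_e_prime + echo.lateral_e_prime) / 2.0
        if mean_ep == 0:
            warnings.warn(
                "mean e' is 0; E/e'_mean left missing", RuntimeWarning, stacklevel=2
            )
        else:
            updates["e_over_e_prime_mean"] = echo.mitral_e_vel / mean_ep
    return replace(echo, **updates) if updates else echo


@dataclass
class CohortSummary:
    """Per-variable moments overall and by elevated-PCWP stratum."""

    n: int
    pcwp_threshold: float
    n_missing_pcwp: int
    n_elevated: int
    n_normal: int
    prevalence: float | None  # among records with known PCWP
    table: pd.DataFrame  # index: variable; columns: (stratum, stat)


def summarize_cohort(cohort: Cohort, pcwp_threshold: float = 15.0) -> CohortSummary:
    """Mean/SD per variable, overall and stratified by PCWP >= threshold.

    Moments use non-missing values only.  Records with missing PCWP are
    counted overall but excluded from the strata and from prevalence.
    """
    if len(cohort) == 0:
        raise ValueError("summarize_cohort requires a non-empty cohort")
    df = cohort.to_dataframe()
    num = df.drop(columns=["patient_id"]).astype(float)
    known = num["pcwp_mmhg"].notna()
    elevated = known & (num["pcwp_mmhg"] >= pcwp_threshold)
    normal = known & (num["pcwp_mmhg"] < pcwp_threshold)

    def _stats(sub: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {"count": sub.notna().sum(), "mean": sub.mean(), "sd": sub.std(ddof=1)}
        )

    parts = {
        "overall": _stats(num),
        "elevated": _stats(num[elevated]),
        "normal": _stats(num[normal]),
    }
    table = pd.concat(parts, axis=1)  # columns: (stratum, stat)
    n_known = int(known.sum())
    prevalence = float(elevated.sum() / n_known) if n_known else None
    return CohortSummary(
        n=len(cohort),
        pcwp_threshold=pcwp_threshold,
        n_missing_pcwp=int((~known).sum()),
        n_elevated=int(elevated.sum()),
        n_normal=int(normal.sum()),
        prevalence=prevalence,
        table=table,
    )
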
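"""End-to-end orchestration: simulate -> classify -> evaluate -> compare.

Reproduces the shape of the validation analysis on any cohort, real or
synthetic: a stratified cohort summary, single-cutoff performance
tables (overall and within the preserved-deformation subgroup, LV-GLS
>= 16%), Step-1 grading with and without LA reservoir strain, and the
head-to-head comparison of the base filling-pressure algorithm against
the three LAS_r-modified variants including paired DeLong tests.

Artifacts are emitted as machine-readable CSV/JSON twins of the
human-readable tables, each stamped with the run seed and a hash of the
configuration so any output can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .algorithm import CRITERIA, ClassificationResult, classify_cohort, lasr_criterion
from .cohort import Cohort, read_cohort_csv, summarize_cohort, write_cohort_csv
from .diagnostics import (
    DelongComparison,
    IndeterminatePolicy,
    algorithm_auc,
    binary_outcomes,
    confusion,
    cutoff_table,
    delong_compare,
    performance,
)
from .models import build_model_spec
from .synthetic import GeneratorConfig, generate_cohort, validate_synthetic

logger = logging.getLogger("diastolab")

__all__ = ["RunConfig", "ReportBundle", "run_full_analysis", "compare_models"]

STEP2_LABELS = ("base", "model1", "model2", "model3")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of ``cohort_csv`` / ``generator`` provides the input.
    """

    cohort_csv: str | None = None
    generator: GeneratorConfig | None = None
    algorithms: tuple[str, ...] = STEP2_LABELS
    lasr_cutoff: float = 18.0
    lasr_sweep: tuple[float, ...] = (23.0, 21.0, 18.0)
    step2_policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE
    step1_policy: IndeterminatePolicy = IndeterminatePolicy.AS_POSITIVE
    pcwp_threshold: float = 15.0
    subgroup: str = "lv_gls_pct >= 16"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort_csv is None) == (self.generator is None):
            raise ValueError("provide exactly one of cohort_csv or generator")
        unknown = set(self.algorithms) - set(STEP2_LABELS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    def to_json(self) -> str:
        doc = {
            "cohort_csv": self.cohort_csv,
            "generator": json.loads(self.generator.to_json()) if self.generator else None,
            "algorithms": list(self.algorithms),
            "lasr_cutoff": self.lasr_cutoff,
            "lasr_sweep": list(self.lasr_sweep),
            "step2_policy": self.step2_policy.value,
            "step1_policy": self.step1_policy.value,
            "pcwp_threshold": self.pcwp_threshold,
            "subgroup": self.subgroup,
            "seed": self.seed,
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        return cls(
            cohort_csv=doc.get("cohort_csv"),
            generator=(
                GeneratorConfig.from_json(json.dumps(doc["generator"]))
                if doc.get("generator")
                else None
            ),
            algorithms=tuple(doc.get("algorithms", STEP2_LABELS)),
            lasr_cutoff=doc.get("lasr_cutoff", 18.0),
            lasr_sweep=tuple(doc.get("lasr_sweep", (23.0, 21.0, 18.0))),
            step2_policy=IndeterminatePolicy(doc.get("step2_policy", "exclude")),
            step1_policy=IndeterminatePolicy(doc.get("step1_policy", "as_positive")),
            pcwp_threshold=doc.get("pcwp_threshold", 15.0),
            subgroup=doc.get("subgroup", "lv_gls_pct >= 16"),
            output_dir=doc.get("output_dir"),
            seed=doc.get("seed", 0),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    metadata: dict
    cohort_summary: pd.DataFrame
    cutoffs: pd.DataFrame
    cutoffs_subgroup: pd.DataFrame | None
    step1: pd.DataFrame
    step2_models: pd.DataFrame
    model_comparison: pd.DataFrame
    calibration: pd.DataFrame | None = None


def _truth(cohort: Cohort, threshold: float) -> dict[str, bool | None]:
    return {
        r.patient_id: (None if r.pcwp is None else r.pcwp >= threshold) for r in cohort
    }


def _summary_row(label: str, outcomes, truth, policy, total_n) -> dict:
    cm = confusion(outcomes, truth, policy)
    perf = performance(cm, total_n=total_n)
    row = {
        "algorithm": label,
        "n": total_n,
        "n_determinate": cm.n,
        "n_indeterminate": cm.n_indeterminate,
        "n_not_assessable": cm.n_not_assessable,
        "feasibility": perf.feasibility,
        "sensitivity": perf.sensitivity,
        "specificity": perf.specificity,
        "ppv": perf.ppv,
        "npv": perf.npv,
        "accuracy": perf.accuracy,
        "kappa": perf.kappa,
        "kappa_band": perf.kappa_band,
    }
    try:
        roc = algorithm_auc(outcomes, truth, policy)
        row.update(auc=roc.auc, auc_ci_low=roc.ci[0], auc_ci_high=roc.ci[1])
    except ValueError:
        row.update(auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan)
    return row


def compare_models(
    results_by_model: Mapping[str, Sequence[ClassificationResult]],
    truth: Mapping[str, bool | None],
    policy: IndeterminatePolicy = IndeterminatePolicy.EXCLUDE,
    base_label: str = "base",
) -> pd.DataFrame:
    """Each model vs the base algorithm on both-determinate patients.

    The paired DeLong test needs a shared patient set, so the AUC
    difference is computed on the intersection of patients with a
    determinate call (and known reference) under both algorithms; the
    intersection size is logged and reported.
    """
    if base_label not in results_by_model or len(results_by_model) < 2:
        raise ValueError("compare_models requires the base model plus at least one other")
    base_out = binary_outcomes(results_by_model[base_label])
    rows = []
    for label, results in results_by_model.items():
        if label == base_label:
            continue
        out = binary_outcomes(results)
        shared = [
            pid
            for pid, o in out.items()
            if o in ("positive", "negative")
            and base_out.get(pid) in ("positive", "negative")
            and truth.get(pid) is not None
        ]
        row: dict = {"model": label, "vs": base_label, "n_shared_determinate": len(shared)}
        flags = [truth[pid] for pid in shared]
        if shared and any(flags) and not all(flags):
            a = [1.0 if out[pid] == "positive" else 0.0 for pid in shared]
            b = [1.0 if base_out[pid] == "positive" else 0.0 for pid in shared]
            cmp = delong_compare(a, b, flags)
            row.update(
                auc_model=cmp.auc_a,
                auc_base=cmp.auc_b,
                auc_diff=cmp.diff,
                delong_z=cmp.z,
                delong_p=cmp.p,
                degenerate=cmp.degenerate,
            )
        else:
            logger.warning("compare_models: no usable shared determinate set for %s", label)
            row.update(
                auc_model=np.nan, auc_base=np.nan, auc_diff=np.nan,
                delong_z=np.nan, delong_p=np.nan, degenerate=True,
            )
        # feasibility / kappa deltas on the full cohort
        perf_m = performance(confusion(out, truth, policy))
        perf_b = performance(confusion(base_out, truth, policy))
        row["feasibility_diff"] = (
            perf_m.feasibility - perf_b.feasibility
            if None not in (perf_m.feasibility, perf_b.feasibility)
            else np.nan
        )
        row["kappa_diff"] = (
            perf_m.kappa - perf_b.kappa
            if None not in (perf_m.kappa, perf_b.kappa)
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Run the complete analysis; deterministic given the config."""
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        calibration = validate_synthetic(cohort, config.generator).to_frame()
    else:
        cohort = read_cohort_csv(config.cohort_csv)
        calibration = None
    logger.info("cohort of %d patients (%s)", len(cohort), cohort.provenance)

    truth = _truth(cohort, config.pcwp_threshold)
    n_known_ref = sum(v is not None for v in truth.values())
    logger.info("reference PCWP known for %d patients", n_known_ref)

    summary = summarize_cohort(cohort, config.pcwp_threshold)
    summary_table = summary.table.copy()
    summary_table.columns = ["_".join(c) for c in summary_table.columns]
    summary_table = summary_table.reset_index(names="variable")

    single = [
        CRITERIA["e_a_high"],
        CRITERIA["septal_e_prime_low"],
        CRITERIA["lateral_e_prime_low"],
        CRITERIA["e_over_e_prime_high"],
        CRITERIA["lavi_high"],
        *(lasr_criterion(c) for c in config.lasr_sweep),
        CRITERIA["tr_high"],
    ]
    cutoffs = cutoff_table(cohort, single, pcwp_threshold=config.pcwp_threshold)
    try:
        cutoffs_sub = cutoff_table(
            cohort,
            [lasr_criterion(c) for c in config.lasr_sweep],
            pcwp_threshold=config.pcwp_threshold,
            subgroup=config.subgroup,
        )
    except Exception:
        logger.warning("subgroup predicate %r failed; skipping", config.subgroup)
        cutoffs_sub = None

    # Step-1 grading with and without LA reservoir strain
    step1_rows = []
    res = classify_cohort(cohort, build_model_spec("step1_base"))
    step1_rows.append(
        _summary_row("step1_base", binary_outcomes(res, "step1"), truth,
                     config.step1_policy, n_known_ref)
    )
    for c in config.lasr_sweep:
        res = classify_cohort(cohort, build_model_spec("step1_plus_lasr", c))
        step1_rows.append(
            _summary_row(f"step1_plus_lasr_{c:g}", binary_outcomes(res, "step1"),
                         truth, config.step1_policy, n_known_ref)
        )
    step1 = pd.DataFrame(step1_rows)

    # Step-2: base vs LAS_r models
    results_by_model = {
        label: classify_cohort(cohort, build_model_spec(label, config.lasr_cutoff))
        for label in config.algorithms
    }
    step2_rows = [
        _summary_row(label, binary_outcomes(results), truth,
                     config.step2_policy, n_known_ref)
        for label, results in results_by_model.items()
    ]
    step2 = pd.DataFrame(step2_rows)
    for label, results in results_by_model.items():
        out = binary_outcomes(results)
        counts = {
            "determinate": sum(o in ("positive", "negative") for o in out.values()),
            "indeterminate": sum(o == "indeterminate" for o in out.values()),
            "not_assessable": sum(o == "not_assessable" for o in out.values()),
        }
        logger.info(
            "%s: %d determinate / %d indeterminate / %d not assessable of %d",
            label, counts["determinate"], counts["indeterminate"],
            counts["not_assessable"], len(cohort),
        )

    if "base" in results_by_model and len(results_by_model) > 1:
        comparison = compare_models(results_by_model, truth, config.step2_policy)
    else:
        comparison = pd.DataFrame()

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "n": len(cohort),
        "n_known_reference": n_known_ref,
        "provenance": cohort.provenance,
    }
    bundle = ReportBundle(
        metadata=metadata,
        cohort_summary=summary_table,
        cutoffs=cutoffs,
        cutoffs_subgroup=cutoffs_sub,
        step1=step1,
        step2_models=step2,
        model_comparison=comparison,
        calibration=calibration,
    )
    if config.output_dir:
        write_bundle(bundle, Path(config.output_dir), cohort)
    return bundle


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_bundle(bundle: ReportBundle, outdir: Path, cohort: Cohort | None = None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "metadata.json").write_text(
        json.dumps(bundle.metadata, indent=2, sort_keys=True) + "\n"
    )
    _write_csv(bundle.cohort_summary, outdir / "cohort_summary.csv")
    _write_csv(bundle.cutoffs, outdir / "cutoff_performance.csv")
    if bundle.cutoffs_subgroup is not None:
        _write_csv(bundle.cutoffs_subgroup, outdir / "cutoff_performance_subgroup.csv")
    _write_csv(bundle.step1, outdir / "step1_performance.csv")
    _write_csv(bundle.step2_models, outdir / "step2_models.csv")
    _write_csv(bundle.model_comparison, outdir / "model_comparison.csv")
    if bundle.calibration is not None:
        _write_csv(bundle.calibration, outdir / "calibration.csv")
    if cohort is not None:
        write_cohort_csv(cohort, outdir / "cohort.csv")
    # human-readable twin
    with (outdir / "report.txt").open("w") as fh:
        fh.write(f"diastolab {bundle.metadata['version']} run report\n")
        fh.write(f"seed={bundle.metadata['seed']} config={bundle.metadata['config_hash']}\n\n")
        for name, df in (
            ("Cohort summary", bundle.cohort_summary),
            ("Single-cutoff performance", bundle.cutoffs),
            ("Step 1", bundle.step1),
            ("Step 2 models", bundle.step2_models),
            ("Model comparison", bundle.model_comparison),
        ):
            fh.write(f"== {name} ==\n")
            fh.write(df.to_string(index=False))
            fh.write("\n\n")


def classification_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Flat results table: one row per patient, trace columns appended."""
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "algorithm": r.algorithm,
            "step1": r.step1.value if r.step1 else "",
            "step2": r.step2.value if r.step2 else "",
        }
        for name, state in r.trace:
            row[f"crit_{name}"] = state.value
        rows.append(row)
    return pd.DataFrame(rows).fillna("")
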
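# Methods

## Problem setting

Elevated left ventricular (LV) filling pressure is the haemodynamic
hallmark of heart failure with preserved ejection fraction. The
reference standard is invasive: pulmonary capillary wedge pressure
(PCWP), with PCWP ≥ 15 mmHg at rest defining "elevated" throughout this
package. Non-invasively, the 2016 ASE/EACVI recommendations assess
diastolic function and filling pressure from a small set of Doppler and
2D echocardiographic variables. `diastolab` implements that decision
rule as an explicit engine, together with three published-style variants
that add left atrial reservoir strain (LAS_r) — the peak positive LA
deformation during ventricular systole, which falls as LA compliance and
function deteriorate — and the statistics needed to validate any of
these against invasive PCWP.

## The decision engine

All criteria are tri-state: *positive*, *negative*, or *missing*. All
cutoffs are strict comparisons as conventionally printed (e.g. TR peak
velocity > 2.8 m/s, septal e′ < 7 cm/s, lateral e′ < 10 cm/s,
E/e′_mean > 14, LAVi > 34 mL/m², LAS_r < {23, 21, 18}%), with one
deliberate exception: the transmitral E/A ratio rule for elevation is
non-strict (E/A ≥ 2.0), matching how that cutoff is printed.

**Step 1 (diastolic function).** Four parameters: the annular e′
parameter (septal *and/or* lateral — evaluable when at least one wall is
measured, positive if any measured wall is below its cutoff),
E/e′_mean, TR peak velocity, and indexed LA volume. All four must be
evaluable, otherwise the grade is *not assessable*. Fewer than 50%
positive is *normal*, exactly 50% *indeterminate*, more than 50%
*dysfunction*.

**Step 2 (filling pressure).** A transmitral gate first: E/A ≤ 0.8
with E ≤ 50 cm/s → *normal*; E/A ≥ 2.0 → *elevated*; E/A missing →
*not assessable*. The gate thresholds are the guideline's; they are
exposed on `AlgorithmSpec` and overridable. Otherwise the three
additional criteria (E/e′_mean, TR, LAVi) are polled: with at least two
evaluable, a strict majority decides; an exact tie is *indeterminate*;
with one or zero evaluable the class cannot be determined
(*indeterminate*). Step 2 is evaluated for every patient regardless of
the Step-1 grade.

**LAS_r variants.** `model1` replaces the TR criterion with
LAS_r < cutoff. `model2` is the base rule except that when exactly one
additional criterion is unevaluable *and* the two evaluable ones
conflict, LAS_r stands in for the missing one; it can therefore only
convert indeterminate calls into determinate ones (a feasibility
dominance property asserted in the tests). `model3` adds LAS_r as a
fourth criterion with the denominator fixed at four: 3–4 positive →
elevated, 0–2 → normal, and a determinate call requires at least 3 of
the 4 evaluable (with only 2 evaluable a majority of four is
unreachable, and no printed rule covers that case, so the conservative
choice is indeterminate). `step1_plus_lasr` adds LAS_r as a fifth
Step-1 parameter; with five voters a tie is impossible and the
indeterminate grade vanishes. The default LAS_r cutoff is 18% for the
models (their stated operating point); 23% and 21% are used in the
sensitivity sweeps. Extending "≤ 50% positive → non-elevated" to zero
positives in `model3` is the only logically consistent reading of the
printed 1-or-2 enumeration, which presumes the branch is reached at all.

Two readings were genuinely open and are resolved explicitly rather than
silently: (a) the annular e′ parameter is treated as evaluable from a
single wall (the literal "and/or" reading); (b) *indeterminate* (tied
or insufficient criteria) and *not assessable* (required inputs
missing) are kept distinct throughout and never merged.

## Diagnostic accuracy statistics

Classifications are validated against the binary reference
PCWP ≥ 15 mmHg. Not-assessable calls are always excluded from the 2×2
matrix — they are a feasibility deficit, not a test result — while
indeterminate calls follow an explicit `IndeterminatePolicy`: the
default is *exclude* for Step-2/model evaluation (feasibility =
determinate fraction) and *as-positive* for Step-1 grading (an
indeterminate grade treated as an abnormal screen). Both are
overridable and logged. Sensitivity, specificity, PPV, NPV and accuracy
use the standard definitions with 0/0 reported as undefined rather than
zero. Cohen's kappa uses the marginal-chance correction with
qualitative bands 0–0.2 slight, 0.21–0.4 fair, 0.41–0.6 moderate,
0.61–0.8 good, > 0.8 excellent, assigned left-closed (κ = 0.20 is
"slight").

AUC is the tie-corrected Mann–Whitney pair statistic computed via
midranks; ties count ½. Markers where *lower* values indicate disease
(LAS_r) are negated first. Standard errors use DeLong's
structural-components (placement-value) estimator; 95% CIs are normal
approximations clipped to [0, 1] (the CI method is this package's
choice; nothing stronger is claimed for it). Paired AUC comparisons use
the covariance-adjusted DeLong test on the intersection of patients
determinate under both algorithms — a paired test needs shared subjects,
and the intersection size is always reported. Identical placements give
z = 0, p = 1, flagged degenerate. A categorical algorithm's AUC treats
its determinate output as a two-valued marker, which reduces exactly to
(sensitivity + specificity)/2.

Pearson correlations use pairwise deletion and the t-distribution
two-sided p. Multiple regression z-scores all variables and reports
standardized coefficients (single-predictor case: identical to Pearson
r) with complete-case deletion. No multiple-testing correction is
applied anywhere.

## Synthetic cohort generator

The generator emulates the statistical shape of a dual-centre invasive
haemodynamic cohort of dyspnoeic patients with preserved EF, so the
whole pipeline is testable without patient data. Mechanism: Gaussian
copula — a latent multivariate standard normal with a target correlation
matrix, mapped through per-variable truncated marginal transforms.

**Marginals.** Each of the ten base variables (PCWP, E, A, septal e′,
lateral e′, TR, LAVi, LAS_r, LV-GLS, EF) has a truncated-normal (or
optionally truncated-lognormal) marginal whose parameters are
moment-matched *after* truncation by a numerical solve, so achieved
means and SDs land on target despite physiologic bounds. Defaults are
the study population's printed moments (PCWP 11 ± 5 mmHg, E 78 ± 30
cm/s, septal e′ 6.6 ± 2.6, lateral e′ 9.2 ± 3.5, TR 3.5 ± 0.7 m/s, LAVi
30 ± 14 mL/m², LAS_r 22 ± 10%, LV-GLS 17 ± 5%, EF 62 ± 7%). PCWP uses a
truncated normal on [2, 40] mmHg: with the 11 ± 5 moments this puts
≈ 21.4% of mass at ≥ 15 mmHg, reproducing the ~21% prevalence of
elevated pressure, whereas any lognormal matched to the same moments
concentrates the upper tail and yields only ≈ 17.8% — the printed
moments and prevalence jointly identify the near-normal shape. The
A-velocity marginal (68 ± 22 cm/s) is a free knob: no published moments
constrain it.

**Dependence.** Marker–PCWP latent correlations are set to the reported
Pearson values (E 0.50, LAVi 0.36, LAS_r −0.37, TR 0.0, septal e′ 0.0)
plus weak choices where only qualitative information exists (lateral e′
−0.15, LV-GLS −0.20, EF 0.0). Correlations *among* echo variables are
not constrained by the source data; defaults (septal–lateral e′ 0.6,
LAS_r–GLS 0.33, LAS_r–LAVi −0.30, E–LAVi 0.25, GLS–EF 0.45 ...) are
plausible physiology and explicitly marked as such. The assembled
matrix is repaired to positive semi-definite by eigenvalue clipping with
diagonal renormalization; if repair moves any entry by more than 0.2 the
dependence spec is rejected as infeasible.

**Ratios are emergent.** E/A and E/e′_mean are *derived* from the
simulated base variables, never simulated directly, which guarantees
internal consistency. Their correlations with PCWP are therefore
emergent. The A-velocity knob was calibrated once, over a small grid,
so that the emergent r(E/A, PCWP) lands near the reported 0.46: with
corr(A, PCWP) = 0.0 and corr(E, A) = 0.45 the emergent value is ≈ 0.46
at n = 20,000 (negative A–PCWP correlations push it far above target).
The emergent r(E/e′, PCWP) ≈ 0.38 is reported but not tuned.

**Missingness** is independent per variable (MCAR) — feasibility
percentages are all the source reports, so the minimal mechanism is
assumed — applied to base variables *before* ratio derivation, so a
ratio is available exactly when its components are. Defaults reproduce
TR observed in 89%, LAS_r in 94%, LV-GLS in 98%, and the four Step-1
inputs jointly in ≈ 83% of patients.

**Determinism.** A cohort is a pure function of its configuration
(including the seed); the provenance string carries a hash of the
config, and `validate_synthetic` produces a calibration report with
pass/fail at the stated tolerances (means 2% relative, SDs 5%,
correlations ±0.03, prevalence ±0.02, feasibilities ±0.01 — calibrated
for n = 20,000, widened by √(20000/n) for smaller cohorts, chosen so
that false failures are vanishingly rare under the fixed test seeds).

**What the generator does not emulate.** Nonlinear marker–pressure
relations (a Gaussian copula is fully described by its correlation
matrix), informative missingness, repeated measures, comorbidity
structure, and inter-centre heterogeneity. One consequence is
quantitative and worth stating plainly: published data show LAS_r with
Pearson r = −0.37 against PCWP *and* a standalone AUC of 0.76, which is
jointly impossible under a bivariate normal law (r = −0.37 implies
AUC ≈ 0.68). The copula honours the correlation, so the synthetic
LAS_r discriminates less strongly than the real one, and the advantage
of the LAS_r-substituted algorithm over the conventional one, while
directionally reproduced, is smaller in synthetic cohorts (AUC gap
≈ 0.02 vs the published ≈ 0.08). Passing tests therefore demonstrate
correctness of the machinery and directional fidelity, not the
magnitude of the published clinical effect.

## Numerical and size choices

Simulation sizes are chosen to keep the full test run fast while
leaving sampling error far below the asserted tolerances: calibration
checks at n = 20,000 (SE of a mean ≈ 0.7% of its SD), directional
end-to-end checks on 40 seeds at n = 2,000, bootstrap cross-checks at
n = 200 with 2,000 replicates. The probe grid for rule-engine
equivalence enumerates all 4⁷ missing/below/at/above combinations of
the seven consulted variables plus low-E/A gate variants (24,576
states). CSV output uses shortest round-trip float representation, so
repeated runs are byte-identical across platforms. Degenerate inputs
are defined, not accidental: A = 0 leaves E/A missing with a warning,
zero-variance vectors make Pearson r an error, empty classes make ROC
an error, and 0/0 proportions are reported as undefined.

## Known limitations

The engine deliberately omits the guideline's special-population
pathways (atrial fibrillation, more than mild mitral disease,
hypertrophic cardiomyopathy, transplant) — cohorts are assumed filtered
upstream, as in the validation setting it models. The DeLong comparison
on the both-determinate intersection conditions on feasibility, which
can differ between algorithms; the intersection is logged so the reader
can judge. Exact small-sample AUC confidence intervals,
net-reclassification indices and calibration curves are out of scope.
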
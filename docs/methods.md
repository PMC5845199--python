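# Methods

## Problem

About 10–20% of children with Kawasaki disease (KD) do not respond to
first-line intravenous immunoglobulin (IVIG; resistance = recrudescent
or persistent fever ≥ 36 h after the infusion ends), and resistant
children carry a markedly higher risk of coronary artery abnormality.
Several point-based scores computed from admission data have been
published to flag likely non-responders before treatment.  `kdscore`
implements six of them — Kobayashi, Egami, Sano, Formosa, Kawamura's
NLR/PLR combination rule, and a five-criterion Chinese single-center
model (registry name `ours`) — together with the statistical machinery
needed to evaluate any of them on a labeled cohort.

## Data model and units

Each patient carries demographics, seven tri-state clinical signs
(present / absent / unknown), an admission laboratory panel, and an
optional response label.  Labs are stored in fixed canonical units:
CRP mg/L, ALT/AST IU/L, Na mmol/L, ALB g/L, platelets 10⁹/L, N% as a
0–100 percentage, cell counts 10⁹/L, total bilirubin µmol/L.  Score
thresholds quoted in older units are converted once at model
construction (CRP ×10 from mg/dL; bilirubin ×17.104 from mg/dL, the
factor implied by bilirubin's 584.66 g/mol molar mass; platelets ×10
from 10⁴/mm³), so scoring never sees mixed units.  The CSV reader
requires an explicit unit declaration per lab column rather than
trusting column labels, because published tables occasionally label a
column with one unit while the printed magnitudes belong to another.

Missing data are first class.  Ratio-based scores in particular lose
patients to incomplete differential counts in real cohorts (~15% in
the reference validation study), so NLR and PLR are derived quantities
that propagate missingness instead of erroring.

## Scoring semantics

Criteria compare one variable against one threshold with the
comparator printed in the source table, taken literally: `≥`/`≤`
inclusive, `>`/`<` strict.  The distinction matters at real
boundaries — platelets of exactly 300×10⁹/L satisfy Kobayashi's
"PLT ≤ 300" but not Egami's "PLT < 300"; age of exactly 6 months
satisfies Egami's "≤ 6 mo" but not the `ours` model's "< 6 months".
Age is treated as a real number of months.

Two missing-data policies are provided.  Under the default
`indeterminate` policy a patient is classified **high** only when the
points already earned guarantee the cutoff, **low** only when meeting
every unevaluable criterion still could not reach it, and
**indeterminate** otherwise; indeterminate patients are excluded from
that model's 2×2 table (and counted), which mirrors how validation
studies report per-model exclusions.  `treat_as_unmet` scores missing
criteria as zero points and classifies everyone — useful as a
sensitivity analysis.

The Kobayashi cutoff defaults to 3 (as in the validation study this
package is organized around) with the original publication's 4
selectable.  The Kawamura rule defaults to requiring both NLR ≥ 3.83
and PLR ≥ 150 (`both_required`), since the combination was reported
more effective than either predictor alone; `either_sufficient` is
exposed because "more than one predictor" is ambiguous in prose
descriptions of the rule.

## Diagnostic accuracy

Sensitivity, specificity, PPV and NPV are exact integer ratios of the
2×2 counts; a zero denominator yields *undefined* (reported as
missing) rather than zero or an error.  Proportion CIs are Wilson
score intervals (Clopper–Pearson would be a drop-in alternative; the
validation literature typically reports none for these, so the choice
is ours).  Printed-style output rounds the exact rationals
half-away-from-zero, which reproduces published two-decimal tables
deterministically (e.g. 359/479 → 0.75) where binary floating point
could not.

ROC AUC is the tie-corrected rank statistic — the probability that a
resistant patient outscores a responsive one, ties counting half —
computed from midranks; it equals the trapezoidal area under the
empirical ROC through all thresholds.  AUC is evaluated on the ordinal
score (total points; for the Kawamura rule the number of satisfied
criteria, 0–2), not on the binary stratification: the binary reading
would force AUC = (sens+spec)/2, which is inconsistent with how
published AUCs for these models exceed that bound.  The AUC interval
is DeLong's asymptotic CI from empirical placement values, truncated
to [0,1]; with perfect separation the variance is zero and the
interval collapses.  Tests verify the AUC against exhaustive pairwise
counting, the identity AUC = (sens+spec)/2 for binary scores, and the
DeLong interval against a looped structural-components oracle and a
2000-replicate stratified bootstrap (agreement within 0.02 required).

AUC is computed over labeled patients whose score inputs are complete
(only then is the ordinal score exact); the 2×2 table uses the
slightly larger set of patients whose *classification* is determinate.
With no missingness the two sets coincide.

## Group comparison

Continuous variables are summarized as median (Q1, Q3) using linear
interpolation between order statistics (the common package default;
the convention is documented because sources rarely state one) and
compared with a two-sided Mann–Whitney U test — exact when both groups
are ≤ 25 without ties, otherwise the tie-corrected normal
approximation without continuity correction.  Categorical variables
are n (%) with a 2×2 chi-square test (no Yates correction), switching
to Fisher's exact test when any expected cell count is below 5 (the
threshold is configurable).  Percentages default to within-group
denominators; a `total_cohort` mode reproduces table layouts where the
two group percentages sum to the overall prevalence.  No
multiple-testing adjustment is applied.

## Synthetic cohort generator

The generator's defaults encode the group-conditional structure of a
real 504-patient validation cohort (25 resistant): 5% incidence,
resistant children younger with higher CRP/AST/N%/TB and lower ALB.
Sampling is group-first — label ~ Bernoulli(0.05), then every variable
from its group-conditional distribution:

- Positive skewed labs (CRP, ALT, AST, PLT, N%, TB, age, WBC):
  log-normal with `mu = ln median`, `sigma = (ln Q3 − ln Q1)/(2 z₀.₇₅)`.
  This matches the target median exactly and the quartile *ratio*
  exactly; a two-parameter family cannot also pin both quartiles
  individually, so calibration checks compare medians and Q3/Q1.
- Na and ALB (near-symmetric physiological ranges): normal truncated
  at zero with `loc = median`, `scale = IQR/(2 z₀.₇₅)`.
- N% is clipped to [0,100]; the clip point lies above the resistant
  group's fitted Q3, so calibrated quantiles are unaffected.
- Neutrophil and lymphocyte counts derive from one WBC draw
  (13 (10, 17) ×10⁹/L, a plausible acute-phase value — WBC is not in
  the calibration targets) and the sampled N%, with a fixed 8%
  monocyte/eosinophil remainder: `neut = wbc·N%/100`,
  `lymph = wbc·max(100−N%−8, 0.5)/100`.  N%, NLR and PLR are thereby
  mutually consistent; NLR and PLR are *derived*, not independently
  calibrated (their printed group quantiles cannot be matched
  simultaneously under within-group independence).
- Signs, sex and KD type are group-conditional Bernoulli draws at the
  published group frequencies; illness day is a rounded normal
  (means 6.8/6.2 days, SD 2.0) floored at 1.
- Missingness is MCAR, independent per variable, default zero; a
  preset sets lymphocyte-count missingness to 76/504 ≈ 15% to exercise
  ratio-score exclusions.

Variables are sampled independently within a group (no copula).  Real
labs correlate — CRP with N%, AST with ALT — so joint-criterion score
distributions (e.g. Sano's) are only approximate; passing calibration
shows marginal fidelity, not joint fidelity.  Cohorts are bitwise
reproducible from the seed.

`calibration_check` compares group medians (default relative tolerance
5%), quartile ratios (15%), sign prevalences (2 percentage points) and
the resistant fraction (3 binomial SDs) against the spec.  At the
realistic 5% incidence the resistant group of a 20,000-patient cohort
has ~1,000 members, where the widest-spread targets (resistant age,
IQR 5.5–42.5 months) have sampling SE near the median tolerance — the
per-target verdicts report the observed deviations so borderline cases
are visible.

## Pipeline

`evaluate_models_on_cohort` applies every selected model to every
patient and reports, per model: all score results, the 2×2 table with
exclusion counts, metrics with CIs, and the score AUC.  Exclusion is
per model, never listwise — a patient missing only lymphocyte data
still counts for the five scores that do not need it — and the counts
always conserve: tp+fp+fn+tn + excluded + unlabeled = cohort size.
`run_pipeline` wraps this in a deterministic artifact bundle
(cohort echo, comparison table, accuracy table, JSON report, log with
every excluded patient id and its missing variables), written
atomically so interrupted runs leave no truncated CSVs.

## Problem sizes

The shipped tests run the full suite in well under a minute: exact
oracles at n ≤ 12–20, monotonicity over 10⁴ perturbations, calibration
and determinism at n = 20,000, parameter recovery at n = 50,000, and
the bootstrap comparison at n = 2,000 with 2,000 replicates.

## Known limitations

- Within-group independence of labs (above) — the main fidelity gap.
- The generator does not target the published p-values or AUCs; those
  depend on patient-level distributions that are not public.  (That
  the synthetic per-model AUC ordering nevertheless resembles the
  published one is an emergent property of the group separations, not
  a calibrated target.)
- Illness day is taken as given; no date arithmetic.
- MCAR missingness only; real incomplete data are plausibly informative.
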
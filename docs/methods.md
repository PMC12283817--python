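# Methods

## Model structure

The model is a decision tree evaluated in expectation (no state cycling: the
20-week horizon is a single episode). Every strategy is evaluated on the same
two-stratum population — a high-risk stratum (probability 0.558, depression
prevalence 0.171, non-depressed EQ-5D 0.869, GP-visit probability 0.780) and
a low-risk stratum (prevalence 0.01715, EQ-5D 0.910, GP-visit 0.642) — so
per-person costs and QALYs are directly comparable across strategies. The
low-risk prevalence is the value implied by the whole-sample (0.103) and
high-risk prevalences given the 0.558 split, not the independently rounded
1.7%: this preserves overall prevalence when the cohort is divided and
reproduces the published projection counts exactly. Whole-population
strategies (no case finding, universal) apply whole-sample operating
characteristics within both strata; the targeted strategy applies the
high-risk-subgroup operating characteristics in the high-risk stratum and
standard care in the low-risk stratum. An alternative single-stratum
evaluation on whole-sample parameters is available
(`evaluate(..., population="whole")`) but is not the default, because
utilities differ by stratum and mixing stratified and unstratified strategies
would make QALY comparisons incoherent.

### Identification

With case finding, every woman in the screened stratum is tested:
P(TP) = prev·sens, P(FP) = (1−prev)(1−spec). Under standard care a depressed
woman is identified with the standard-care sensitivity (0.501), while a
non-depressed woman can only be misidentified if she visits a GP, so the
visit probability multiplies the false-positive pathway only:
P(FP) = (1−prev)·p_visit·(1−spec_std). This asymmetry is required to
reproduce the published 600,000-woman outcome counts (e.g. 30,962 = 61,800 ×
0.501 but 72,665 = 538,200 × 0.722 × 0.187) and is retained as printed.

### Costs

Unit costs are built from staff minutes and per-minute rates exactly as
printed (Whooley £1.57; EPDS/PHQ-9 £3.26; midwife further assessment £55 for
every screen-positive; facilitated self-help £273.44; intensive
psychological therapy £909.69; sertraline plus monitoring £300.26; combined
£935.34; false positives incur 20% of the FSH cost, £54.69; GP consultation
£39.23 for 9.22 min). Money is rounded half-up to the penny at unit-cost
boundaries; expected values are never rounded mid-computation.

Two costing conventions deserve note:

* **Two-stage screening is costed for all screened women** (the
  `first_stage_positive_rate` field defaults to 1.0). The published
  trebled-administration-time scenario raises the universal strategy's cost
  by exactly 2 × (£1.57 + £3.26) = £9.66 per woman, which identifies this as
  the original costing convention; gating the second stage on first-stage
  positivity is available by setting the field to the observed positivity.
* **All persistent false negatives visit a GP mid-horizon** (week 10),
  incurring one assessment consultation; 10% of them are identified and
  treated. In standard-care arms, every woman who visits a GP (at the
  stratum visit rate) additionally incurs one assessment consultation. Both
  conventions are consistent with the published scenario deltas for longer
  GP consultations.

### Utility trajectories

All trajectories are piecewise linear on [0, 20] weeks and integrate exactly
by the trapezoid rule (QALYs = area/52). Depressed-state utilities are
proportional decrements on the stratum non-depressed mean: 12% (mild),
26% (moderate–severe).

| pathway | trajectory |
|---|---|
| true negative | flat non-depressed |
| false positive | flat non-depressed (×(1−d) under the FP-decrement scenario) |
| TP responder | severity utility → non-depressed, linear over the 8-week course, then flat |
| TP non-responder | flat at severity utility |
| FN spontaneous recovery (35%) | severity utility → non-depressed over 7 weeks, then flat |
| FN identified at week 10, responder | flat to week 10, then the treatment ramp (complete at week 18) |
| FN identified, non-responder | flat at severity utility |
| FN never identified, mild | linear decline from mild to moderate–severe utility over the full horizon (untreated depression worsens) |
| FN never identified, mod–severe | flat at moderate–severe utility |

The untreated-mild decline shape (linear over the whole horizon) is a
modelling choice; only its integral matters for results.

### Treatment effects

Recovery probabilities are derived as baseline × relative risk and carried
unrounded: FSH 0.38×1.59 = 0.6042; IPT no-recovery 0.64×0.69 = 0.4416;
sertraline 0.43×1.27 = 0.5461; combined 0.43×1.47 = 0.6321. The printed
two-decimal sertraline pair (0.54/0.46) is internally consistent only with
an unrounded placebo baseline slightly below 0.43, so agreement with the
printed values is to one unit in the second decimal. Moderate–severe cases
split across IPT only / sertraline only / both at 12.8% / 52.3% / 34.9%.

## Synthetic cohort generator

The generator's defaults are the study conditions; they are not tuning
knobs.

* **Risk factors** come from an equicorrelated Gaussian-latent (probit)
  model: factor j is present when √ρ·c + √(1−ρ)·e_j exceeds the threshold
  matching its marginal (2.8%, 35.3%, 34.0%, 18.2%). A single association
  parameter ρ is calibrated by bisection so that P(at least one factor)
  = 0.558; the union probability is computed exactly by Gauss–Hermite
  quadrature over the shared factor, so the calibration is deterministic
  (ρ ≈ 0.4048; independence would give 0.66). Attainable targets lie
  between the largest marginal (perfect association) and the independence
  bound.
* **Instrument responses** load on a latent distress trait,
  N(α·highrisk + dep·(μ + γ·highrisk) + δ·modsev, 1), with
  instrument-specific noise (SD 0.7) and calibrated cut-points. The five
  free parameters (two cut-points, α, μ, γ) are solved — again by
  deterministic quadrature — so that the two-stage Whooley→PHQ-9 strategy
  attains exactly sens/spec 74.2%/85.0% in the high-risk stratum and
  70.6%/89.5% in the whole sample, and single-stage Whooley specificity is
  68% in the high-risk group. The interaction term γ is needed because the
  printed whole-sample and high-risk values jointly imply a much lower
  chain sensitivity among low-risk depressed women (~25%) than high-risk
  ones; a risk-status shift common to depressed and non-depressed women
  cannot satisfy all four targets. EPDS cut-points are set so EPDS≥10
  passes the inclusion filters (sens ~80%) while EPDS≥13 fails on
  sensitivity (~62%). Integer scores are laid out affinely around the
  calibrated cut-points and clipped to the instrument ranges (0–30 EPDS,
  0–27 PHQ-9).
* **Utilities** are the stratum non-depressed mean (0.869/0.910) times the
  severity decrement, plus N(0, 0.03) individual noise clipped to [0, 1].
  The noise SD is deliberately modest so that clipping at the upper bound
  leaves group means effectively unbiased (bias ≈ 10⁻⁵ at a 0.910 mean);
  real EQ-5D index values are more dispersed and left-skewed, which the
  generator does not emulate.
* **Not emulated**: item-level instrument responses; LTE-Q partial
  missingness (a `life_event_missing_rate` flag exists, default 0);
  longitudinal postnatal follow-up; covariate-dependent treatment uptake.
  One structural artefact is unavoidable: in the generator, a chain's
  positives are a subset of each stage's positives, so single-stage PHQ-9
  sensitivity always exceeds the chain's — the published data report
  single-stage PHQ-9 sensitivity below 70% alongside a 74.2% chain, which
  no coherent joint distribution can reproduce. Passing recovery tests
  therefore demonstrate that the pipeline estimates what the generator
  encodes, not that the generator matches every feature of real cohorts.

## Derivation

All proportions carry Wilson score 95% intervals (via statsmodels), which
are bounded in [0, 1] and clamped to bracket the point estimate; the printed
high-risk interval (50.7–60.7% at 218/391) reproduces to ±0.5 points.
Strategy inclusion requires sensitivity ≥ 70% and specificity ≥ 60%, both
inclusive. Depressed-state utilities are decrement-derived from stratum
non-depressed means rather than estimated directly from depressed records,
mirroring the model's parameterisation.

## Probabilistic sensitivity analysis

Each of 24 probability/utility parameters is drawn from a beta distribution
matched by method of moments to its point estimate and SE (SE from a printed
95% CI as width/3.92, including asymmetric CIs); unit costs are fixed.
Derived treatment-effect probabilities are sampled directly on the derived
probability using its printed CI (not by sampling the relative risk). The
three-way treatment mix is drawn componentwise and renormalised to sum to
one. The stratified prevalences and the high-risk proportion are drawn and
the whole-sample prevalence recomputed from them, keeping every draw
internally consistent (drawing the low-risk prevalence directly also keeps
it non-negative, which back-solving from a drawn whole-sample prevalence
would not). The GP-identification probability for missed cases (0.10,
expert opinion, no SE) is fixed. Draws are common across strategies within
an iteration; 95% intervals are percentile-based (2.5/97.5); CEAC ties in
net monetary benefit are split equally so the probabilities across
strategies sum to one at every threshold.

Operating-characteristic SEs for the modelled two-stage strategy are not
printed; defaults use binomial SEs at the source cohort's approximate
stratum sizes (≈40/351 whole-sample and ≈37/181 high-risk depressed/
non-depressed women). Because draws are common and the universal strategy's
cost advantage (~£9/person) is large relative to parameter uncertainty, the
base-case CEAC concentrates on the universal strategy more strongly than a
model with independent draws or additional structural uncertainty would;
the qualitative ordering (universal highest, no case finding lowest at
£20,000/QALY) is the robust output.

## Numerical choices and problem sizes

Trapezoidal integration is exact for the piecewise-linear trajectories.
Branch probabilities must sum to 1 within 1e-9 per arm or evaluation
aborts. Incremental analysis sorts by cost with label tie-breaks, applies
strict dominance, then removes extendedly dominated options iteratively
until frontier ICERs strictly increase. Projection counts round half-up,
with true negatives taken as the block remainder so counts sum to the
cohort size. Test and acceptance runs use a 100,000-woman cohort (marginals
recover within ±0.005, conditional prevalences within ±0.01, estimates
within 2 Monte-Carlo SEs), a 200,000-walk microsimulation cross-check
(agreement within 3 Monte-Carlo SEs per strategy), and 2,000 PSA
iterations; all sizes are package defaults chosen to keep Monte-Carlo error
well inside the assertion tolerances.

## Limitations

The horizon stops at birth: persistent postnatal depression, infant and
partner outcomes, and repeat screening are out of scope. Treatment is a
single episode without sequencing or adherence. Efficacy parameters derive
from postnatal populations. The no-case-finding arm's printed per-person
mean cannot be decomposed uniquely from published information; the
implemented composition (assessment consultations for all GP visitors plus
the pathway costs above) reproduces the published *differences* between
strategies closely (universal saves £8.79/person here vs £8.86 published;
targeted exceeds no case finding by £0.83 vs £0.71) while sitting ~£4.6
below the published absolute level in all three arms, and the branch-level
audit table makes the composition inspectable. Strategy-level results
(dominance pattern, scenario classifications, ICER orders of magnitude) are
insensitive to this level shift.
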
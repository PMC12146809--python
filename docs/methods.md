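# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## SUV quantification

Body-weight SUV only: SUV = C · w / D, with activity concentration C in
Bq/mL, weight w in grams, and the injected dose D decay-corrected from
injection to scan start, D = D₀ · 2^(−Δt/T½) (T½ = 6586.2 s for ¹⁸F).
Lean-body-mass and body-surface-area variants are out of scope, since
the SUV ≥ 4 threshold tradition this package implements is defined on
body-weight SUV. Decay correction composes over split intervals and the
conversion is linear in C and w and inverse in D; both properties are
asserted as invariants. Vendor images already scaled to SUV pass
through unchanged with a metadata flag.

## TMTV segmentation

Lesions are the 26-connected components (configurable: 6/18) of the
voxel set {SUV ≥ threshold}, threshold 4.0 *inclusive*. TMTV is the
total retained voxel count times the voxel volume — computed from the
total count, not by summing per-lesion floats, so that equality against
a phantom's voxel-count truth is exact rather than within rounding.
Operator judgments are replaced by deterministic rules, each recorded in
an audit log:

- **Exclusion**: a component is removed when strictly more than 50% of
  its voxels lie in the physiological-uptake mask (brain, bladder,
  heart, …). Majority overlap is a reproducible stand-in for the
  operator's per-volume decision.
- **Spleen**: involved if a thresholded component lies inside the organ
  (focal), or if the organ-mean SUV strictly exceeds 1.5× the liver
  background (diffuse), the liver background being the mean SUV over a
  supplied VOI (a 3-cm-sphere builder is provided). Diffuse involvement
  contributes the whole anatomical organ volume by default — how diffuse
  organ involvement is conventionally volumed — and can be switched to
  thresholded voxels only. Neither the connectivity, the liver VOI
  definition, nor the diffuse-spleen volume convention is fixed by the
  segmentation standard; all three are explicit, configurable choices
  here, not claims about any particular reading center.
- **Marrow**: components majority-inside the marrow mask count only when
  flagged focal; diffuse marrow uptake contributes nothing. Focality is
  an operator input; a volume-fraction heuristic auto-flagger exists for
  simulation use only.
- No minimum lesion volume by default; configurable for sensitivity
  analyses.

The legacy 41%-of-SUVmax mode detects lesions with the absolute
threshold, then regrows each at 0.41 × its SUVmax inside a dilated
bounding region, keeping the component containing the lesion peak.
Voxels are never double-counted across lesions.

## Synthetic cohorts

The simulator reproduces the distributional facts the survival analyses
rest on; defaults are fixed once and are not tuning knobs.

- **TMTV**: two-piece lognormal — log-scale SD 1.734 below the median
  and 1.304 above, median 161 mL. A single lognormal cannot satisfy
  median 161 mL with quartiles 50 and 388 mL (the two quartiles imply
  incompatible spreads), while the two-piece form reproduces all three
  quantiles exactly and yields ≈47% of subjects above 180 mL and ≈8.6%
  in the 180–240 mL band. The density has a step at the median; for a
  marginal-distribution emulator this is immaterial.
- **Covariates**: independent Bernoulli draws at the published
  prevalences (age>60 50%, B2M>ULN 55%, BM+ 55%, Hb<12 16%, LoDLIN>6 cm
  55%, male 46%, experimental arm 52%, R-B 42%). Independence puts
  P(FLIPI2 ≥ 3) at 0.43, inside the observed ≈40% without imposing a
  correlation structure. Classical-FLIPI factors not published for this
  population (stage III–IV, LDH>ULN, >4 nodal areas) are set to
  0.85/0.25/0.55, typical of high-tumor-burden follicular lymphoma.
- **Hazard**: exponential baseline (Weibull optional) with a step
  log-HR ln 1.6 above τ\* = 180 mL — a change-point effect, matching the
  dichotomized analyses the package validates — plus ln 2.0 for
  FLIPI2-high and ln 1.3 for male sex. A smooth per-500-mL log-linear
  alternative supports spline tests. The baseline rate is *solved*, not
  sampled: quadrature over the covariate mixture pins the marginal
  5-year PFS at 67% (OS model analogously at 93%). PFS is generated
  directly as the composite endpoint; OS comes from its own marginal
  model, and joint consistency between the two endpoints is not
  enforced.
- **Censoring**: uniform accrual over 64 months with an administrative
  cutoff at 89 months gives potential follow-up U(25, 89) — median 57
  months — with no dropout model.
- **Reader noise**: multiplicative lognormal with unit mean and stated
  CV (σ² = ln(1+cv²)), the natural model for proportional measurement
  error in volume reading.

What passing tests on these cohorts do **not** show: robustness to
correlated risk factors, informative censoring, non-proportional
hazards, competing mortality, or real scanner effects (no partial-volume
blur, no reconstruction noise unless the optional Gaussian blur is
switched on). The phantoms likewise have uniform-uptake geometric
lesions; exactness there validates the bookkeeping, not segmentation of
realistic texture.

## Survival engine

Cox fits use Efron tie handling with optional stratification by
randomization arm (lifelines backend); CIs are 95% Wald on the log
scale; AIC = −2ℓ + 2p with p the number of regression columns. The
log-rank test is computed directly (observed−expected with the
hypergeometric variance including the ties factor, summed over strata)
because a stratified version is needed throughout. The maximally
selected statistic uses the Cox *score* test for each candidate
indicator evaluated at the null model's estimates, with the adjusters'
information partialled out — a Breslow-form variance without the
finite-population ties correction; at distinct event times it equals the
classical log-rank, which is asserted as an invariant.

Restricted cubic splines use Harrell's truncated-power restricted basis
with his recommended quantile placements (k=3: 0.10/0.50/0.90 … k=7:
0.025/…/0.975), normalized by (t_k−t_1)². Because the cubic columns of
a heavy-tailed covariate are severely collinear, spline Cox fits run on
a QR-orthonormalized centered basis and map coefficients back — the fit
(log-likelihood, AIC, fitted curve) is invariant to this
reparametrization, but without it the Newton iterations genuinely fail
at k ≥ 5. Knot count is chosen by minimum mean AIC over with-replacement
resamples.

Harrell's c counts pairs comparable under right censoring (event i with
t_i < t_j, or t_i = t_j with j censored; score ties count ½), computed
by a vectorized all-pairs pass whose row sums give the exact leave-one-out
jackknife in the same O(n²) sweep; the CI is normal-theory on the
jackknife variance. The resample/out-of-bag split leaves out (1−1/n)ⁿ →
36.8% of records in expectation.

## Cutoff derivation

- **Maximally selected log-rank**: candidates are the unique TMTV values
  between the 10th and 90th percentiles (protecting group sizes); ties
  go to the smallest cutoff. No small-sample p-value correction
  (Lausen–Schumacher) is applied — the internal validation below is the
  guard against selection optimism. Users should expect substantial
  sampling variability of the argmax at moderate effect sizes: in
  simulations at HR 1.6, n=700, the estimate lands within ±20% of the
  true change point in only ~two-thirds of replicates (and essentially
  always at HR 2.0 or n=2000); this is a property of maximally selected
  statistics, not of the implementation.
- **Time-dependent ROC**: cumulative/dynamic cases and controls at a
  36-month horizon (configurable; 36 months matches a 3-year PFS
  classification horizon), censoring handled by inverse-probability-of-
  censoring weights from the Kaplan–Meier estimate of the censoring
  distribution; the cutoff maximizes sensitivity × specificity. The
  criterion attributed to Liu is operationalized exactly this way and
  isolated behind the function boundary, since the literature names the
  method without fixing the weighting details.
- **Spline crossing**: the fitted spline log-HR curve, referenced to the
  cohort median, is searched upward from the reference for a zero
  crossing from below (bisection to 0.1 mL). For a monotone fitted
  curve — which is what a smoothed step effect produces — the crossing
  degenerates to the reference itself and is flagged as such; if the
  curve never becomes positive, "no cutpoint" is reported rather than an
  arbitrary value. Consequently this method's apparent accuracy partly
  reflects the cohort median (≈161 mL) sitting near the true change
  point (180 mL); the degenerate flag makes that visible. Under a null
  effect the method declines to assert an interior cutoff (degenerate or
  no-crossing) in most replicates.
- **Consensus**: each method's candidate, rounded to a configurable
  grid, is evaluated in the reference (standard-therapy) stratum by the
  log-rank statistic of the dichotomized split; the largest statistic
  wins and the full evaluation table is returned. Near-equivalent
  candidates (e.g. 171 vs 181 when τ\*=180) are decided by sampling
  noise; the table, not just the winner, is the real output.
- **Internal validation**: bootstrap stability (distribution of the
  re-derived cutoff across resamples) and out-of-bag hazard ratios —
  per resample the cutoff is applied (or re-derived in-bag) and a
  dichotomized Cox model is fit on the ~37% out-of-bag subjects;
  log-HRs are pooled as mean with an empirical 95% interval.

## Prognostic models

FLIPI2 counts five adverse factors, high risk at ≥3 (the eligible
population has score >0, so the remainder is reported as
"intermediate"). The combined model counts two adverse features — TMTV
above the cutoff and FLIPI2-high — into low/intermediate/high groups.
POD24 is an event within 24 months of registration (origin
configurable), among subjects with either such an event or ≥24 months
of potential follow-up; the 2×2 comparison uses Fisher's exact test by
default, chi-squared by flag. Model discrimination gain is reported as
Δc with jackknife CIs on each c plus a likelihood-ratio test of the
added term.

The bootstrap inclusion fraction (retention of the TMTV term across
resamples under LRT p<0.05 and under AIC) is reported as defined, with a
caveat: for a *null* term its expectation is ≈0.12–0.17, not the test
size, because a resample's z-statistic is inflated ≈√2 relative to an
independent replicate. Type-I calibration statements therefore require
independent replicates, which is how the package's null-calibration
check measures it.

Bland–Altman agreement reports bias and 1.96-SD limits of agreement on
the mL scale, and the repeatability coefficient of variation in the
within-subject form for proportional error, CV% = 100·√(mean((dᵢ/mᵢ)²)/2)
over reader pairs. The naive SD(d)/(√2·mean) form is not scale-free and
would be dominated by the largest tumors under a heavy-tailed volume
distribution (evaluating to ~3× the true reader CV); the ratio form
returns the generating CV regardless of scale.

`run_full_analysis` executes the whole chain and emits canonical JSON
(sorted keys, rounded floats): identical configuration and seed produce
byte-identical reports. Default problem sizes — n=689, B=200 bootstrap
resamples, 50 resamples for knot selection — run in about a minute on
one CPU; B=1000 reproduces the classical bootstrap counts at
proportionally higher cost. Stage failures are caught per stage and
reported in place of that section.

## Known limitations

- Organ masks are inputs; no automatic organ segmentation or CT
  registration.
- The DICOM reader covers standard radiopharmaceutical tags only; no
  vendor private-tag handling or EARL harmonization.
- The simulator's independence assumptions (factors ⊥ TMTV, PFS ⊥ OS
  given covariates) make it a testbed, not a population model.
- c-Harrell is computed in-sample; adding any term carries a small
  positive optimism bias (~0.007 for one null df at n=400 in our null
  simulations), which the null-calibration check bounds but does not
  remove.
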
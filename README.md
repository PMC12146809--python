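# tmtvkit

Baseline total metabolic tumor volume (TMTV) on FDG-PET is a candidate
prognostic biomarker in high-tumor-burden follicular lymphoma: patients
whose summed lesion volume at diagnosis is large progress earlier under
immunochemotherapy. `tmtvkit` implements the full quantification and
biostatistics chain needed to study this marker —

1. **PET quantification** (`pet_suv`): body-weight standardized uptake
   value, SUV = C·w/D with C the activity concentration (Bq/mL), w the
   body weight (g) and D the injected dose decay-corrected to scan start
   (D = D₀·2^(−Δt/T½), T½ = 6586.2 s for ¹⁸F). NIfTI-1 IO with JSON
   metadata sidecars; optional DICOM PET series reader.
2. **TMTV segmentation** (`tmtv_segmentation`): the standardized fixed
   absolute threshold SUV ≥ 4 with 26-connected lesion individuation,
   deterministic physiological-uptake exclusion (majority-overlap rule),
   the spleen rule (focal uptake, or diffuse uptake > 150% of the liver
   background mean), the marrow focality rule, and the legacy 41%-SUVmax
   per-lesion relative threshold for comparison with historical cutoffs.
3. **Survival engine** (`survival_core`): Kaplan–Meier, stratified
   log-rank, stratified Cox PH (Efron ties, via lifelines), restricted
   cubic splines with Harrell quantile knots and bootstrap minimum-AIC
   knot selection, Harrell's c with jackknife CIs, and bootstrap /
   out-of-bag (≈36.8%) resampling.
4. **Cutpoint derivation** (`cutpoint_pipeline`): three survival-based
   estimators of a prognostic TMTV cutoff — maximally selected
   (adjusted, stratified) log-rank statistic; time-dependent ROC at a
   clinical horizon with IPCW weighting, maximizing sensitivity ×
   specificity (Liu criterion); and the zero-crossing of a spline Cox
   log-HR curve — plus consensus selection in the reference arm,
   bootstrap stability, and out-of-bag hazard-ratio validation.
5. **Prognostic models** (`prognostic_models`): FLIPI/FLIPI2 scoring,
   the combined TMTV×FLIPI2 three-group risk model, POD24 (progression
   within 24 months, Fisher exact), Δc-Harrell model comparison,
   bootstrap inclusion fractions, Bland–Altman inter-reader agreement,
   and a deterministic end-to-end report generator.
6. **Synthetic data** (`synthetic_data`): digital phantoms with exact
   voxel-count truth and simulated cohorts with the distributional
   structure the analyses assume (two-piece lognormal TMTV, median
   161 mL, IQR 50–388 mL; change-point hazard HR 1.6 above 180 mL;
   5-year PFS 67%; ~57-month median follow-up), so every stage is
   testable without patient data.

## Worked example

```python
import numpy as np
from tmtvkit import (CohortSpec, generate_cohort, generate_phantom,
                     compute_tmtv, to_suv, maxstat_cutpoint,
                     roc_cutpoint_liu, cox_fit)
from tmtvkit.synthetic_data import random_lesion_phantom

# --- phantom -> SUV -> TMTV (exact against the voxel-count truth)
spec = random_lesion_phantom(seed=3)
vol, meta, truth = generate_phantom(spec, seed=3)
result = compute_tmtv(to_suv(vol, meta))
print(result.tmtv_ml, truth.true_tmtv_ml)   # 56.768 56.768

# --- simulated cohort -> cutoff derivation -> dichotomized hazard ratio
df = generate_cohort(CohortSpec(n=689, seed=2))
print(round(np.median(df.tmtv_ml), 1))       # 168.8
print(round(maxstat_cutpoint(df).cutoff_ml)) # 143
print(round(roc_cutpoint_liu(df).cutoff_ml)) # 192
work = df.assign(above=(df.tmtv_ml > 180).astype(int))
m = cox_fit(work, ["above"], strata="arm")
print(round(float(m.hr["above"]), 2))        # 1.66
```

The phantom TMTV equals the generator's truth to the voxel; on the
simulated cohort the ROC cutoff estimator lands near the true 180 mL change
point (the maximally selected statistic scatters more widely, as the
methods note discusses) and the dichotomized Cox model recovers the simulated hazard ratio
of 1.6 (here 1.66 with 95% CI 1.27–2.16).

A shell interface wraps the same functions:

```bash
tmtvkit simulate-cohort --n 689 --seed 2 --out cohort.csv
tmtvkit cutpoint --cohort cohort.csv --methods maxstat,roc,rcs --out cut.json
tmtvkit analyze --cohort cohort.csv --seed 2 --out report.json
```

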
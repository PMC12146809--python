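"""Prognostic TMTV cutoff derivation and internal validation.

Three survival-based methods locate a cutoff on the TMTV axis:

1. **Maximally selected log-rank** — the adjusted, stratified Cox score
   statistic for 1{TMTV > c} is evaluated over a candidate grid (unique
   TMTV values between the 10th and 90th percentiles by default) and the
   argmax is returned.
2. **Time-dependent ROC (Liu)** — cumulative/dynamic sensitivity and
   specificity at a clinical horizon (default 36 months) are estimated
   with inverse-probability-of-censoring weights; the cutoff maximizes
   the product sensitivity x specificity.
3. **Restricted cubic spline** — a spline Cox fit of TMTV (knot count
   from bootstrap AIC selection) gives a continuous log-HR curve relative
   to the cohort median; the cutoff is where the curve crosses zero from
   below on the upper side of the reference (bisection to 0.1 mL).  For a
   monotone fitted curve the crossing degenerates to the reference itself
   and is flagged.

A consensus step evaluates the candidate cutoffs in the reference
stratum and picks the one with the largest log-rank statistic.  Internal
validation uses bootstrap stability of the cutoff and out-of-bag
dichotomized hazard ratios.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .survival_core import (CoxModel, bootstrap_oob_split, cox_fit,
                            cox_score_candidates, fit_rcs_cox, km_estimate,
                            logrank_test, rcs_basis, select_knots_bootstrap)

METHODS = ("maxstat", "auc-roc-liu", "rcs")


@dataclasses.dataclass
class CutpointResult:
    method: str
    cutoff_ml: float | None
    criterion: float | None
    grid: np.ndarray | None = dataclasses.field(default=None, repr=False)
    trace: np.ndarray | None = dataclasses.field(default=None, repr=False)
    degenerate: bool = False
    note: str = ""


@dataclasses.dataclass
class StabilityReport:
    cutoffs: np.ndarray
    median: float
    iqr: tuple[float, float]
    B: int
    seed: int
    n_failed: int


@dataclasses.dataclass
class OobValidation:
    log_hrs: np.ndarray
    pooled_hr: float
    hr_ci: tuple[float, float]
    B: int
    seed: int
    n_skipped: int


def candidate_grid(tmtv: np.ndarray, q_low: float = 0.10, q_high: float = 0.90
                   ) -> np.ndarray:
    """Unique TMTV values between the q_low and q_high quantiles."""
    lo, hi = np.quantile(tmtv, [q_low, q_high])
    vals = np.unique(tmtv)
    return vals[(vals >= lo) & (vals <= hi)]


# ---------------------------------------------------------------------------
# Method 1: maximally selected (adjusted, stratified) log-rank
# ---------------------------------------------------------------------------

def maxstat_cutpoint(df: pd.DataFrame, covariate: str = "tmtv_ml",
                     adjusters: Sequence[str] = (), strata: str | None = None,
                     duration_col: str = "pfs_months", event_col: str = "pfs_event",
                     grid: np.ndarray | None = None) -> CutpointResult:
    """Cutoff maximizing the score chi-square for 1{TMTV > c}.

    With adjusters, the statistic is the score test for adding the
    indicator to a stratified Cox model containing them; without, it
    reduces to the classical (stratified) log-rank.  Ties go to the
    smallest cutoff.
    """
    x = df[covariate].to_numpy(dtype=float)
    if grid is None:
        grid = candidate_grid(x)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty candidate grid")
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    strata_vals = df[strata].to_numpy() if strata else None

    Z = (x[:, None] > grid[None, :]).astype(float)
    if adjusters:
        null_model = cox_fit(df, list(adjusters), duration_col, event_col, strata)
        lp = null_model.linear_predictor(df)
        X = df[list(adjusters)].to_numpy(dtype=float)
        Iinv = null_model.fitter.variance_matrix_.to_numpy()
        U, V = cox_score_candidates(time, event, Z, strata_vals, lp, X, Iinv)
    else:
        U, V = cox_score_candidates(time, event, Z, strata_vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U ** 2 / V, -np.inf)
    best = int(np.argmax(chi2))  # argmax returns the first (smallest) on ties
    return CutpointResult(method="maxstat", cutoff_ml=float(grid[best]),
                          criterion=float(chi2[best]), grid=grid, trace=chi2)


# ---------------------------------------------------------------------------
# Method 2: time-dependent ROC at a horizon (Liu criterion)
# ---------------------------------------------------------------------------

def roc_cutpoint_liu(df: pd.DataFrame, covariate: str = "tmtv_ml",
                     horizon: float = 36.0,
                     duration_col: str = "pfs_months", event_col: str = "pfs_event",
                     grid: np.ndarray | None = None) -> CutpointResult:
    """Cutoff maximizing sensitivity x specificity at the horizon.

    Cumulative/dynamic definition — cases are subjects with an event by
    the horizon, controls those still event-free — with censoring handled
    by inverse-probability-of-censoring weights from the Kaplan-Meier
    estimate of the censoring distribution.  With no censoring before the
    horizon this reduces exactly to the empirical binary-outcome ROC.
    """
    x = df[covariate].to_numpy(dtype=float)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy(dtype=int)
    if not ((time <= horizon) & (event == 1)).any():
        raise ValueError("no events before the horizon")
    if grid is None:
        grid = candidate_grid(x)
    grid = np.asarray(grid, dtype=float)

    # censoring survival G (events of the reversed indicator)
    G = km_estimate(time, 1 - event)
    cases = (time <= horizon) & (event == 1)
    controls = time > horizon
    w_case = np.array([1.0 / max(G.survival_at(t, side="left"), 1e-12)
                       for t in time[cases]])
    sens = ((x[cases][:, None] > grid[None, :]) * w_case[:, None]).sum(axis=0) \
        / w_case.sum()
    spec = (x[controls][:, None] <= grid[None, :]).sum(axis=0) / max(controls.sum(), 1)
    crit = sens * spec
    best = int(np.argmax(crit))
    return CutpointResult(method="auc-roc-liu", cutoff_ml=float(grid[best]),
                          criterion=float(crit[best]), grid=grid, trace=crit,
                          note=f"horizon={horizon} months")


# ---------------------------------------------------------------------------
# Method 3: restricted cubic spline crossing
# ---------------------------------------------------------------------------

def rcs_cutpoint(df: pd.DataFrame, covariate: str = "tmtv_ml",
                 adjusters: Sequence[str] = (), strata: str | None = None,
                 duration_col: str = "pfs_months", event_col: str = "pfs_event",
                 k: int | None = None, knot_selection_B: int = 100,
                 seed: int = 0, reference: float | None = None) -> CutpointResult:
    """Cutoff read off the spline log-HR curve.

    The spline Cox fit gives f(x) = log HR(x) relative to the reference
    (cohort median by default, where f = 0 by construction).  The cutoff
    is the smallest x above the reference where f crosses 0 from below,
    located by bisection to 0.1 mL.  If f is positive immediately above
    the reference (monotone curve) the crossing degenerates to the
    reference and is flagged; if f never becomes positive, no cutpoint is
    reported.
    """
    x = df[covariate].to_numpy(dtype=float)
    if k is None:
        sel = select_knots_bootstrap(df, covariate, adjusters, strata,
                                     duration_col, event_col,
                                     B=knot_selection_B, seed=seed)
        k = sel.selected_k
    _, curve, _ = fit_rcs_cox(df, covariate, k, adjusters, strata,
                              duration_col, event_col)
    ref = float(np.median(x)) if reference is None else float(reference)
    f_ref = float(curve(ref)[0])

    def f(v):
        return float(curve(v)[0]) - f_ref

    hi_support = float(np.quantile(x, 0.95))
    grid = np.linspace(ref, hi_support, 512)
    fv = curve(grid) - f_ref

    if fv[1] > 0:
        return CutpointResult(method="rcs", cutoff_ml=ref, criterion=0.0,
                              degenerate=True,
                              note=f"monotone increasing at reference {ref:.1f} mL; "
                                   "crossing degenerates to the reference",
                              grid=grid, trace=fv)
    # find the first upward zero crossing after the curve has been negative
    crossing_idx = None
    for i in range(1, len(grid) - 1):
        if fv[i] <= 0 < fv[i + 1]:
            crossing_idx = i
            break
    if crossing_idx is None:
        return CutpointResult(method="rcs", cutoff_ml=None, criterion=None,
                              note="no upward zero crossing in data support",
                              grid=grid, trace=fv)
    lo, hi = grid[crossing_idx], grid[crossing_idx + 1]
    while hi - lo > 0.1:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return CutpointResult(method="rcs", cutoff_ml=float(0.5 * (lo + hi)),
                          criterion=0.0, grid=grid, trace=fv,
                          note=f"k={k}, reference {ref:.1f} mL")


# ---------------------------------------------------------------------------
# Consensus and band analysis
# ---------------------------------------------------------------------------

def consensus_cutoff(results: Sequence[CutpointResult], df: pd.DataFrame,
                     covariate: str = "tmtv_ml",
                     duration_col: str = "pfs_months", event_col: str = "pfs_event",
                     reference_col: str = "arm", reference_value: str = "standard",
                     round_to: float = 1.0) -> dict:
    """Pick the working cutoff among the per-method candidates.

    Each candidate (rounded to ``round_to`` mL) is evaluated in the
    reference stratum by the log-rank statistic of the dichotomized
    groups (dichotomized Cox HR reported alongside); the candidate with
    the largest statistic wins.
    """
    candidates = sorted({round(r.cutoff_ml / round_to) * round_to
                         for r in results if r.cutoff_ml is not None})
    if not candidates:
        raise ValueError("no candidate cutoffs")
    sub = df[df[reference_col] == reference_value] if reference_col in df else df
    rows = []
    for c in candidates:
        ind = (sub[covariate] > c).astype(int)
        if ind.nunique() < 2:
            rows.append({"cutoff_ml": c, "logrank_chi2": np.nan, "hr": np.nan,
                         "note": "degenerate split"})
            continue
        chi2, _, p = logrank_test(sub[duration_col], sub[event_col], ind)
        work = sub.assign(_above=ind)
        try:
            m = cox_fit(work, ["_above"], duration_col, event_col)
            hr = float(m.hr["_above"])
            ci = (float(m.ci_lower["_above"]), float(m.ci_upper["_above"]))
        except ValueError:
            hr, ci = np.nan, (np.nan, np.nan)
        rows.append({"cutoff_ml": c, "logrank_chi2": chi2, "logrank_p": p,
                     "hr": hr, "hr_ci": ci})
    table = pd.DataFrame(rows)
    best = table.loc[table["logrank_chi2"].idxmax()]
    return {"chosen_cutoff_ml": float(best["cutoff_ml"]),
            "evaluation": table,
            "reference": f"{reference_col}={reference_value}"}


def band_analysis(df: pd.DataFrame, low: float, high: float,
                  covariate: str = "tmtv_ml",
                  duration_col: str = "pfs_months", event_col: str = "pfs_event",
                  strata: str | None = "arm") -> dict:
    """Three-band split {<=low, (low, high], >high}: occupancy, KM and HRs."""
    if low >= high:
        raise ValueError("low must be < high")
    x = df[covariate].to_numpy(dtype=float)
    band = np.where(x <= low, "low", np.where(x <= high, "mid", "high"))
    n = len(df)
    occupancy = {b: float((band == b).mean()) for b in ("low", "mid", "high")}
    out = {"occupancy": occupancy, "n": n, "bands": {}}
    strata_values = df[strata].unique() if strata and strata in df else [None]
    for s in strata_values:
        sub = df if s is None else df[df[strata] == s]
        b = band if s is None else band[(df[strata] == s).to_numpy()]
        entry = {}
        for name in ("low", "mid", "high"):
            m = b == name
            if m.sum() == 0:
                entry[name] = {"n": 0, "note": "empty band"}
                continue
            km = km_estimate(sub[duration_col][m], sub[event_col][m])
            entry[name] = {"n": int(m.sum()),
                           "surv_60m": km.survival_at(60.0)}
        # pairwise HRs vs the low band
        for name in ("mid", "high"):
            m = (b == name) | (b == "low")
            work = sub[m].assign(_grp=(b[m] == name).astype(int))
            try:
                fit = cox_fit(work, ["_grp"], duration_col, event_col)
                entry[f"hr_{name}_vs_low"] = float(fit.hr["_grp"])
            except ValueError as exc:
                entry[f"hr_{name}_vs_low"] = None
        out["bands"][str(s)] = entry
    return out


# ---------------------------------------------------------------------------
# Bootstrap stability and out-of-bag validation
# ---------------------------------------------------------------------------

def bootstrap_stability(df: pd.DataFrame, derive: Callable[[pd.DataFrame], float | None],
                        B: int = 200, seed: int = 0) -> StabilityReport:
    """Distribution of the cutoff re-derived on bootstrap resamples."""
    rng = np.random.default_rng(seed)
    n = len(df)
    cutoffs = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            c = derive(df.iloc[idx].reset_index(drop=True))
        except ValueError:
            c = None
        if c is None:
            failed += 1
        else:
            cutoffs.append(float(c))
    arr = np.asarray(cutoffs)
    if arr.size == 0:
        raise ValueError("cutoff derivation failed on every resample")
    q25, q75 = np.quantile(arr, [0.25, 0.75])
    return StabilityReport(cutoffs=arr, median=float(np.median(arr)),
                           iqr=(float(q25), float(q75)), B=B, seed=seed,
                           n_failed=failed)


def oob_validate(df: pd.DataFrame, cutoff: float, B: int = 200, seed: int = 0,
                 covariate: str = "tmtv_ml",
                 duration_col: str = "pfs_months", event_col: str = "pfs_event",
                 strata: str | None = None,
                 rederive: Callable[[pd.DataFrame], float | None] | None = None
                 ) -> OobValidation:
    """Out-of-bag hazard ratios for the dichotomized cutoff.

    Per resample the cutoff is either applied as given or re-derived on
    the in-bag data (``rederive``), then a dichotomized Cox model is fit
    on the out-of-bag subjects.  Log-HRs are pooled as their mean with an
    empirical 95% interval.  Resamples whose OOB set has fewer than two
    groups or whose fit fails are skipped and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(df)
    log_hrs = []
    skipped = 0
    for _ in range(B):
        in_bag, oob = bootstrap_oob_split(n, rng)
        c = cutoff
        if rederive is not None:
            try:
                c = rederive(df.iloc[in_bag].reset_index(drop=True))
            except ValueError:
                c = None
            if c is None:
                skipped += 1
                continue
        test = df.iloc[oob]
        ind = (test[covariate] > c).astype(int)
        if ind.nunique() < 2 or test[event_col].sum() < 2:
            skipped += 1
            continue
        work = test.assign(_above=ind)
        try:
            m = cox_fit(work, ["_above"], duration_col, event_col, strata)
        except ValueError:
            skipped += 1
            continue
        log_hrs.append(float(m.coefs["_above"]))
    arr = np.asarray(log_hrs)
    if arr.size == 0:
        raise ValueError("no usable OOB resamples")
    lo, hi = np.quantile(arr, [0.025, 0.975])
    return OobValidation(log_hrs=arr, pooled_hr=float(np.exp(arr.mean())),
                         hr_ci=(float(np.exp(lo)), float(np.exp(hi))),
                         B=B, seed=seed, n_skipped=skipped)


def compare_published_cutoff(df: pd.DataFrame, published: float = 510.0,
                             working: float = 180.0,
                             covariate: str = "tmtv_ml",
                             adjusters: Sequence[str] = (),
                             strata: str | None = None,
                             duration_col: str = "pfs_months",
                             event_col: str = "pfs_event") -> dict:
    """Side-by-side univariable/multivariable report at two cutoffs.

    Used to contrast the working cutoff with the historical 510 mL value
    derived under the legacy 41%-SUVmax segmentation.
    """
    report = {}
    for label, c in (("working", working), ("published", published)):
        ind = (df[covariate] > c).astype(int)
        entry = {"cutoff_ml": float(c), "n_above": int(ind.sum())}
        if ind.nunique() < 2:
            entry["note"] = "degenerate split: one group empty"
            report[label] = entry
            continue
        work = df.assign(_above=ind)
        try:
            uni = cox_fit(work, ["_above"], duration_col, event_col, strata)
            entry["univariable_hr"] = float(uni.hr["_above"])
            entry["univariable_ci"] = (float(uni.ci_lower["_above"]),
                                       float(uni.ci_upper["_above"]))
            if adjusters:
                multi = cox_fit(work, ["_above"] + list(adjusters),
                                duration_col, event_col, strata)
                entry["multivariable_hr"] = float(multi.hr["_above"])
                entry["multivariable_ci"] = (float(multi.ci_lower["_above"]),
                                             float(multi.ci_upper["_above"]))
        except ValueError as exc:
            entry["note"] = f"degenerate fit: {exc}"
        report[label] = entry
    return report


def derive_cutpoints(df: pd.DataFrame, methods: Sequence[str] = METHODS,
                     adjusters: Sequence[str] = (), strata: str | None = None,
                     horizon: float = 36.0, knot_selection_B: int = 100,
                     seed: int = 0, **kw) -> list[CutpointResult]:
    """Run the requested cutoff methods with shared defaults."""
    out = []
    for m in methods:
        if m == "maxstat":
            out.append(maxstat_cutpoint(df, adjusters=adjusters, strata=strata, **kw))
        elif m == "auc-roc-liu":
            out.append(roc_cutpoint_liu(df, horizon=horizon, **kw))
        elif m == "rcs":
            out.append(rcs_cutpoint(df, adjusters=adjusters, strata=strata,
                                    knot_selection_B=knot_selection_B, seed=seed, **kw))
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
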
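"""Prognostic index scoring, risk models and the full analysis pipeline.

Covers FLIPI / FLIPI2 scoring, univariable and multivariable Cox tables,
the combined TMTV x FLIPI2 three-group risk model, early progression
(POD24), concordance-based model comparison, the bootstrap inclusion
fraction of the TMTV term, Bland-Altman inter-reader agreement, and an
orchestrating `run_full_analysis` that produces a deterministic JSON +
markdown report from a cohort (real or synthetic) and a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import cutpoint_pipeline as cp
from .survival_core import (CoxModel, concordance, cox_fit, hr_per_increment,
                            km_estimate, logrank_test)
from .synthetic_data import (FLIPI2_FACTORS, FLIPI_FACTORS, CohortSpec,
                             ReaderNoiseSpec, generate_cohort, read_cohort,
                             simulate_readers)

RISK_LABELS = ("low", "intermediate", "high")


# ---------------------------------------------------------------------------
# Prognostic index scoring
# ---------------------------------------------------------------------------

def _score(data, factors: Sequence[str], index_name: str):
    if isinstance(data, pd.DataFrame):
        missing = [f for f in factors if f not in data.columns
                   or data[f].isna().any()]
        if missing:
            raise ValueError(f"{index_name} factors missing: {missing}")
        return sum(data[f].astype(int) for f in factors)
    missing = [f for f in factors if f not in data or pd.isna(data[f])]
    if missing:
        raise ValueError(f"{index_name} factors missing: {missing}")
    return int(sum(int(bool(data[f])) for f in factors))


def flipi2_score(data) -> tuple:
    """FLIPI2 score (0-5) and class.

    Adverse factors: age > 60, Hb < 12 g/dL, B2M > ULN, bone marrow
    involvement, longest node diameter > 6 cm.  Class is 'high' for >= 3
    factors, 'intermediate' otherwise (trial eligibility required a score
    above 0, so no separate low class is used).
    Accepts a record (mapping/Series) or a cohort DataFrame (vectorized).
    """
    score = _score(data, FLIPI2_FACTORS, "FLIPI2")
    if isinstance(score, pd.Series):
        return score, np.where(score >= 3, "high", "intermediate")
    return score, ("high" if score >= 3 else "intermediate")


def flipi_score(data) -> tuple:
    """Classical FLIPI score (0-5) and class (low 0-1 / intermediate 2 /
    high >= 3).  Factors: age > 60, stage III-IV, Hb < 12, LDH > ULN,
    > 4 nodal areas."""
    score = _score(data, FLIPI_FACTORS, "FLIPI")

    def classify(s):
        return "high" if s >= 3 else ("intermediate" if s == 2 else "low")

    if isinstance(score, pd.Series):
        return score, score.map(classify).to_numpy()
    return score, classify(score)


def combined_risk_group(tmtv_ml, cut: float, flipi2_class) -> np.ndarray | str:
    """Three-group TMTV x FLIPI2 classification.

    Adverse features: TMTV above the cutoff; high-risk FLIPI2.
    0 adverse -> low, 1 -> intermediate, 2 -> high.
    """
    tmtv_arr = np.asarray(tmtv_ml, dtype=float)
    cls_arr = np.asarray(flipi2_class)
    adverse = (tmtv_arr > cut).astype(int) + (cls_arr == "high").astype(int)
    labels = np.array(RISK_LABELS)[adverse]
    return labels if tmtv_arr.ndim else str(labels)


# ---------------------------------------------------------------------------
# Regression tables
# ---------------------------------------------------------------------------

def univariable_table(df: pd.DataFrame, covariates: Sequence[str],
                      duration_col: str = "pfs_months",
                      event_col: str = "pfs_event",
                      strata: str | None = "arm") -> pd.DataFrame:
    """One stratified Cox fit per covariate; n(%) for binary covariates."""
    rows = []
    n = len(df)
    for cov in covariates:
        row = {"covariate": cov}
        vals = df[cov]
        if set(pd.unique(vals.dropna())) <= {0, 1}:
            pos = int(vals.sum())
            row["n"] = pos
            row["pct"] = round(100.0 * pos / n)
        try:
            m = cox_fit(df, [cov], duration_col, event_col, strata)
            row.update(HR=float(m.hr[cov]), ci_lower=float(m.ci_lower[cov]),
                       ci_upper=float(m.ci_upper[cov]), p=float(m.p_values[cov]))
        except ValueError as exc:
            row["note"] = f"degenerate: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


def multivariable_model(df: pd.DataFrame, cut: float = 180.0,
                        adjusters: Sequence[str] = ("flipi2_high", "sex_male",
                                                    "regimen_rb"),
                        strata: str | None = "arm",
                        duration_col: str = "pfs_months",
                        event_col: str = "pfs_event") -> dict:
    """Adjusted Cox models with TMTV in both continuous and dichotomized form.

    The continuous form is scaled per 500 mL; the dichotomized form uses
    the working cutoff.  Both are adjusted by the given covariates and
    stratified (randomization arm by default).
    """
    work = df.copy()
    if "regimen_rb" in adjusters and "regimen_rb" not in work:
        work["regimen_rb"] = (work["regimen"] == "R-B").astype(int)
    work["tmtv_per500"] = work["tmtv_ml"] / 500.0
    work["tmtv_above"] = (work["tmtv_ml"] > cut).astype(int)
    out = {}
    for key, col in (("continuous_per500", "tmtv_per500"),
                     ("dichotomized", "tmtv_above")):
        m = cox_fit(work, [col] + list(adjusters), duration_col, event_col, strata)
        out[key] = {
            "hr": float(m.hr[col]),
            "ci": (float(m.ci_lower[col]), float(m.ci_upper[col])),
            "p": float(m.p_values[col]),
            "model": m,
        }
    return out


# ---------------------------------------------------------------------------
# POD24
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Pod24Result:
    table: np.ndarray        # rows: TMTV (low, high); cols: (no POD24, POD24)
    proportions: dict
    p_value: float
    n_evaluable: int
    test: str


def pod24(df: pd.DataFrame, cut: float = 180.0,
          duration_col: str = "pfs_months", event_col: str = "pfs_event",
          test: str = "fisher") -> Pod24Result:
    """Early progression (event within 24 months) by TMTV group.

    Evaluable subjects have either an event by 24 months or at least 24
    months of follow-up (the clock starts at registration).  The 2x2
    table is tested with Fisher's exact test (two-sided) by default;
    ``test='chi2'`` uses the chi-squared test.
    """
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    evaluable = (t >= 24.0) | ((e == 1) & (t <= 24.0))
    if not evaluable.any():
        raise ValueError("no evaluable subjects for POD24")
    sub = df[evaluable]
    pod = ((sub[event_col] == 1) & (sub[duration_col] <= 24.0)).to_numpy()
    high = (sub["tmtv_ml"] > cut).to_numpy()
    table = np.array([
        [int((~high & ~pod).sum()), int((~high & pod).sum())],
        [int((high & ~pod).sum()), int((high & pod).sum())],
    ])
    if test == "fisher":
        _, p = stats.fisher_exact(table, alternative="two-sided")
    elif test == "chi2":
        _, p, _, _ = stats.chi2_contingency(table, correction=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    props = {
        "low": float(table[0, 1] / table[0].sum()) if table[0].sum() else float("nan"),
        "high": float(table[1, 1] / table[1].sum()) if table[1].sum() else float("nan"),
    }
    return Pod24Result(table=table, proportions=props, p_value=float(p),
                       n_evaluable=int(evaluable.sum()), test=test)


# ---------------------------------------------------------------------------
# Model comparison (concordance) and bootstrap inclusion fraction
# ---------------------------------------------------------------------------

def model_comparison(df: pd.DataFrame, base_covariates: Sequence[str],
                     added: Sequence[str] | str,
                     duration_col: str = "pfs_months",
                     event_col: str = "pfs_event",
                     strata: str | None = "arm") -> dict:
    """Discrimination gain from adding a term to a Cox model.

    Reports Harrell's c with jackknife 95% CI for the base and extended
    models, their difference, and the likelihood-ratio test of the added
    term(s).
    """
    added = [added] if isinstance(added, str) else list(added)
    base = cox_fit(df, list(base_covariates), duration_col, event_col, strata)
    full = cox_fit(df, list(base_covariates) + added, duration_col, event_col, strata)
    t = df[duration_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=int)
    c_base = concordance(base.linear_predictor(df), t, e)
    c_full = concordance(full.linear_predictor(df), t, e)
    lrt = 2.0 * (full.log_likelihood - base.log_likelihood)
    p = float(stats.chi2.sf(lrt, df=len(added)))
    return {
        "c_base": c_base, "c_full": c_full,
        "delta_c": c_full.c - c_base.c,
        "lrt_chi2": float(lrt), "lrt_p": p,
        "base_model": base, "full_model": full,
    }


@dataclasses.dataclass
class BifReport:
    B: int
    n_used: int
    retained_lrt: float      # fraction with likelihood-ratio p < 0.05
    retained_aic: float      # fraction where AIC favors the TMTV model
    seed: int


def bif(df: pd.DataFrame, cut: float = 180.0, B: int = 200, seed: int = 0,
        base_covariates: Sequence[str] = ("flipi2_high",),
        duration_col: str = "pfs_months", event_col: str = "pfs_event",
        strata: str | None = "arm") -> BifReport:
    """Bootstrap inclusion fraction of the dichotomized TMTV term.

    Per resample, the base model (FLIPI2 fixed) is fit with and without
    1{TMTV > cut}; retention is counted under (a) likelihood-ratio
    p < 0.05 and (b) lower AIC.  Failed resamples are excluded.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(df)
    work = df.assign(_above=(df["tmtv_ml"] > cut).astype(int))
    kept_lrt = kept_aic = used = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        dfb = work.iloc[idx].reset_index(drop=True)
        try:
            base = cox_fit(dfb, list(base_covariates), duration_col, event_col, strata)
            full = cox_fit(dfb, list(base_covariates) + ["_above"],
                           duration_col, event_col, strata)
        except ValueError:
            continue
        used += 1
        lrt = 2.0 * (full.log_likelihood - base.log_likelihood)
        if stats.chi2.sf(lrt, df=1) < 0.05:
            kept_lrt += 1
        if full.aic < base.aic:
            kept_aic += 1
    if used == 0:
        raise ValueError("all bootstrap resamples failed")
    return BifReport(B=B, n_used=used, retained_lrt=kept_lrt / used,
                     retained_aic=kept_aic / used, seed=seed)


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    cv_percent: float
    n_pairs: int


def bland_altman(readings: np.ndarray) -> BlandAltmanResult:
    """Inter-reader agreement from a reader-by-subject matrix.

    Differences are taken against per-subject means over all reader
    pairs; the bias and 1.96-SD limits of agreement are on the raw mL
    scale.  Because TMTV measurement error is proportional to the value,
    the repeatability coefficient of variation uses the within-subject
    convention on paired ratios:

        CV% = 100 * sqrt( mean( (d_i / m_i)^2 ) / 2 )

    which is scale-free (identical readers give exactly 0%).
    """
    arr = np.asarray(readings, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a k x n matrix with k >= 2 readers")
    k, n = arr.shape
    diffs, means = [], []
    for a in range(k):
        for b in range(a + 1, k):
            diffs.append(arr[a] - arr[b])
            means.append(0.5 * (arr[a] + arr[b]))
    d = np.concatenate(diffs)
    m = np.concatenate(means)
    ok = np.isfinite(d) & np.isfinite(m) & (m > 0)
    d, m = d[ok], m[ok]
    if d.size < 2:
        raise ValueError("fewer than 2 complete measurement pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    cv = 100.0 * math.sqrt(float(np.mean((d / m) ** 2)) / 2.0)
    return BlandAltmanResult(bias=bias, loa_lower=bias - 1.96 * sd,
                             loa_upper=bias + 1.96 * sd, cv_percent=cv,
                             n_pairs=int(d.size))


# ---------------------------------------------------------------------------
# Full analysis orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of `run_full_analysis`.

    ``cohort_csv=None`` simulates the default synthetic cohort.  ``B``
    drives every bootstrap (OOB validation, inclusion fraction, cutoff
    stability); ``knot_selection_B`` the spline knot search.
    """

    cohort_csv: str | None = None
    n: int = 689
    seed: int = 0
    B: int = 200
    knot_selection_B: int = 50
    horizon_months: float = 36.0
    working_cutoff_round: float = 1.0
    adjusters: tuple[str, ...] = ("flipi2_high", "sex_male", "regimen_rb")
    strata: str = "arm"
    reader_cv: float = 0.05
    reader_fraction: float = 0.20
    published_cutoff_ml: float = 510.0


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else round(v, 10)
    if isinstance(obj, (np.integer, int, bool, str)) or obj is None:
        return obj if not isinstance(obj, np.integer) else int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    if dataclasses.is_dataclass(obj):
        d = {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)
             if f.name not in ("fitter", "grid", "trace", "organ_masks",
                               "per_resample_aic", "log_hrs", "cutoffs",
                               "model", "base_model", "full_model")}
        return _jsonify(d)
    return str(obj)


def run_full_analysis(config: AnalysisConfig | None = None) -> dict:
    """Execute the whole prognostic pipeline on one cohort.

    Stages: cohort summary -> cutoff derivation (three methods +
    consensus) -> univariable / multivariable PFS models -> POD24 ->
    combined TMTV x FLIPI2 model (PFS and, when present, OS) ->
    discrimination comparison, inclusion fraction, OOB validation, band
    analysis, published-cutoff comparison, and simulated inter-reader
    agreement.  Stage failures are caught and reported under the stage
    name; the rest of the report is still emitted.

    The report is a JSON-serializable dict; identical config and seed
    give a byte-identical `to_report_json` output.
    """
    config = config or AnalysisConfig()
    report: dict = {"config": dataclasses.asdict(config)}
    if config.cohort_csv:
        df = read_cohort(config.cohort_csv)
    else:
        df = generate_cohort(CohortSpec(n=config.n, seed=config.seed))
    if "regimen_rb" not in df and "regimen" in df:
        df = df.assign(regimen_rb=(df["regimen"] == "R-B").astype(int))

    def stage(name, fn):
        try:
            report[name] = fn()
        except Exception as exc:
            report[name] = {"error": f"{name} failed: {exc}"}

    tmtv = df["tmtv_ml"].to_numpy(dtype=float)

    def _summary():
        q25, med, q75 = np.quantile(tmtv, [0.25, 0.5, 0.75])
        km = km_estimate(df["pfs_months"], df["pfs_event"])
        fu = km_estimate(df["pfs_months"], 1 - df["pfs_event"])  # reverse KM
        return {
            "n": len(df),
            "tmtv_median_ml": med, "tmtv_iqr_ml": (q25, q75),
            "flipi2_high_fraction": float(df["flipi2_high"].mean()),
            "n_pfs_events": int(df["pfs_event"].sum()),
            "pfs_5yr": km.survival_at(60.0),
            "median_followup_months": _median_survival(fu),
        }

    stage("summary", _summary)

    results = cp.derive_cutpoints(
        df, adjusters=list(config.adjusters), strata=config.strata,
        horizon=config.horizon_months, knot_selection_B=config.knot_selection_B,
        seed=config.seed)
    report["cutpoints"] = {r.method: {"cutoff_ml": r.cutoff_ml,
                                      "criterion": r.criterion,
                                      "degenerate": r.degenerate,
                                      "note": r.note} for r in results}
    consensus = cp.consensus_cutoff(results, df,
                                    round_to=config.working_cutoff_round)
    cut = float(consensus["chosen_cutoff_ml"])
    report["consensus"] = {"chosen_cutoff_ml": cut,
                           "evaluation": consensus["evaluation"]}

    stage("continuous_tmtv", lambda: _continuous_tmtv(df, config))
    stage("univariable", lambda: univariable_table(
        df, ["age_gt60", "sex_male", "hb_lt12", "b2m_gt_uln", "bm_involved",
             "lodlin_gt6", "flipi2_high", "regimen_rb"]
        , strata=config.strata))
    stage("univariable_tmtv", lambda: _dichotomized_univariable(df, cut, config))
    stage("multivariable", lambda: {
        k: {kk: vv for kk, vv in v.items() if kk != "model"}
        for k, v in multivariable_model(df, cut, config.adjusters,
                                        config.strata).items()})
    stage("pod24", lambda: pod24(df, cut))
    stage("combined_model", lambda: _combined_model(df, cut, config))
    stage("model_comparison", lambda: _comparison(df, cut, config))
    stage("bif", lambda: bif(df, cut, B=config.B, seed=config.seed,
                             strata=config.strata))
    stage("oob_validation", lambda: cp.oob_validate(
        df, cut, B=config.B, seed=config.seed, strata=config.strata))
    stage("band_analysis", lambda: cp.band_analysis(df, cut, cut + 60.0,
                                                    strata=config.strata))
    stage("published_cutoff", lambda: cp.compare_published_cutoff(
        df, published=config.published_cutoff_ml, working=cut,
        adjusters=list(config.adjusters), strata=config.strata))
    stage("agreement", lambda: _agreement(df, config))
    return report


def _median_survival(km) -> float | None:
    below = km.survival <= 0.5
    idx = np.flatnonzero(below)
    return float(km.times[idx[0]]) if idx.size else None


def _continuous_tmtv(df, config) -> dict:
    work = df.assign(tmtv_per500=df["tmtv_ml"] / 500.0)
    m = cox_fit(work, ["tmtv_per500"], strata=config.strata)
    hr, lo, hi = hr_per_increment(m, "tmtv_per500", 1.0)
    return {"hr_per_500ml": hr, "ci": (lo, hi), "p": float(m.p_values["tmtv_per500"])}


def _dichotomized_univariable(df, cut, config) -> dict:
    work = df.assign(_above=(df["tmtv_ml"] > cut).astype(int))
    m = cox_fit(work, ["_above"], strata=config.strata)
    km_low = km_estimate(work.loc[work._above == 0, "pfs_months"],
                         work.loc[work._above == 0, "pfs_event"])
    km_high = km_estimate(work.loc[work._above == 1, "pfs_months"],
                          work.loc[work._above == 1, "pfs_event"])
    return {"cutoff_ml": cut,
            "n_above": int(work._above.sum()),
            "hr": float(m.hr["_above"]),
            "ci": (float(m.ci_lower["_above"]), float(m.ci_upper["_above"])),
            "p": float(m.p_values["_above"]),
            "pfs_5yr_low": km_low.survival_at(60.0),
            "pfs_5yr_high": km_high.survival_at(60.0)}


def _combined_model(df, cut, config) -> dict:
    _, cls = flipi2_score(df)
    groups = combined_risk_group(df["tmtv_ml"].to_numpy(), cut, cls)
    out: dict = {"cutoff_ml": cut, "groups": {}}
    endpoints = [("pfs", "pfs_months", "pfs_event")]
    if "os_months" in df and "os_event" in df:
        endpoints.append(("os", "os_months", "os_event"))
    else:
        out["os_note"] = "OS columns absent: OS section skipped"
    for name, tcol, ecol in endpoints:
        section = {}
        for g in RISK_LABELS:
            m = groups == g
            if m.sum() == 0:
                section[g] = {"n": 0}
                continue
            km = km_estimate(df[tcol][m], df[ecol][m])
            section[g] = {"n": int(m.sum()),
                          "fraction": float(m.mean()),
                          "surv_5yr": km.survival_at(60.0)}
        for g in ("intermediate", "high"):
            m = (groups == g) | (groups == "low")
            work = df[m].assign(_g=(groups[m] == g).astype(int))
            try:
                fit = cox_fit(work, ["_g"], tcol, ecol, config.strata)
                section[f"hr_{g}_vs_low"] = float(fit.hr["_g"])
                section[f"hr_{g}_vs_low_ci"] = (float(fit.ci_lower["_g"]),
                                                float(fit.ci_upper["_g"]))
            except ValueError:
                section[f"hr_{g}_vs_low"] = None
        chi2, dfree, p = logrank_test(df[tcol], df[ecol], groups)
        section["logrank"] = {"chi2": chi2, "df": dfree, "p": p}
        out[name] = section
    return out


def _comparison(df, cut, config) -> dict:
    work = df.assign(_above=(df["tmtv_ml"] > cut).astype(int))
    res = model_comparison(work, ["flipi2_high"], "_above",
                           strata=config.strata)
    return {
        "c_flipi2": {"c": res["c_base"].c,
                     "ci": (res["c_base"].ci_lower, res["c_base"].ci_upper)},
        "c_flipi2_plus_tmtv": {"c": res["c_full"].c,
                               "ci": (res["c_full"].ci_lower,
                                      res["c_full"].ci_upper)},
        "delta_c": res["delta_c"],
        "lrt_chi2": res["lrt_chi2"], "lrt_p": res["lrt_p"],
    }


def _agreement(df, config) -> dict:
    rng_seed = config.seed + 10007
    n_sub = max(2, int(round(config.reader_fraction * len(df))))
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(df), size=n_sub, replace=False)
    truth = df["tmtv_ml"].to_numpy(dtype=float)[idx]
    mat = simulate_readers(truth, ReaderNoiseSpec(k_readers=2, cv=config.reader_cv),
                           seed=rng_seed)
    res = bland_altman(mat)
    return {"n_subjects": n_sub, "simulated_reader_cv": config.reader_cv,
            "bias_ml": res.bias, "loa_ml": (res.loa_lower, res.loa_upper),
            "cv_percent": res.cv_percent}


def to_report_json(report: dict) -> str:
    """Canonical JSON (sorted keys, fixed float rounding): identical
    inputs give byte-identical output."""
    return json.dumps(_jsonify(report), sort_keys=True, indent=2)


def to_report_markdown(report: dict) -> str:
    """Human-readable markdown rendering of the analysis report."""
    lines = ["# TMTV prognostic analysis report", ""]
    s = report.get("summary", {})
    if "error" not in s:
        lines += [
            f"- cohort n = {s.get('n')}",
            f"- median TMTV = {s.get('tmtv_median_ml'):.1f} mL "
            f"(IQR {s.get('tmtv_iqr_ml', (float('nan'),)*2)[0]:.1f}-"
            f"{s.get('tmtv_iqr_ml', (float('nan'),)*2)[1]:.1f})",
            f"- FLIPI2 high: {100 * s.get('flipi2_high_fraction', float('nan')):.0f}%",
            f"- 5-year PFS: {100 * s.get('pfs_5yr', float('nan')):.0f}%",
            "",
        ]
    cps = report.get("cutpoints", {})
    if cps:
        lines.append("## Cutoff derivation")
        for method, r in cps.items():
            c = r.get("cutoff_ml")
            lines.append(f"- {method}: "
                         + (f"{c:.1f} mL" if c is not None else "no cutpoint")
                         + (f" ({r['note']})" if r.get("note") else ""))
        cons = report.get("consensus", {})
        if cons:
            lines.append(f"- consensus working cutoff: "
                         f"{cons.get('chosen_cutoff_ml'):.0f} mL")
        lines.append("")
    uni = report.get("univariable_tmtv", {})
    if uni and "error" not in uni:
        lines += ["## Dichotomized TMTV (PFS)",
                  f"- HR {uni['hr']:.2f} (95% CI {uni['ci'][0]:.2f}-{uni['ci'][1]:.2f})",
                  f"- 5-yr PFS {100*uni['pfs_5yr_low']:.0f}% (low) vs "
                  f"{100*uni['pfs_5yr_high']:.0f}% (high)", ""]
    comp = report.get("model_comparison", {})
    if comp and "error" not in comp:
        lines += ["## Discrimination",
                  f"- c-Harrell FLIPI2: {comp['c_flipi2']['c']:.3f}",
                  f"- c-Harrell FLIPI2 + TMTV: {comp['c_flipi2_plus_tmtv']['c']:.3f}",
                  f"- delta c = {comp['delta_c']:.3f}", ""]
    return "\n".join(lines)
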
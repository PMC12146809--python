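"""Survival-analysis engine used by the cutpoint and prognostic layers.

Kaplan-Meier estimation and Cox proportional-hazards fitting (Efron tie
handling, optional stratification by randomization arm) are backed by
lifelines.  The pieces the cutpoint machinery needs in vectorized or
stratified form are implemented here directly:

* a stratified k-group log-rank test with the hypergeometric variance;
* the stratified, covariate-adjusted Cox *score* test evaluated
  simultaneously for many candidate dichotomizations (the engine behind
  the maximally selected log-rank statistic);
* Harrell's restricted cubic spline basis with his recommended quantile
  knot placements, plus bootstrap minimum-AIC knot-count selection;
* Harrell's concordance index with a leave-one-out jackknife CI;
* with-replacement bootstrap / out-of-bag index splits (~36.8% OOB).

All confidence intervals are two-sided 95% Wald intervals on the log
scale; AIC uses partial-likelihood degrees of freedom equal to the
number of regression columns.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as _ll_concordance_index
from scipy import stats

Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SurvivalData:
    """Time-to-event view over a cohort DataFrame."""

    df: pd.DataFrame
    duration_col: str = "pfs_months"
    event_col: str = "pfs_event"
    strata_col: str | None = "arm"

    def __post_init__(self):
        t = self.df[self.duration_col].to_numpy(dtype=float)
        e = self.df[self.event_col].to_numpy()
        if np.any(t <= 0):
            raise ValueError("times must be positive")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event flags must be 0/1")

    @property
    def time(self) -> np.ndarray:
        return self.df[self.duration_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df[self.event_col].to_numpy(dtype=int)

    @property
    def strata(self) -> np.ndarray | None:
        if self.strata_col is None or self.strata_col not in self.df:
            return None
        return self.df[self.strata_col].to_numpy()


@dataclasses.dataclass
class KmCurve:
    """Product-limit estimate with Greenwood variance."""

    times: np.ndarray          # distinct event times
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray       # S(t) at each event time (right-continuous)
    greenwood_var: np.ndarray

    def survival_at(self, horizon: float, side: str = "right") -> float:
        """Step value at the last event time <= horizon ('right') or
        strictly < horizon ('left', i.e. S(t-))."""
        cmp = self.times <= horizon if side == "right" else self.times < horizon
        idx = np.flatnonzero(cmp)
        return float(self.survival[idx[-1]]) if idx.size else 1.0


@dataclasses.dataclass
class CoxModel:
    """Cox PH fit report (Efron ties, optional stratification)."""

    coefs: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    strata: str | list[str] | None
    converged: bool
    fitter: CoxPHFitter | None = dataclasses.field(default=None, repr=False)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = df[list(self.coefs.index)].astype(float)
        return X.to_numpy() @ self.coefs.to_numpy()

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefs, "se": self.se, "HR": self.hr,
            "HR 95% lower": self.ci_lower, "HR 95% upper": self.ci_upper,
            "p": self.p_values,
        })


@dataclasses.dataclass
class RcsBasis:
    """Restricted cubic spline basis (truncated-power form).

    ``k`` knots give ``k-1`` columns: the identity plus ``k-2`` nonlinear
    terms that are exactly linear beyond the boundary knots and have
    continuous first and second derivatives everywhere.
    """

    knots: np.ndarray
    matrix: np.ndarray
    column_names: list[str]

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return _rcs_design(np.asarray(x, dtype=float), self.knots)


@dataclasses.dataclass
class ConcordanceResult:
    c: float
    ci_lower: float
    ci_upper: float
    usable_pairs: float
    jackknife_se: float


@dataclasses.dataclass
class KnotSelection:
    selected_k: int
    mean_aic: dict[int, float]
    per_resample_aic: pd.DataFrame  # rows = resamples, columns = k
    n_failures: int


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time: Sequence[float], event: Sequence[int]) -> KmCurve:
    """Kaplan-Meier product-limit estimate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table
    obs = table["observed"].to_numpy()
    keep = obs > 0
    times = table.index.to_numpy(dtype=float)[keep]
    at_risk = table["at_risk"].to_numpy(dtype=float)[keep]
    d = obs[keep].astype(float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()[keep]
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d))); the term where the
    # whole risk set fails (S drops to 0) is left out rather than infinite
    denom = at_risk * (at_risk - d)
    gw = surv ** 2 * np.cumsum(np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0))
    return KmCurve(times=times, at_risk=at_risk, n_events=d, survival=surv,
                   greenwood_var=gw)


# ---------------------------------------------------------------------------
# Log-rank test (k groups, optional strata)
# ---------------------------------------------------------------------------

def logrank_test(time, event, group, strata=None) -> tuple[float, int, float]:
    """Stratified k-group log-rank test.

    Observed-minus-expected counts with the hypergeometric variance,
    summed across strata, then chi2 = Z' V^{-1} Z with k-1 df.

    Returns (chi-square, df, p).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    strata = np.zeros(time.size) if strata is None else np.asarray(strata)

    z = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for s in np.unique(strata):
        m = strata == s
        t, e, g = time[m], event[m], group[m]
        gi = np.searchsorted(levels, g) if levels.dtype.kind in "if" else \
            np.array([np.where(levels == x)[0][0] for x in g])
        for td in np.unique(t[e == 1]):
            at_risk = t >= td
            n_total = at_risk.sum()
            d_total = ((t == td) & (e == 1)).sum()
            if n_total <= 1:
                continue
            n_g = np.bincount(gi[at_risk], minlength=k).astype(float)
            d_g = np.bincount(gi[(t == td) & (e == 1)], minlength=k).astype(float)
            p_g = n_g / n_total
            z += (d_g - d_total * p_g)[:-1]
            factor = d_total * (n_total - d_total) / (n_total - 1)
            Vt = factor * (np.diag(p_g) - np.outer(p_g, p_g))
            V += Vt[:-1, :-1]
    chi2 = float(z @ np.linalg.pinv(V) @ z)
    df = k - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Cox PH (lifelines-backed)
# ---------------------------------------------------------------------------

def cox_fit(df: pd.DataFrame, covariates: Sequence[str],
            duration_col: str = "pfs_months", event_col: str = "pfs_event",
            strata: str | Sequence[str] | None = None) -> CoxModel:
    """Stratified Cox PH fit (Efron ties) reporting HRs with 95% CIs.

    Raises ValueError with a diagnostic for degenerate inputs (constant
    covariates, too few events) and wraps lifelines convergence failures.
    """
    covariates = list(covariates)
    n_events = int(df[event_col].sum())
    if n_events < len(covariates):
        raise ValueError(f"{n_events} events < {len(covariates)} covariates")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant: no information")
    cols = covariates + [duration_col, event_col]
    strata_list = [strata] if isinstance(strata, str) else list(strata or [])
    cols += strata_list
    data = df[cols].copy()
    cph = CoxPHFitter()
    converged = True
    try:
        import warnings as _warnings
        from lifelines.exceptions import ConvergenceWarning
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", ConvergenceWarning)
            cph.fit(data, duration_col=duration_col, event_col=event_col,
                    strata=strata_list or None)
        converged = not any(issubclass(w.category, ConvergenceWarning)
                            for w in caught)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ValueError(f"Cox fit failed to converge: {exc}") from exc
    coefs = cph.params_
    se = cph.standard_errors_
    return CoxModel(
        coefs=coefs, se=se,
        hr=np.exp(coefs),
        ci_lower=np.exp(coefs - Z95 * se),
        ci_upper=np.exp(coefs + Z95 * se),
        p_values=cph.summary["p"],
        log_likelihood=float(cph.log_likelihood_),
        aic=float(-2.0 * cph.log_likelihood_ + 2.0 * len(covariates)),
        n=len(data), n_events=n_events,
        strata=strata, converged=converged, fitter=cph,
    )


def hr_per_increment(model: CoxModel, covariate: str, delta: float
                     ) -> tuple[float, float, float]:
    """HR (with 95% CI) for an increase of `delta` units in a continuous
    covariate: exp(delta * coef), CI transformed identically."""
    beta = float(model.coefs[covariate])
    se = float(model.se[covariate])
    return (float(np.exp(delta * beta)),
            float(np.exp(delta * beta - Z95 * abs(delta) * se)),
            float(np.exp(delta * beta + Z95 * abs(delta) * se)))


# ---------------------------------------------------------------------------
# Adjusted, stratified score test over candidate dichotomizations
# ---------------------------------------------------------------------------

def cox_score_candidates(time, event, Z, strata=None, lp_adjust=None,
                         X_adjust=None, info_adjust_inv=None,
                         chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Score statistics for adding each column of Z to a (fitted) null model.

    For every candidate column z (typically 1{TMTV > c}) this computes the
    partial-likelihood score U and model-based (Breslow-form) variance V
    of the added term, evaluated at the null model's coefficients, with
    adjustment-covariate information partialled out:

        V_c = I_zz,c - I_ztheta,c  I_theta^-1  I_theta z,c

    U^2/V is the (adjusted, stratified) log-rank-type chi-square.  With no
    adjusters and distinct event times this equals the classical log-rank
    statistic.

    Parameters: ``lp_adjust`` is the null-model linear predictor,
    ``X_adjust`` the adjustment design (n x p), ``info_adjust_inv`` the
    null model's inverse information (its variance matrix).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    Z = np.asarray(Z, dtype=float)
    n, C = Z.shape
    strata = np.zeros(n) if strata is None else np.asarray(strata)
    lp = np.zeros(n) if lp_adjust is None else np.asarray(lp_adjust, dtype=float)
    has_adj = X_adjust is not None
    if has_adj:
        X = np.asarray(X_adjust, dtype=float)
        p = X.shape[1]
        Iinv = np.asarray(info_adjust_inv, dtype=float)

    U = np.zeros(C)
    Izz = np.zeros(C)
    Izx = np.zeros((C, p)) if has_adj else None

    for s in np.unique(strata):
        m = strata == s
        order = np.argsort(time[m], kind="stable")
        t = time[m][order]
        e = event[m][order]
        w = np.exp(lp[m][order])
        Zs = Z[m][order]
        first = np.searchsorted(t, t, side="left")
        S0 = np.cumsum(w[::-1])[::-1]
        deaths = np.flatnonzero(e == 1)
        r = first[deaths]
        if has_adj:
            Xs = X[m][order]
            Sx = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
            Ex = Sx[r] / S0[r, None]
        for lo in range(0, C, chunk):
            sl = slice(lo, lo + chunk)
            Zc = Zs[:, sl]
            Sz = np.cumsum((w[:, None] * Zc)[::-1], axis=0)[::-1]
            Ez = Sz[r] / S0[r, None]
            U[sl] += (Zc[deaths] - Ez).sum(axis=0)
            Izz[sl] += (Ez - Ez ** 2).sum(axis=0)  # z binary: E[z^2] = E[z]
            if has_adj:
                Szx = np.cumsum(((w[:, None] * Zc)[:, :, None] * Xs[:, None, :])[::-1],
                                axis=0)[::-1]
                Ezx = Szx[r] / S0[r, None, None]
                Izx[sl] += (Ezx - Ez[:, :, None] * Ex[:, None, :]).sum(axis=0)

    if has_adj:
        V = Izz - np.einsum("cp,pq,cq->c", Izx, Iinv, Izx)
    else:
        V = Izz
    return U, V


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

#: Harrell's recommended knot quantiles by knot count
HARRELL_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def _rcs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = len(knots)
    t1, tkm1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (plus3(x - tj)
                - plus3(x - tkm1) * (tk - tj) / (tk - tkm1)
                + plus3(x - tk) * (tkm1 - tj) / (tk - tkm1)) / norm
        cols.append(term)
    return np.column_stack(cols)


def rcs_basis(x: Sequence[float], k: int = 5,
              knots: Sequence[float] | None = None) -> RcsBasis:
    """Restricted cubic spline basis with Harrell quantile knots.

    ``k`` in [3, 7]; explicit ``knots`` override the quantile placement.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        if k not in HARRELL_KNOT_QUANTILES:
            raise ValueError("k must be between 3 and 7")
        knots = np.quantile(x, HARRELL_KNOT_QUANTILES[k])
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != knots.size:
        raise ValueError("knots are not distinct: not enough distinct x values")
    names = ["x"] + [f"x'{j}" for j in range(1, len(knots) - 1)]
    return RcsBasis(knots=knots, matrix=_rcs_design(x, knots), column_names=names)


def fit_rcs_cox(df: pd.DataFrame, covariate: str, k: int,
                adjusters: Sequence[str] = (), strata: str | None = None,
                duration_col: str = "pfs_months", event_col: str = "pfs_event",
                knots: Sequence[float] | None = None):
    """Cox fit with an RCS term, numerically stabilized.

    The truncated-power columns of a heavy-tailed covariate are severely
    collinear, so the fit runs on an orthonormalized (QR) version of the
    centered basis and the coefficients are mapped back.  Returns
    ``(CoxModel, curve, basis)`` where ``curve(x)`` evaluates the fitted
    spline contribution to the log hazard (up to a constant).
    """
    x = df[covariate].to_numpy(dtype=float)
    basis = rcs_basis(x, k=k, knots=knots)
    M = basis.matrix
    mean = M.mean(axis=0)
    Q, R = np.linalg.qr(M - mean)
    if np.min(np.abs(np.diag(R))) < 1e-10 * np.max(np.abs(np.diag(R))):
        raise ValueError("spline basis is rank deficient (coincident knots?)")
    scale = np.sqrt(len(df))
    cols = [f"_rcsq{j}" for j in range(Q.shape[1])]
    work = df.copy()
    work[cols] = Q * scale
    model = cox_fit(work, cols + list(adjusters), duration_col, event_col, strata)
    gamma = model.coefs[cols].to_numpy() * scale
    beta = np.linalg.solve(R, gamma)

    def curve(xnew):
        return (basis.evaluate(np.atleast_1d(np.asarray(xnew, dtype=float)))
                - mean) @ beta

    return model, curve, basis


def select_knots_bootstrap(df: pd.DataFrame, covariate: str,
                           adjusters: Sequence[str] = (),
                           strata: str | None = None,
                           duration_col: str = "pfs_months",
                           event_col: str = "pfs_event",
                           k_range: Iterable[int] = range(3, 8),
                           B: int = 1000, seed: int = 0) -> KnotSelection:
    """Choose the spline knot count by minimum mean AIC over bootstrap
    resamples of the adjusted, stratified Cox fit.

    For each with-replacement resample and each candidate k, the RCS basis
    (knots at Harrell quantiles of the resample) enters a Cox model with
    the adjusters; the k minimizing the across-resample mean AIC wins.
    Failed fits are excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    ks = list(k_range)
    n = len(df)
    records = []
    n_failures = 0
    for b in range(B):
        idx = rng.integers(0, n, n) if B > 1 else np.arange(n)
        dfb = df.iloc[idx].reset_index(drop=True)
        row = {}
        for k in ks:
            try:
                model, _, _ = fit_rcs_cox(dfb, covariate, k, adjusters, strata,
                                          duration_col, event_col)
                row[k] = model.aic
            except ValueError:
                n_failures += 1
                row[k] = np.nan
        records.append(row)
    trace = pd.DataFrame(records, columns=ks)
    mean_aic = trace.mean(axis=0, skipna=True)
    if mean_aic.isna().all():
        raise ValueError("all spline fits failed")
    selected = int(mean_aic.idxmin())
    return KnotSelection(selected_k=selected,
                         mean_aic={int(k): float(v) for k, v in mean_aic.items()},
                         per_resample_aic=trace, n_failures=n_failures)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def concordance(scores, time, event, jackknife: bool = True) -> ConcordanceResult:
    """Harrell's c for risk scores (higher score = higher risk).

    Usable pairs under right censoring: (i, j) with an event in i and
    either t_i < t_j, or t_i = t_j with j censored.  Ties in score count
    one half.  The 95% CI is normal-theory with the leave-one-out
    jackknife variance.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    n = t.size
    comparable = (e[:, None] == 1) & ((t[:, None] < t[None, :])
                                      | ((t[:, None] == t[None, :]) & (e[None, :] == 0)))
    np.fill_diagonal(comparable, False)
    win = np.where(s[:, None] > s[None, :], 1.0,
                   np.where(s[:, None] == s[None, :], 0.5, 0.0))
    W = win * comparable
    P = float(comparable.sum())
    if P == 0:
        raise ValueError("no usable pairs")
    Wtot = float(W.sum())
    c = Wtot / P
    if not jackknife or n < 3:
        return ConcordanceResult(c, float("nan"), float("nan"), P, float("nan"))
    rowW = W.sum(axis=1) + W.sum(axis=0)
    rowP = comparable.sum(axis=1) + comparable.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = (Wtot - rowW) / (P - rowP)
    c_loo = np.where(np.isfinite(c_loo), c_loo, c)
    var = (n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)
    se = float(np.sqrt(var))
    return ConcordanceResult(c, c - Z95 * se, c + Z95 * se, P, se)


def lifelines_concordance(scores, time, event) -> float:
    """lifelines' Harrell c on risk scores (cross-check convenience)."""
    return float(_ll_concordance_index(time, -np.asarray(scores), event))


# ---------------------------------------------------------------------------
# Bootstrap / out-of-bag splits
# ---------------------------------------------------------------------------

def bootstrap_oob_split(n: int, rng: np.random.Generator | int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One with-replacement resample and its out-of-bag complement.

    The expected OOB fraction is (1 - 1/n)^n -> 1/e, about 36.8% ("about
    37% of records"), which is what makes the OOB set usable as an
    internal test set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    in_bag = rng.integers(0, n, n)
    oob = np.setdiff1d(np.arange(n), in_bag)
    return in_bag, oob
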
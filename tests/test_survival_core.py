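"""Survival engine vs independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from tmtvkit.survival_core import (HARRELL_KNOT_QUANTILES, bootstrap_oob_split,
                                   concordance, cox_fit, cox_score_candidates,
                                   fit_rcs_cox, hr_per_increment, km_estimate,
                                   lifelines_concordance, logrank_test,
                                   rcs_basis, select_knots_bootstrap)

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------


def km_oracle(time, event, horizon):
    """Product-limit by direct multiplication over event times."""
    s = 1.0
    for td in sorted({t for t, e in zip(time, event) if e == 1}):
        if td > horizon:
            break
        n = sum(1 for t in time if t >= td)
        d = sum(1 for t, e in zip(time, event) if t == td and e == 1)
        s *= 1 - d / n
    return s


def logrank_oracle(time, event, group):
    """2-group log-rank via explicit hypergeometric tables."""
    num = 0.0
    var = 0.0
    for td in sorted({t for t, e in zip(time, event) if e == 1}):
        n1 = sum(1 for t, g in zip(time, group) if t >= td and g == 1)
        n0 = sum(1 for t, g in zip(time, group) if t >= td and g == 0)
        n = n1 + n0
        d = sum(1 for t, e in zip(time, event) if t == td and e == 1)
        d1 = sum(1 for t, e, g in zip(time, event, group)
                 if t == td and e == 1 and g == 1)
        num += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)
    return num ** 2 / var


def concordance_oracle(scores, time, event):
    """All-pairs O(n^2) count of Harrell-comparable pairs."""
    conc = pairs = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            if time[i] < time[j] or (time[i] == time[j] and event[j] == 0):
                pairs += 1
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / pairs


def cox_loglik_1d(beta, time, event, x):
    """1-covariate Breslow partial log-likelihood (distinct times)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_hand_example(self):
        """times 1 (censored), 2 (event), 3 (censored) -> S(2) = 0.5."""
        km = km_estimate([1, 2, 3], [0, 1, 0])
        assert km.survival_at(2.0) == pytest.approx(0.5)

    def test_no_events_survival_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0

    def test_all_events_closed_form(self):
        km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        for kth, t in enumerate([1, 2, 3, 4], start=1):
            assert km.survival_at(t) == pytest.approx((4 - kth) / 4)

    def test_equals_oracle_on_random_data(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.integers(0, 2, 40)
        km = km_estimate(t, e)
        for h in (2.0, 5.0, 10.0, 25.0):
            assert km.survival_at(h) == pytest.approx(km_oracle(t, e, h), abs=1e-10)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 60) + 0.1
        km = km_estimate(t, np.ones(60, dtype=int))
        for h in np.quantile(t, [0.2, 0.5, 0.8]):
            assert km.survival_at(h) == pytest.approx((t > h).mean(), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [2, 4, 5, 7]
        e = [1, 1, 0, 1]
        chi2, _, p = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_hypergeometric(self, tiny_survival):
        t = tiny_survival.pfs_months.to_numpy()
        e = tiny_survival.pfs_event.to_numpy()
        g = tiny_survival.group.to_numpy()
        chi2, df, _ = logrank_test(t, e, g)
        assert df == 1
        assert chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 50) + 0.1
        e = rng.integers(0, 2, 50)
        g = rng.integers(0, 2, 50)
        chi2, _, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40) + 0.1
        e = rng.integers(0, 2, 40)
        g = rng.integers(0, 2, 40)
        assert logrank_test(t, e, g)[0] == pytest.approx(
            logrank_test(t, e, g, strata=np.zeros(40))[0])

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_tiny_fit_matches_grid_search(self, tiny_survival):
        """Coefficient equals the argmax of the brute partial likelihood."""
        m = cox_fit(tiny_survival, ["group"])
        t = tiny_survival.pfs_months.to_numpy()
        e = tiny_survival.pfs_event.to_numpy()
        x = tiny_survival.group.to_numpy()
        grid = np.arange(-4, 4, 1e-3)
        lls = [cox_loglik_1d(b, t, e, x) for b in grid]
        assert m.coefs["group"] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_constant_covariate_flagged(self, tiny_survival):
        bad = tiny_survival.assign(flat=1.0)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(bad, ["flat"])

    def test_location_shift_invariance_scale_equivariance(self, default_cohort):
        df = default_cohort.assign(x=default_cohort.tmtv_ml / 100.0)
        m1 = cox_fit(df, ["x"])
        m2 = cox_fit(df.assign(x=df.x + 5.0), ["x"])
        m3 = cox_fit(df.assign(x=df.x * 2.0), ["x"])
        assert m1.coefs["x"] == pytest.approx(m2.coefs["x"], rel=1e-6)
        assert m1.coefs["x"] == pytest.approx(2 * m3.coefs["x"], rel=1e-6)

    def test_hr_ci_consistency(self, default_cohort):
        df = default_cohort.assign(above=(default_cohort.tmtv_ml > 180).astype(int))
        m = cox_fit(df, ["above"], strata="arm")
        assert m.hr["above"] == pytest.approx(np.exp(m.coefs["above"]))
        assert m.aic == pytest.approx(-2 * m.log_likelihood + 2)

    def test_hr_per_increment(self, default_cohort):
        df = default_cohort.assign(tmtv=default_cohort.tmtv_ml)
        m = cox_fit(df, ["tmtv"])
        hr, lo, hi = hr_per_increment(m, "tmtv", 500.0)
        assert hr == pytest.approx(np.exp(500 * m.coefs["tmtv"]))
        assert lo < hr < hi
        zero = m
        zero.coefs["tmtv"] = 0.0
        assert hr_per_increment(zero, "tmtv", 500.0)[0] == 1.0


class TestScoreCandidates:
    def test_reduces_to_classical_logrank_without_adjusters(self):
        """Tie-free data: score chi-square = log-rank chi-square."""
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 80) + rng.uniform(0, 0.01, 80)
        e = rng.integers(0, 2, 80)
        x = rng.uniform(0, 100, 80)
        for c in (30.0, 50.0, 70.0):
            z = (x > c).astype(float)
            U, V = cox_score_candidates(t, e, z[:, None])
            assert U[0] ** 2 / V[0] == pytest.approx(
                logrank_oracle(t, e, z), rel=1e-9)

    def test_stratified_sums_over_strata(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 60) + rng.uniform(0, 0.01, 60)
        e = rng.integers(0, 2, 60)
        z = rng.integers(0, 2, 60).astype(float)[:, None]
        s = rng.integers(0, 2, 60)
        U, V = cox_score_candidates(t, e, z, strata=s)
        U0, V0 = cox_score_candidates(t[s == 0], e[s == 0], z[s == 0])
        U1, V1 = cox_score_candidates(t[s == 1], e[s == 1], z[s == 1])
        assert U[0] == pytest.approx(U0[0] + U1[0])
        assert V[0] == pytest.approx(V0[0] + V1[0])


class TestRcs:
    def test_k3_gives_two_columns(self):
        rng = np.random.default_rng(6)
        b = rcs_basis(rng.uniform(0, 100, 200), k=3)
        assert b.matrix.shape[1] == 2

    def test_linear_below_first_knot(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 100, 500)
        b = rcs_basis(x, k=5)
        below = x < b.knots[0]
        assert np.all(b.matrix[below, 1:] == 0.0)

    def test_linear_beyond_last_knot(self):
        """Second differences vanish above the boundary knot."""
        x = np.sort(np.random.default_rng(8).uniform(0, 100, 500))
        b = rcs_basis(x, k=4)
        xs = np.linspace(b.knots[-1] + 1, b.knots[-1] + 50, 100)
        M = b.evaluate(xs)
        second = np.diff(M, n=2, axis=0)
        assert np.abs(second).max() < 1e-8

    def test_second_derivative_continuous_at_knots(self):
        """The basis is piecewise cubic, so an exact cubic fit on each side
        of a knot recovers the one-sided second derivatives; they must
        agree at every interior knot for every column."""
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 100, 1000)
        b = rcs_basis(x, k=5)
        delta = 0.5
        scale = max(np.abs(np.diff(b.evaluate(np.linspace(0, 100, 400)),
                                   n=2, axis=0)).max() / (100 / 399) ** 2, 1e-12)
        for t in b.knots[1:-1]:
            left_x = np.linspace(t - delta, t, 4)
            right_x = np.linspace(t, t + delta, 4)
            for col in range(1, b.matrix.shape[1]):
                pl = np.polynomial.Polynomial.fit(
                    left_x, b.evaluate(left_x)[:, col], 3)
                pr = np.polynomial.Polynomial.fit(
                    right_x, b.evaluate(right_x)[:, col], 3)
                d2l = pl.deriv(2)(t)
                d2r = pr.deriv(2)(t)
                assert abs(d2l - d2r) / scale < 1e-6

    def test_quantile_placement(self):
        x = np.arange(1000, dtype=float)
        b = rcs_basis(x, k=5)
        np.testing.assert_allclose(
            b.knots, np.quantile(x, HARRELL_KNOT_QUANTILES[5]))

    def test_spline_loglik_improves_with_k(self, default_cohort):
        """More knots can only help the fit on the same data."""
        m3, _, _ = fit_rcs_cox(default_cohort, "tmtv_ml", 3)
        m5, _, _ = fit_rcs_cox(default_cohort, "tmtv_ml", 5)
        assert m5.log_likelihood >= m3.log_likelihood - 1e-6

    def test_select_knots_b1_single_sample(self, default_cohort):
        sel = select_knots_bootstrap(default_cohort, "tmtv_ml", B=1, seed=0)
        assert sel.selected_k == min(sel.mean_aic, key=sel.mean_aic.get)
        assert sel.per_resample_aic.shape[0] == 1


class TestConcordance:
    def test_perfect_scores(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        res = concordance(-t, t, e, jackknife=False)  # earlier event = higher risk
        assert res.c == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10, 800) + 0.01
        e = np.ones(800, dtype=int)
        res = concordance(rng.normal(size=800), t, e, jackknife=False)
        assert res.c == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10, 50).round(1) + 0.1
        e = rng.integers(0, 2, 50)
        s = rng.normal(size=50)
        res = concordance(s, t, e)
        assert res.c == pytest.approx(concordance_oracle(s, t, e), abs=1e-12)
        assert res.ci_lower < res.c < res.ci_upper

    def test_matches_lifelines_on_tie_free_data(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 80)
        e = rng.integers(0, 2, 80)
        s = rng.normal(size=80)
        assert concordance(s, t, e, jackknife=False).c == pytest.approx(
            lifelines_concordance(s, t, e), abs=1e-12)

    def test_no_usable_pairs_raises(self):
        with pytest.raises(ValueError):
            concordance([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestBootstrapOob:
    def test_partition_property(self):
        in_bag, oob = bootstrap_oob_split(100, 0)
        assert set(in_bag) | set(oob) == set(range(100))
        assert set(in_bag) & set(oob) == set()

    def test_oob_fraction_near_1_over_e(self):
        rng = np.random.default_rng(13)
        fractions = [bootstrap_oob_split(689, rng)[1].size / 689
                     for _ in range(1000)]
        assert 0.36 < np.mean(fractions) < 0.375

    def test_deterministic_per_seed(self):
        a = bootstrap_oob_split(50, 7)
        b = bootstrap_oob_split(50, 7)
        np.testing.assert_array_equal(a[0], b[0])
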
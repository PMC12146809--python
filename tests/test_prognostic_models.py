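"""Prognostic indices, risk models, agreement and the full pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmtvkit.prognostic_models import (AnalysisConfig, bif, bland_altman,
                                       combined_risk_group, flipi2_score,
                                       flipi_score, model_comparison,
                                       multivariable_model, pod24,
                                       run_full_analysis, to_report_json,
                                       to_report_markdown, univariable_table)
from tmtvkit.survival_core import concordance, cox_fit
from tmtvkit.synthetic_data import (CohortSpec, HazardModel, ReaderNoiseSpec,
                                    generate_cohort, simulate_readers)


def fisher_oracle(table):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2

    def prob(x):
        return (stats.hypergeom.pmf(x, n, row1, col1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        if prob(x) <= p_obs * (1 + 1e-9):
            total += prob(x)
    return total


class TestScoring:
    def test_flipi2_zero_factors(self):
        rec = dict(age_gt60=0, hb_lt12=0, b2m_gt_uln=0, bm_involved=0,
                   lodlin_gt6=0)
        score, cls = flipi2_score(rec)
        assert score == 0 and cls == "intermediate"

    def test_flipi2_three_factors_high(self):
        rec = dict(age_gt60=1, hb_lt12=1, b2m_gt_uln=0, bm_involved=1,
                   lodlin_gt6=0)
        score, cls = flipi2_score(rec)
        assert score == 3 and cls == "high"

    def test_flipi2_missing_factor_named(self):
        with pytest.raises(ValueError, match="bm_involved"):
            flipi2_score(dict(age_gt60=1, hb_lt12=0, b2m_gt_uln=0, lodlin_gt6=0))

    def test_flipi2_high_prevalence_near_40pct(self, large_cohort):
        _, cls = flipi2_score(large_cohort)
        assert abs((cls == "high").mean() - 0.40) < 0.04

    def test_flipi_classes(self):
        zero = dict(age_gt60=0, stage_3_4=0, hb_lt12=0, ldh_gt_uln=0, nodal_gt4=0)
        assert flipi_score(zero) == (0, "low")
        five = {k: 1 for k in zero}
        assert flipi_score(five) == (5, "high")
        two = dict(age_gt60=1, stage_3_4=1, hb_lt12=0, ldh_gt_uln=0, nodal_gt4=0)
        assert flipi_score(two)[1] == "intermediate"

    def test_flipi2_outperforms_flipi_when_it_drives_hazard(self):
        """The hazard acts through the FLIPI2-high class, so FLIPI2 should
        discriminate better than FLIPI in most replicates."""
        wins = 0
        for rep in range(5):
            df = generate_cohort(CohortSpec(n=600, seed=4000 + rep))
            t = df.pfs_months.to_numpy()
            e = df.pfs_event.to_numpy()
            s2, _ = flipi2_score(df)
            s1, _ = flipi_score(df)
            c2 = concordance(s2.to_numpy(float), t, e, jackknife=False).c
            c1 = concordance(s1.to_numpy(float), t, e, jackknife=False).c
            wins += c2 > c1
        assert wins >= 3


class TestRiskGroups:
    @pytest.mark.parametrize("tmtv,cls,expected", [
        (150.0, "intermediate", "low"),
        (400.0, "intermediate", "intermediate"),
        (150.0, "high", "intermediate"),
        (400.0, "high", "high"),
    ])
    def test_group_assignment(self, tmtv, cls, expected):
        assert combined_risk_group(tmtv, 180.0, cls) == expected

    def test_partition_of_cohort(self, default_cohort):
        _, cls = flipi2_score(default_cohort)
        groups = combined_risk_group(default_cohort.tmtv_ml.to_numpy(), 180.0, cls)
        counts = pd.Series(groups).value_counts()
        assert counts.sum() == len(default_cohort)

    def test_hazard_ordering_on_simulated_cohorts(self):
        """HR(high vs low) > HR(intermediate vs low) > 1 in the majority."""
        ordered = 0
        for rep in range(5):
            df = generate_cohort(CohortSpec(n=700, seed=5000 + rep))
            _, cls = flipi2_score(df)
            groups = combined_risk_group(df.tmtv_ml.to_numpy(), 180.0, cls)
            hrs = {}
            for g in ("intermediate", "high"):
                m = (groups == g) | (groups == "low")
                work = df[m].assign(_g=(groups[m] == g).astype(int))
                hrs[g] = float(cox_fit(work, ["_g"], strata="arm").hr["_g"])
            ordered += hrs["high"] > hrs["intermediate"] > 1.0
        assert ordered >= 3


class TestRegressionTables:
    def test_univariable_recovers_injected_binary_effect(self):
        df = generate_cohort(CohortSpec(n=2000, seed=6000))
        table = univariable_table(df, ["flipi2_high", "sex_male"])
        row = table[table.covariate == "flipi2_high"].iloc[0]
        assert row.ci_lower < 2.0 < row.ci_upper  # injected log-HR ln(2)
        assert row.n == df.flipi2_high.sum()

    def test_duplicated_cohort_strata_match_single_copy(self, default_cohort):
        df = default_cohort.assign(copy_id=0)
        doubled = pd.concat([df, df.assign(copy_id=1)], ignore_index=True)
        one = univariable_table(default_cohort, ["flipi2_high"], strata=None)
        two = univariable_table(doubled, ["flipi2_high"], strata="copy_id")
        assert one.iloc[0].HR == pytest.approx(two.iloc[0].HR, rel=1e-6)

    def test_degenerate_covariate_flagged_not_fatal(self, default_cohort):
        df = default_cohort.assign(flat=1)
        table = univariable_table(df, ["flat", "flipi2_high"])
        assert "note" in table.columns
        assert table[table.covariate == "flat"].iloc[0].notna()["note"]

    def test_multivariable_reports_both_forms(self, default_cohort):
        out = multivariable_model(default_cohort, cut=180.0)
        assert 1.0 < out["dichotomized"]["hr"] < 3.0
        assert out["continuous_per500"]["hr"] > 1.0

    def test_orthogonal_null_adjusters_change_little(self):
        df = generate_cohort(CohortSpec(
            n=3000, seed=6500,
            pfs_model=HazardModel(log_hr_covariates=())))  # only TMTV effect
        out = multivariable_model(df, cut=180.0)
        work = df.assign(_above=(df.tmtv_ml > 180).astype(int))
        una = cox_fit(work, ["_above"], strata="arm")
        assert out["dichotomized"]["hr"] == pytest.approx(
            float(una.hr["_above"]), rel=0.05)


class TestPod24:
    def test_reported_table_p_value(self):
        """The printed 2x2 (58/310 vs 42/354) gives Fisher p ~ 0.017."""
        table = np.array([[354 - 42, 42], [310 - 58, 58]])
        _, p = stats.fisher_exact(table)
        assert p == pytest.approx(0.017, abs=0.005)

    def test_identical_proportions_p_one(self):
        df = pd.DataFrame({
            "tmtv_ml": [100.0] * 20 + [400.0] * 20,
            "pfs_months": ([10.0] * 5 + [40.0] * 15) * 2,
            "pfs_event": ([1] * 5 + [0] * 15) * 2,
        })
        res = pod24(df, 180.0)
        assert res.p_value == pytest.approx(1.0)

    def test_fisher_matches_enumeration_oracle(self):
        for a, b, c, d in [(3, 7, 1, 9), (5, 5, 2, 8), (10, 0, 4, 6)]:
            table = np.array([[a, b], [c, d]])
            _, p = stats.fisher_exact(table)
            assert p == pytest.approx(fisher_oracle(table), abs=1e-10)

    def test_evaluability_rule(self):
        df = pd.DataFrame({
            "tmtv_ml": [100.0, 100.0, 400.0, 400.0],
            "pfs_months": [10.0, 12.0, 30.0, 5.0],
            "pfs_event": [0, 1, 0, 1],
        })
        res = pod24(df, 180.0)
        # censored at 10 months is not evaluable; the other three are
        assert res.n_evaluable == 3
        assert res.table.sum() == 3

    def test_chi2_variant(self, default_cohort):
        res = pod24(default_cohort, 180.0, test="chi2")
        assert 0.0 <= res.p_value <= 1.0


class TestModelComparison:
    def test_noise_covariate_delta_c_near_zero(self):
        deltas = []
        for rep in range(5):
            df = generate_cohort(CohortSpec(n=600, seed=7000 + rep))
            rng = np.random.default_rng(rep)
            work = df.assign(noise=rng.normal(size=len(df)))
            res = model_comparison(work, ["flipi2_high"], "noise")
            deltas.append(res["delta_c"])
        assert abs(np.mean(deltas)) < 0.02

    def test_real_effect_increases_c(self):
        wins = 0
        for rep in range(5):
            df = generate_cohort(CohortSpec(n=600, seed=7100 + rep))
            work = df.assign(_above=(df.tmtv_ml > 180).astype(int))
            res = model_comparison(work, ["flipi2_high"], "_above")
            wins += res["delta_c"] > 0
        assert wins >= 4

    def test_near_duplicate_covariate_adds_nothing(self, default_cohort):
        rng = np.random.default_rng(0)
        work = default_cohort.assign(
            f2=default_cohort.flipi2_high + rng.normal(0, 1e-3, len(default_cohort)))
        res = model_comparison(work, ["flipi2_high"], "f2")
        assert abs(res["delta_c"]) < 0.005


class TestBif:
    def test_b1_fraction_binary(self, default_cohort):
        rep = bif(default_cohort, 180.0, B=1, seed=0)
        assert rep.retained_lrt in (0.0, 1.0)

    def test_strong_effect_high_retention(self):
        df = generate_cohort(CohortSpec(
            n=700, seed=8000, pfs_model=HazardModel(log_hr_tmtv=np.log(2.0))))
        rep = bif(df, 180.0, B=50, seed=1)
        assert rep.retained_lrt > 0.9
        assert rep.retained_aic > 0.9


class TestBlandAltman:
    def test_identical_readers(self):
        mat = np.vstack([np.linspace(50, 400, 30)] * 2)
        res = bland_altman(mat)
        assert res.bias == 0.0 and res.cv_percent == 0.0

    def test_exact_ten_percent_offset(self):
        base = np.linspace(100, 300, 50)
        mat = np.vstack([base * 1.10, base])
        res = bland_altman(mat)
        # d = 0.1 b, m = 1.05 b -> d/m constant
        assert res.bias == pytest.approx(0.10 * base.mean())
        assert res.cv_percent == pytest.approx(100 * 0.1 / 1.05 / np.sqrt(2), rel=1e-6)

    def test_single_reader_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(np.ones((1, 10)))


@pytest.fixture(scope="module")
def small_config():
    return AnalysisConfig(n=250, seed=3, B=15, knot_selection_B=5)


@pytest.fixture(scope="module")
def report(small_config):
    return run_full_analysis(small_config)


class TestFullAnalysis:
    def test_all_sections_present(self, report):
        for section in ("summary", "cutpoints", "consensus", "univariable",
                        "multivariable", "pod24", "combined_model",
                        "model_comparison", "bif", "oob_validation",
                        "band_analysis", "published_cutoff", "agreement"):
            assert section in report, section

    def test_deterministic_json(self, small_config, report):
        again = run_full_analysis(small_config)
        assert to_report_json(report) == to_report_json(again)

    def test_markdown_renders(self, report):
        md = to_report_markdown(report)
        assert "Cutoff derivation" in md

    def test_os_absent_degrades_gracefully(self, small_config, tmp_path):
        from tmtvkit.synthetic_data import generate_cohort as gen, write_cohort
        df = gen(CohortSpec(n=200, seed=4)).drop(columns=["os_months", "os_event"])
        path = tmp_path / "cohort.csv"
        write_cohort(df, path)
        import dataclasses
        cfg = dataclasses.replace(small_config, cohort_csv=str(path))
        rep = run_full_analysis(cfg)
        assert rep["combined_model"]["os_note"].startswith("OS columns absent")
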
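import io
import math

import numpy as np
import pytest
from scipy import stats

from driverscan.meta import (
    PooledResult, StudyEffect, TwoByTwoStudy, cochran_q, genotype_chisq,
    genotype_totals, harbord_test, i_squared, leave_one_out, pool, pool_dl,
    pool_mh, read_studies_csv, select_model, study_effect,
)
from driverscan.synthetic import load_fixture, simulate_meta_studies


def mk(cn, cp, tn, tp, sid="s", eth="e"):
    return TwoByTwoStudy(study_id=sid, ethnicity=eth, case_null=cn,
                         case_present=cp, control_null=tn, control_present=tp)


class TestStudyEffect:
    def test_roy_2001_cross_product(self):
        e = study_effect(mk(17, 16, 8, 25))
        assert e.odds_ratio == pytest.approx(128 / 425, rel=1e-12)
        assert not e.corrected

    def test_symmetric_table_is_null(self):
        e = study_effect(mk(9, 9, 9, 9))
        assert e.log_or == 0.0

    def test_zero_cell_triggers_haldane_correction(self):
        e = study_effect(mk(0, 10, 5, 5))
        assert e.corrected
        assert e.odds_ratio == pytest.approx((10.5 * 5.5) / (5.5 * 0.5))
        assert e.se == pytest.approx(
            math.sqrt(1 / 10.5 + 1 / 5.5 + 1 / 0.5 + 1 / 5.5))

    def test_empty_margin_raises(self):
        # a genotype column can be empty even when both arms have subjects
        with pytest.raises(ValueError, match="margin"):
            study_effect(mk(5, 0, 5, 0))
        # an empty study arm is rejected at construction
        with pytest.raises(ValueError, match="no cases"):
            mk(0, 0, 5, 5)

    def test_woolf_se_reproduced(self):
        e = study_effect(mk(17, 16, 8, 25))
        assert e.se == pytest.approx(math.sqrt(1/17 + 1/16 + 1/8 + 1/25))


class TestGenotypeChisq:
    @pytest.mark.parametrize("table,expected_p", [
        ((17, 16, 8, 25), 0.022),   # Roy 2001, GSTM1/ATDH
        ((57, 30, 87, 89), 0.014),  # Harada 2001, GSTM1/SCZ
    ])
    def test_published_footnote_pvalues(self, table, expected_p):
        _, p = genotype_chisq(mk(*table))
        assert round(p, 3) == expected_p

    def test_equal_proportions_statistic_zero(self):
        chi2, p = genotype_chisq(mk(10, 20, 20, 40))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestCochranQ:
    def test_identical_effects_zero(self):
        effs = [study_effect(mk(10, 20, 10, 20, sid=str(i))) for i in range(4)]
        q, df, p = cochran_q(effs)
        assert q == pytest.approx(0.0)
        assert (df, p) == (3, pytest.approx(1.0))

    def test_term_by_term_hand_oracle(self):
        effs = [StudyEffect("a", 0.2, 0.1, False),
                StudyEffect("b", -0.1, 0.2, False),
                StudyEffect("c", 0.5, 0.25, False)]
        w = np.array([100.0, 25.0, 16.0])
        y = np.array([0.2, -0.1, 0.5])
        ybar = (w * y).sum() / w.sum()
        q_hand = ((w * (y - ybar) ** 2)).sum()
        q, df, p = cochran_q(effs)
        assert q == pytest.approx(q_hand, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(q_hand, 2), rel=1e-12)

    def test_gstm1_atdh_heterogeneity_p(self):
        effs = [study_effect(s) for s in load_fixture("gstm1_atdh")]
        _, _, p = cochran_q(effs)
        assert p == pytest.approx(0.088, abs=5e-4)

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            cochran_q([StudyEffect("a", 0.0, 1.0, False)])


class TestISquared:
    def test_q_equal_df_is_zero(self):
        i2, _, _ = i_squared(5.0, 5)
        assert i2 == 0.0

    def test_published_atdh_value(self):
        i2, lo, hi = i_squared(20.3, 13)
        assert i2 == pytest.approx((20.3 - 13) / 20.3 * 100, rel=1e-12)
        assert round(i2) == 36

    def test_gstt1_scz_interval(self):
        effs = [study_effect(s) for s in load_fixture("gstt1_scz")]
        q, df, _ = cochran_q(effs)
        i2, lo, hi = i_squared(q, df)
        assert round(i2) == 74
        assert lo == pytest.approx(35.1, abs=0.1)
        assert hi == pytest.approx(89.5, abs=0.1)

    def test_small_q_branch_produces_interval(self):
        i2, lo, hi = i_squared(2.0, 5)
        assert i2 == 0.0
        assert 0.0 <= lo <= hi <= 100.0

    def test_df_below_one_raises(self):
        with pytest.raises(ValueError):
            i_squared(1.0, 0)


class TestPooling:
    @pytest.mark.parametrize("fixture,or2,lo2,hi2", [
        ("gstm1_atdh", 0.71, 0.56, 0.90),
        ("gstm1_scz", 0.78, 0.66, 0.92),
        ("gstt1_scz", 1.37, 0.93, 2.03),
    ])
    def test_dl_reproduces_published_pooled_or(self, fixture, or2, lo2, hi2):
        res = pool_dl([study_effect(s) for s in load_fixture(fixture)])
        assert round(res.pooled_or, 2) == or2
        assert round(res.ci_low, 2) == lo2
        assert round(res.ci_high, 2) == hi2

    def test_identical_studies_tau2_zero_or_one(self):
        effs = [study_effect(mk(50, 50, 50, 50, sid=str(i))) for i in range(5)]
        res = pool_dl(effs)
        assert res.pooled_or == pytest.approx(1.0)
        assert res.tau2 == 0.0

    def test_dl_with_zero_tau2_equals_inverse_variance_fixed(self):
        effs = [study_effect(mk(50, 50, 50, 50, sid=str(i))) for i in range(4)]
        res = pool_dl(effs)
        y = np.array([e.log_or for e in effs])
        w = np.array([1 / e.se**2 for e in effs])
        assert res.log_or == pytest.approx((w * y).sum() / w.sum())

    def test_pooled_or_within_per_study_range(self):
        studies = load_fixture("gstm1_atdh")
        effs = [study_effect(s) for s in studies]
        ors = [e.odds_ratio for e in effs]
        res = pool_dl(effs)
        assert min(ors) <= res.pooled_or <= max(ors)

    def test_dl_agrees_with_statsmodels(self):
        # independent route: statsmodels' combined-effects machinery
        from statsmodels.stats.meta_analysis import combine_effects

        effs = [study_effect(s) for s in load_fixture("gstm1_atdh")]
        y = np.array([e.log_or for e in effs])
        v = np.array([e.se**2 for e in effs])
        sm = combine_effects(y, v, method_re="dl")
        res = pool_dl(effs)
        assert res.log_or == pytest.approx(sm.mean_effect_re, rel=1e-10)
        assert res.tau2 == pytest.approx(sm.tau2, rel=1e-10)

    def test_simulation_recovers_true_log_or(self):
        mus = []
        for rep in range(200):
            truth = simulate_meta_studies(
                k=10, theta=math.log(0.7), tau2=0.05, p0=0.5,
                n_cases_range=(200, 400), n_controls_range=(200, 400),
                rng_seed=1000 + rep)
            mus.append(pool_dl([study_effect(s) for s in truth.studies]).log_or)
        mc_se = np.std(mus) / math.sqrt(len(mus))
        assert abs(np.mean(mus) - math.log(0.7)) < 4 * mc_se + 0.01


class TestMantelHaenszel:
    def test_duplicated_stratum_equals_stratum_or(self):
        s = mk(17, 16, 8, 25)
        res = pool_mh([s] * 5)
        assert res.pooled_or == pytest.approx(128 / 425, rel=1e-12)

    def test_two_strata_hand_sum(self):
        s1, s2 = mk(10, 20, 15, 25), mk(8, 12, 20, 10)
        # a=case_present, b=control_present, c=case_null, d=control_null
        r = (20 * 15) / 70 + (12 * 20) / 50
        s_ = (25 * 10) / 70 + (10 * 8) / 50
        res = pool_mh([s1, s2])
        assert res.pooled_or == pytest.approx(r / s_, rel=1e-12)

    def test_gstm1_atdh_mh_brackets_crude_or(self):
        studies = load_fixture("gstm1_atdh")
        res = pool_mh(studies)
        # the crude Total-row cross-product is (331*981)/(348*1308) ~ 0.713
        assert 0.6 <= res.pooled_or <= 0.8

    def test_ci_contains_estimate(self):
        res = pool_mh(load_fixture("gstm1_scz"))
        assert res.ci_low <= res.pooled_or <= res.ci_high


class TestModelSelectionAndSensitivity:
    @pytest.mark.parametrize("k,model", [(2, "DL_random"), (14, "DL_random"),
                                         (19, "DL_random"), (20, "MH_fixed"),
                                         (25, "MH_fixed")])
    def test_study_count_rule(self, k, model):
        assert select_model(k) == model

    def test_identical_studies_leave_one_out_constant(self):
        studies = [mk(30, 20, 20, 30, sid=str(i)) for i in range(5)]
        full = pool(studies, model="DL_random")
        loo, pmin, pmax = leave_one_out(studies, model="DL_random")
        assert len(loo) == 5
        for _, r in loo:
            assert r.pooled_or == pytest.approx(full.pooled_or)
        assert pmin == pytest.approx(pmax)

    def test_three_studies_match_pairwise_pooling(self):
        studies = [mk(30, 20, 20, 30), mk(25, 30, 22, 28), mk(40, 10, 30, 20)]
        loo, _, _ = leave_one_out(studies, model="DL_random")
        for i, (omitted, res) in enumerate(loo):
            pair = [s for j, s in enumerate(studies) if j != i]
            assert res.pooled_or == pytest.approx(
                pool(pair, model="DL_random").pooled_or)

    def test_gstm1_atdh_fixed_effect_robust_to_any_omission(self):
        studies = load_fixture("gstm1_atdh")
        loo, pmin, pmax = leave_one_out(studies, model="MH_fixed")
        assert pmax < 0.05  # every omission keeps the pooled effect significant

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            leave_one_out([mk(1, 2, 3, 4), mk(4, 3, 2, 1)], model="DL_random")


class TestHarbord:
    def test_published_pvalues(self):
        _, _, _, p_atdh = harbord_test(load_fixture("gstm1_atdh"))
        _, _, _, p_scz = harbord_test(load_fixture("gstm1_scz"))
        assert p_atdh == pytest.approx(0.56, abs=0.01)
        assert p_scz == pytest.approx(0.0637, abs=0.001)

    def test_normal_equations_oracle(self):
        studies = [mk(10, 20, 15, 25), mk(8, 12, 20, 10),
                   mk(30, 40, 35, 45), mk(5, 15, 10, 20)]
        zs, vs = [], []
        for s in studies:
            a, b, c, d = s.case_present, s.control_present, s.case_null, s.control_null
            n = a + b + c + d
            zs.append(a - (a + b) * (a + c) / n)
            vs.append((a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1)))
        x = np.sqrt(vs)
        yv = np.array(zs) / x
        xb, yb = x.mean(), yv.mean()
        slope = ((x - xb) * (yv - yb)).sum() / ((x - xb) ** 2).sum()
        intercept_hand = yb - slope * xb
        intercept, se, t, p = harbord_test(studies)
        assert intercept == pytest.approx(intercept_hand, rel=1e-10)
        assert 0.0 <= p <= 1.0

    def test_collinear_null_construction(self):
        # balanced tables (a=b, c=d) have efficient score Z identically 0,
        # so every (sqrt(V), Z/sqrt(V)) point lies on the zero line through
        # the origin: intercept 0, no evidence of small-study effects
        studies = [mk(30, 20, 30, 20), mk(60, 40, 60, 40), mk(15, 10, 15, 10)]
        intercept, se, t, p = harbord_test(studies)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_needs_three_studies(self):
        with pytest.raises(ValueError):
            harbord_test([mk(1, 2, 3, 4), mk(4, 3, 2, 1)])


class TestIOAndTotals:
    def test_read_studies_csv_roundtrip(self):
        csv = ("study_id,ethnicity,case_null,case_present,"
               "control_null,control_present\nRoy 2001,Indian,17,16,8,25\n")
        (s,) = read_studies_csv(io.StringIO(csv))
        assert s == mk(17, 16, 8, 25, sid="Roy 2001", eth="Indian")

    def test_missing_column_raises(self):
        with pytest.raises(ValueError, match="missing"):
            read_studies_csv(io.StringIO("study_id,ethnicity\nx,y\n"))

    def test_fixture_totals_and_frequencies(self):
        t = genotype_totals(load_fixture("gstm1_atdh"))
        assert (t["n_cases"], t["n_controls"]) == (679, 2289)
        assert t["case_null_freq"] == pytest.approx(51.25, abs=0.005)
        assert t["n_minor"] == 1329
        assert t["minor_genotype"] == "null"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mk(-1, 2, 3, 4)
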
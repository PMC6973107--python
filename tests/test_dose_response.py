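"""Quadratic mixed dose-response fit, BMD machinery, Dunnett screening."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smach.dose_response import (
    QuadraticFit,
    back_transform,
    bmd,
    bmd_analysis,
    bmd_se_delta,
    bmdl,
    dose_scale,
    dunnett_anova,
    effective_dose,
    fit_quadratic_mixed,
    similarity_radius,
)
from smach.synthetic_data import LitterGenConfig, generate_litters


def _fit_from_beta(beta, vcov=None):
    return QuadraticFit(
        beta=np.asarray(beta, dtype=float),
        vcov=np.eye(3) if vcov is None else np.asarray(vcov),
        litter_variance=0.0,
        residual_variance=1.0,
        n_obs=65,
    )


class TestDoseScale:
    def test_control_maps_to_zero_and_monotone(self):
        x = dose_scale([0.0, 0.5, 10.0, 100.0])
        assert x[0] == 0.0
        assert (np.diff(x) > 0).all()

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            dose_scale([-1.0])


class TestQuadraticMixedFit:
    def test_noise_free_data_recovered_exactly(self):
        lit = generate_litters(
            LitterGenConfig(litter_sd=0.0, residual_sd=0.0, seed=0)
        )
        fit = fit_quadratic_mixed(lit.table)
        assert np.allclose(fit.beta, [1.0, -0.17, 0.07], atol=1e-8)

    def test_zero_litter_variance_matches_ols(self):
        lit = generate_litters(
            LitterGenConfig(litter_sd=0.0, residual_sd=0.05, seed=3)
        )
        fit = fit_quadratic_mixed(lit.table)
        x = dose_scale(lit.table["dose_multiple"].to_numpy())
        X = np.column_stack([np.ones_like(x), x, x * x])
        ols = np.linalg.lstsq(X, lit.table["response"].to_numpy(), rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_parameter_recovery_over_replicates(self):
        # mean coefficient estimates should be within Monte-Carlo error of
        # truth at the default litter design
        ests = []
        for seed in range(60):
            lit = generate_litters(LitterGenConfig(seed=seed))
            ests.append(fit_quadratic_mixed(lit.table).beta)
        ests = np.asarray(ests)
        mc_se = ests.std(axis=0) / np.sqrt(len(ests))
        assert np.all(np.abs(ests.mean(axis=0) - [1.0, -0.17, 0.07]) < 4 * mc_se)

    def test_fewer_than_three_doses_rejected(self):
        tab = pd.DataFrame(
            {
                "litter_id": ["a", "a", "b", "b"],
                "dose_multiple": [0.0, 0.0, 1.0, 1.0],
                "response": [1.0, 1.1, 0.9, 0.95],
            }
        )
        with pytest.raises(ValueError, match="3 distinct dose"):
            fit_quadratic_mixed(tab)


class TestBmdRoot:
    def test_linear_case(self):
        assert bmd(_fit_from_beta([1.0, -0.1, 0.0]), 0.05) == pytest.approx(0.5)

    def test_quadratic_worked_example(self):
        # root of 0.06917 x^2 - 0.17088 x + 0.05*1.0028 = 0
        fit = _fit_from_beta([1.0028, -0.17088, 0.06917])
        assert bmd(fit, 0.05) == pytest.approx(0.3403, abs=5e-4)

    def test_bmd_vanishes_with_bmr(self):
        fit = _fit_from_beta([1.0, -0.17, 0.07])
        bmrs = [0.04, 0.02, 0.01, 0.001]
        roots = [bmd(fit, b) for b in bmrs]
        assert all(np.diff(roots) < 0)
        assert roots[-1] < 0.01

    def test_monotone_in_bmr_for_decreasing_curve(self):
        fit = _fit_from_beta([1.0, -0.1, 0.0])
        roots = [bmd(fit, b) for b in (0.02, 0.05, 0.08)]
        assert roots[0] < roots[1] < roots[2]

    def test_unreachable_bmr_raises(self):
        # max decline of this curve is ~1%, so a 5% decline has no real root
        fit = _fit_from_beta([1.0, -0.05, 0.06])
        with pytest.raises(ValueError, match="not reached"):
            bmd(fit, 0.05)

    def test_increasing_curve_raises(self):
        with pytest.raises(ValueError):
            bmd(_fit_from_beta([1.0, 0.1, 0.0]), 0.05)


class TestDeltaMethodSe:
    def test_linear_case_closed_form(self):
        vcov = np.diag([0.01, 0.0004, 0.0])
        fit = _fit_from_beta([1.0, -0.1, 0.0], vcov)
        x = bmd(fit, 0.05)
        se, unstable = bmd_se_delta(fit, x, 0.05)
        # gradient (bmr/-b1... ) reduces to (-bmr/b1, -x/b1, -x^2/b1)
        g = np.array([-0.05 / -0.1, -x / -0.1, -(x ** 2) / -0.1])
        assert se == pytest.approx(np.sqrt(g @ vcov @ g), rel=1e-9)
        assert not unstable

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 20:
            b0 = rng.uniform(0.8, 1.2)
            b1 = rng.uniform(-0.3, -0.1)
            b2 = rng.uniform(0.0, 0.08)
            beta = np.array([b0, b1, b2])
            fit = _fit_from_beta(beta)
            try:
                x = bmd(fit, 0.05)
            except ValueError:
                continue
            checked += 1
            eps = 1e-7
            num = np.empty(3)
            for j in range(3):
                bp, bm = beta.copy(), beta.copy()
                bp[j] += eps
                bm[j] -= eps
                num[j] = (
                    bmd(_fit_from_beta(bp), 0.05) - bmd(_fit_from_beta(bm), 0.05)
                ) / (2 * eps)
            from smach.dose_response import _bmd_gradient

            assert np.allclose(_bmd_gradient(beta, x, 0.05), num, rtol=1e-5)


class TestEffectiveDoseAndRadius:
    def test_linear_effective_dose(self):
        assert effective_dose(_fit_from_beta([1.0, -0.1, 0.0]), 0.08) == pytest.approx(0.8)

    def test_decline_equal_bmr_is_identity(self):
        fit = _fit_from_beta([1.0, -0.17, 0.07])
        assert effective_dose(fit, 0.05) == bmd(fit, 0.05)

    def test_radius_worked_example(self):
        assert similarity_radius(0.49, 1.05) == pytest.approx(0.56)
        assert similarity_radius(0.3, 0.3) == 0.0
        assert similarity_radius(0.49 + 1.0, 1.05 + 1.0) == pytest.approx(0.56)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            similarity_radius(1.0, 0.5)

    def test_back_transform_one_decimal(self):
        assert round(back_transform(0.49), 1) == 2.1
        assert round(back_transform(1.05), 1) == 10.2


class TestBmdl:
    def test_zero_se_returns_bmd(self):
        assert bmdl(0.49, 0.0, 62) == 0.49

    def test_normal_quantile_value(self):
        assert bmdl(0.49, 0.33, None) == pytest.approx(-0.0528, abs=5e-4)

    def test_monotone_decreasing_in_se(self):
        vals = [bmdl(0.49, s, 62) for s in (0.1, 0.2, 0.4)]
        assert vals[0] > vals[1] > vals[2]

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            bmdl(0.49, 0.33, 0)


class TestDunnett:
    def test_group_pattern_with_depressed_mid_and_high_doses(self):
        # plant the observed group-mean pattern: mid/high doses depressed,
        # low dose slightly elevated but within noise; unbalanced litter
        # counts as in a real developmental study (frozen seed)
        rng = np.random.default_rng(13)
        means = {0.0: 0.99, 0.5: 1.02, 10.0: 0.89, 100.0: 0.94}
        dams = {0.0: 6, 0.5: 3, 10.0: 4, 100.0: 5}
        rows, lid = [], 0
        for d, m in means.items():
            for _ in range(dams[d]):
                lid += 1
                u = 0.015 * rng.standard_normal()
                for e in 0.04 * rng.standard_normal(5):
                    rows.append(
                        {"litter_id": f"L{lid}", "dose_multiple": d,
                         "response": m + u + float(e)}
                    )
        tab = dunnett_anova(pd.DataFrame(rows), mc_seed=1)
        assert tab.loc[10.0, "significant"]
        assert tab.loc[100.0, "significant"]
        assert not tab.loc[0.5, "significant"]
        assert tab.loc[10.0, "estimate"] < 0

    def test_single_comparison_matches_unadjusted_t(self):
        rng = np.random.default_rng(5)
        rows = []
        for lid in range(12):
            d = 0.0 if lid < 6 else 10.0
            shift = 0.0 if lid < 6 else -0.06
            u = 0.02 * rng.standard_normal()
            for e in 0.04 * rng.standard_normal(5):
                rows.append({"litter_id": f"L{lid}", "dose_multiple": d,
                             "response": 1.0 + shift + u + float(e)})
        tab = dunnett_anova(pd.DataFrame(rows), n_mc=200_000, mc_seed=2)
        t, df = tab.loc[10.0, "t"], 12 - 2
        p_unadj = 2 * stats.t.sf(abs(t), df)
        assert tab.loc[10.0, "p_adj"] == pytest.approx(p_unadj, abs=0.01)

    def test_missing_control_rejected(self):
        tab = pd.DataFrame(
            {"litter_id": list("aabb"), "dose_multiple": [1.0, 1.0, 2.0, 2.0],
             "response": [1.0, 1.1, 0.9, 0.95]}
        )
        with pytest.raises(ValueError, match="control"):
            dunnett_anova(tab)


def test_bmd_analysis_end_to_end(default_litters):
    fit, res = bmd_analysis(default_litters.table)
    assert res.bmd > 0
    assert res.ed8 > res.bmd
    assert res.radius == pytest.approx(res.ed8 - res.bmd)
    assert res.bmdl < res.bmd
    assert res.bmd_multiple == pytest.approx(back_transform(res.bmd))
    assert fit.litter_variance >= 0
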
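"""Instrument screening, first stage, IV diagnostics, CF/2SLS identities."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from geopersona.control_function import (
    ControlFunctionRegressor,
    anderson_underid,
    cf_second_stage,
    cragg_donald,
    davidson_mackinnon,
    first_stage,
    linear_control_function,
    sargan,
    select_instruments,
    stock_yogo_critical,
    two_sls,
)
from geopersona.errors import DegenerateError, DesignError, ScreeningFailureError
from geopersona.simulate import SimConfig, generate_panel


def iv_data(n=2000, seed=0, strength=0.7, endog=0.0, invalid=0.0):
    """One linear IV dataset: trait x, instruments z1/z2, control c, outcome y.

    ``endog`` loads an omitted factor on both x and the outcome error;
    ``invalid`` loads instrument z1 directly on the outcome error.
    """
    rng = np.random.default_rng(seed)
    h = rng.standard_normal(n)  # omitted factor
    base = rng.standard_normal(n)
    z = strength * base[:, None] + np.sqrt(1 - strength**2) * rng.standard_normal((n, 2))
    c = rng.standard_normal(n)
    x = base + endog * h + 0.3 * c + 0.5 * rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = 1.0 + 2.0 * x + 0.7 * c + endog * h + invalid * z[:, 0] + e
    return y, x, z, c[:, None]


class TestSelectInstruments:
    def panel_frames(self, seed=1):
        y, x, z, c = iv_data(seed=seed)
        traits = pd.DataFrame({"neuroticism": x})
        cands = pd.DataFrame({"z1": z[:, 0], "z2": z[:, 1], "noise": np.random.default_rng(seed + 1).standard_normal(len(x))})
        return y, traits, cands

    def test_trait_itself_retained_iff_outcome_screen_passes(self):
        y, traits, cands = self.panel_frames()
        cands["self"] = traits["neuroticism"]
        # the trait drives the outcome, so corr(self, y) is large: rejected
        with_screen = select_instruments(cands, traits, y, r_outcome_max=0.99)
        assert "self" in with_screen.instruments["neuroticism"]
        with pytest.raises(ScreeningFailureError):
            select_instruments(cands[["self"]], traits, y, r_outcome_max=0.1)

    def test_pure_noise_candidate_rejected(self):
        y, traits, cands = self.panel_frames()
        res = select_instruments(cands, traits, y, r_outcome_max=1.0)
        assert "noise" not in res.instruments["neuroticism"]
        report = res.report.set_index("candidate")
        assert abs(report.loc["noise", "r_trait"]) < 0.1

    def test_vacuous_thresholds_retain_all(self):
        y, traits, cands = self.panel_frames()
        res = select_instruments(
            cands, traits, y, r_trait_min=0.0, r_outcome_max=1.0, alpha=1.0
        )
        assert res.instruments["neuroticism"] == list(cands.columns)

    def test_screening_idempotent(self):
        y, traits, cands = self.panel_frames()
        first = select_instruments(cands, traits, y, r_outcome_max=1.0)
        kept = first.instruments["neuroticism"]
        second = select_instruments(cands[kept], traits, y, r_outcome_max=1.0)
        assert second.instruments["neuroticism"] == kept


def as_panel(y, x, z, c, n_counties=None):
    n = len(y)
    n_counties = n_counties or n // 2
    return pd.DataFrame(
        {
            "fips": [f"{i % n_counties:05d}" for i in range(n)],
            "year": [2014 + (i // n_counties) % 3 for i in range(n)],
            "lower": y,
            "upper": y,
            "observed_exact": True,
            "neuroticism": x,
            "z1": z[:, 0],
            "z2": z[:, 1],
            "c": c[:, 0],
        }
    )


class TestFirstStage:
    def test_exact_linear_trait_gives_zero_residuals(self):
        y, x, z, c = iv_data(seed=2)
        panel = as_panel(y, z[:, 0] + 2 * z[:, 1], z, c)
        fs = first_stage("neuroticism", panel, ["z1", "z2"], ["c"], year_dummies=False)
        assert np.max(np.abs(fs.residuals)) < 1e-10

    def test_residuals_orthogonal_to_regressors(self):
        y, x, z, c = iv_data(seed=3)
        panel = as_panel(y, x, z, c)
        fs = first_stage("neuroticism", panel, ["z1", "z2"], ["c"], year_dummies=False)
        for col in ("z1", "z2", "c"):
            assert abs(fs.residuals @ panel[col].to_numpy()) < 1e-8 * len(y)

    def test_strong_instruments_give_large_partial_f(self):
        y, x, z, c = iv_data(seed=4, strength=0.8)
        panel = as_panel(y, x, z, c)
        fs = first_stage("neuroticism", panel, ["z1", "z2"], ["c"], year_dummies=False)
        assert fs.partial_f > 10


class TestAnderson:
    def test_duplicated_trait_gives_stat_n(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(400)
        c = rng.standard_normal((400, 1))
        stat, p = anderson_underid(x, x.copy(), c)
        assert stat == pytest.approx(400, rel=1e-10)

    def test_strong_instruments_reject_underidentification(self):
        y, x, z, c = iv_data(seed=6)
        stat, p = anderson_underid(x, z, c)
        assert p < 1e-3

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            n = 200
            x = rng.standard_normal(n)
            z = rng.standard_normal((n, 2))  # unrelated to x
            c = rng.standard_normal((n, 1))
            pvals.append(anderson_underid(x, z, c)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestCraggDonald:
    def test_equals_partial_f_single_endogenous_single_instrument(self):
        y, x, z, c = iv_data(seed=8)
        panel = as_panel(y, x, z, c)
        fs = first_stage("neuroticism", panel, ["z1"], ["c"], year_dummies=False)
        cd = cragg_donald(x, z[:, :1], c)
        assert cd == pytest.approx(fs.partial_f, abs=1e-8)

    def test_zero_strength_near_zero_and_nonnegative(self):
        y, x, z, c = iv_data(seed=9)
        rng = np.random.default_rng(10)
        znoise = rng.standard_normal((len(x), 2))
        cd = cragg_donald(x, znoise, c)
        assert 0 <= cd < 5

    def test_critical_value_table(self):
        assert stock_yogo_critical(3) == 13.91
        assert stock_yogo_critical(1) == 16.38  # size table fallback
        assert stock_yogo_critical(99) is None


class TestSargan:
    def test_orthogonal_residuals_give_zero(self):
        rng = np.random.default_rng(11)
        Z = rng.standard_normal((300, 2))
        C = rng.standard_normal((300, 1))
        e = rng.standard_normal(300)
        W = np.column_stack([np.ones(300), Z, C])
        e = e - W @ np.linalg.lstsq(W, e, rcond=None)[0]
        stat, df, p = sargan(e, Z, C)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert df == 1

    def test_just_identified_raises(self):
        rng = np.random.default_rng(12)
        with pytest.raises(DesignError):
            sargan(rng.standard_normal(100), rng.standard_normal((100, 1)), rng.standard_normal((100, 1)))

    def test_detects_invalid_instrument(self):
        rejections = 0
        for seed in range(40):
            y, x, z, c = iv_data(n=2000, seed=200 + seed, invalid=0.4)
            beta = two_sls(y, x, z, c)
            W = np.column_stack([np.ones(len(y)), x, c])
            resid = y - W @ beta
            _, _, p = sargan(resid, z, c)
            rejections += p < 0.05
        assert rejections / 40 > 0.5


class TestDavidsonMacKinnon:
    def test_null_p_values_uniform(self):
        pvals = []
        for seed in range(300):
            y, x, z, c = iv_data(n=300, seed=1000 + seed, endog=0.0)
            Ins = np.column_stack([np.ones(len(y)), z, c])
            R = x - Ins @ np.linalg.lstsq(Ins, x, rcond=None)[0]
            pvals.append(davidson_mackinnon(y, x, c, R)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_power_under_confounding(self):
        rejections = 0
        for seed in range(50):
            y, x, z, c = iv_data(n=2000, seed=2000 + seed, endog=0.8)
            Ins = np.column_stack([np.ones(len(y)), z, c])
            R = x - Ins @ np.linalg.lstsq(Ins, x, rcond=None)[0]
            rejections += davidson_mackinnon(y, x, c, R)[1] < 0.05
        assert rejections / 50 > 0.8

    def test_zero_residuals_degenerate(self):
        y, x, z, c = iv_data(seed=13)
        with pytest.raises(DegenerateError):
            davidson_mackinnon(y, x, c, np.zeros_like(x))


class TestTwoSLS:
    def test_equals_ols_when_instrument_is_regressor(self):
        y, x, z, c = iv_data(seed=14, endog=0.0)
        beta_iv = two_sls(y, x, x.copy(), c)
        W = np.column_stack([np.ones(len(y)), x, c])
        beta_ols = np.linalg.lstsq(W, y, rcond=None)[0]
        np.testing.assert_allclose(beta_iv, beta_ols, atol=1e-10)

    def test_cf_identity_on_linear_exact_data(self):
        y, x, z, c = iv_data(seed=15, endog=0.8)
        np.testing.assert_allclose(
            linear_control_function(y, x, z, c), two_sls(y, x, z, c), atol=1e-8
        )

    def test_deterministic(self):
        y, x, z, c = iv_data(seed=16)
        np.testing.assert_array_equal(two_sls(y, x, z, c), two_sls(y, x, z, c))

    def test_order_condition(self):
        y, x, z, c = iv_data(seed=17)
        with pytest.raises(DesignError):
            two_sls(y, np.column_stack([x, c[:, 0] + x]), z[:, :1], c)


class TestControlFunctionSecondStage:
    def make_panel(self, seed, endog, n_counties=150, T=3):
        cfg = SimConfig(
            n_counties=n_counties, n_years=T, seed=seed, intercept_true=-8.0,
            beta_true={"neuroticism": 0.25}, gamma_true={},
            sigma_u=2.0, sigma_e=3.0, confounder_strength=endog,
        )
        latent, out = generate_panel(cfg)
        return out.merge(latent, on=["fips", "year"])

    def test_exogenous_data_cf_agrees_with_naive(self):
        from geopersona.interval_model import fit_interval_re

        panel = self.make_panel(seed=31, endog=0.0, n_counties=250)
        naive = fit_interval_re(panel, ["neuroticism"])
        cf = ControlFunctionRegressor(
            instruments={"neuroticism": ["z_neuroticism_1", "z_neuroticism_2"]},
            trait_cols=["neuroticism"],
        ).fit(panel)
        diff = abs(cf.fit_.params["neuroticism"] - naive.params["neuroticism"])
        assert diff < 2 * naive.se["neuroticism"]

    def test_endogenous_data_cf_reduces_bias(self):
        from geopersona.interval_model import fit_interval_re

        panel = self.make_panel(seed=32, endog=0.6, n_counties=300)
        naive = fit_interval_re(panel, ["neuroticism"])
        cf = ControlFunctionRegressor(
            instruments={"neuroticism": ["z_neuroticism_1", "z_neuroticism_2"]},
            trait_cols=["neuroticism"],
        ).fit(panel)
        err_naive = abs(naive.params["neuroticism"] - 0.25)
        err_cf = abs(cf.fit_.params["neuroticism"] - 0.25)
        assert err_cf < err_naive

    def test_cf_reduces_bias_across_seeds_linear(self):
        # linear all-exact analogue of the interval CF, cheap enough to
        # repeat: CF must beat naive OLS in most replicates
        wins = 0
        for seed in range(50):
            y, x, z, c = iv_data(n=800, seed=3000 + seed, endog=0.8)
            W = np.column_stack([np.ones(len(y)), x, c])
            naive = np.linalg.lstsq(W, y, rcond=None)[0][1]
            cfb = linear_control_function(y, x, z, c)[1]
            wins += abs(cfb - 2.0) < abs(naive - 2.0)
        assert wins >= 40

    def test_residual_alignment_listwise_drop(self):
        from geopersona.interval_model import fit_interval_re

        panel = self.make_panel(seed=33, endog=0.0, n_counties=60)
        resid = panel[["fips", "year"]].copy()
        rng = np.random.default_rng(0)
        resid["resid_neuroticism"] = rng.standard_normal(len(resid))
        resid.loc[resid.index[:12], "resid_neuroticism"] = np.nan
        fit = cf_second_stage(panel, resid, ["neuroticism"], [])
        assert fit.n_obs == len(panel) - 12

    def test_diagnostics_frame_shape(self):
        panel = self.make_panel(seed=34, endog=0.3, n_counties=120)
        cf = ControlFunctionRegressor(
            instruments={"neuroticism": ["z_neuroticism_1", "z_neuroticism_2"]},
            trait_cols=["neuroticism"],
        ).fit(panel)
        d = cf.diagnostics_frame()
        assert list(d["trait"]) == ["neuroticism"]
        assert (d["sargan_df"] == 1).all()
        assert ((0 <= d["sargan_p"]) & (d["sargan_p"] <= 1)).all()
        assert d["anderson_p"].iloc[0] < 1e-3
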
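"""Mixed-model fitting, likelihood-ratio tests, Tukey contrasts, % changes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sprintox.inference import (
    fit_mixed_model,
    lrt_effect,
    percent_change_summary,
    test_effect as lrt_for_effect,
    tukey_contrasts,
)
from sprintox.synthetic import simulate_endpoint_table


def balanced_table(n=8, effects=(0.0, -5.0, -10.0), intercepts=None,
                   resid_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    if intercepts is None:
        intercepts = rng.normal(0.0, 4.0, n)
    rows = []
    for i in range(n):
        for cond, eff in zip((0, 45, 60), effects):
            rows.append({"participant": f"P{i}", "condition": cond,
                         "value": 30.0 + eff + intercepts[i]
                         + rng.normal(0.0, resid_sd)})
    return pd.DataFrame(rows)


class TestFitMixedModel:
    def test_perfect_fit_limit_recovers_effects_exactly(self):
        tab = balanced_table(effects=(0.0, -5.0, -10.0), resid_sd=0.0)
        fit = fit_mixed_model(tab)
        fe = fit.result.fe_params
        est = {int(k.split("T.")[1].rstrip("]")): v
               for k, v in fe.items() if "condition" in k}
        assert est[45] == pytest.approx(-5.0, abs=1e-6)
        assert est[60] == pytest.approx(-10.0, abs=1e-6)

    def test_single_participant_rejected(self):
        tab = balanced_table(n=8)
        with pytest.raises(ValueError, match="participants"):
            fit_mixed_model(tab[tab.participant == "P0"])

    def test_single_level_factor_rejected(self):
        tab = balanced_table(n=8)
        with pytest.raises(ValueError, match="levels"):
            fit_mixed_model(tab[tab.condition == 0])

    def test_estimates_recovered_within_noise(self):
        tab = simulate_endpoint_table(40, 30.0, 10.0, 3.0,
                                      factors={0: 1.0, 45: 0.8, 60: 0.6},
                                      seed=9)
        fit = fit_mixed_model(tab, reml=True)
        fe = fit.result.fe_params
        est = {int(k.split("T.")[1].rstrip("]")): v
               for k, v in fe.items() if "condition" in k}
        assert est[45] == pytest.approx(-6.0, abs=2.0)
        assert est[60] == pytest.approx(-12.0, abs=2.0)


class TestLrt:
    def test_identical_models_statistic_zero(self):
        tab = balanced_table(resid_sd=2.0)
        a = fit_mixed_model(tab)
        b = fit_mixed_model(tab)
        res = lrt_effect(a, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == 1.0

    def test_affine_invariance(self):
        tab = balanced_table(effects=(0.0, -3.0, -6.0), resid_sd=2.0, seed=4)
        r1 = lrt_for_effect(tab, "condition")
        tab2 = tab.assign(value=5.0 * tab.value + 100.0)
        r2 = lrt_for_effect(tab2, "condition")
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-4)

    def test_reml_fits_rejected_for_lrt(self):
        tab = balanced_table(resid_sd=2.0)
        a = fit_mixed_model(tab, reml=True)
        b = fit_mixed_model(tab, reml=True)
        with pytest.raises(ValueError, match="ML"):
            lrt_effect(a, b)

    def test_large_effect_detected(self):
        tab = simulate_endpoint_table(11, 30.0, 12.0, 3.0,
                                      factors={0: 1.0, 45: 0.526, 60: 0.342},
                                      seed=2)
        res = lrt_for_effect(tab, "condition")
        assert res.df == 2
        assert res.p_value < 1e-4

    def test_f_and_chisq_references_agree_at_large_n(self):
        tab = simulate_endpoint_table(400, 30.0, 12.0, 3.0,
                                      factors={0: 1.0, 45: 0.98, 60: 1.0},
                                      seed=5)
        pf = lrt_for_effect(tab, "condition", reference="f").p_value
        pc = lrt_for_effect(tab, "condition", reference="chisq").p_value
        assert pf == pytest.approx(pc, abs=0.01)


class TestTukey:
    def test_two_level_factor_equals_plain_t(self):
        tab = balanced_table(effects=(0.0, -4.0, 0.0), resid_sd=2.0, seed=3)
        tab = tab[tab.condition != 60]
        fit = fit_mixed_model(tab, reml=True)
        con = tukey_contrasts(fit, "condition")
        assert len(con) == 1
        t = abs(con.t.iloc[0])
        p_t = 2 * stats.t.sf(t, con.attrs["df"])
        assert con.p_tukey.iloc[0] == pytest.approx(p_t, abs=1e-4)

    def test_equal_means_zero_contrasts(self):
        tab = balanced_table(effects=(0.0, 0.0, 0.0), resid_sd=0.0)
        fit = fit_mixed_model(tab)
        con = tukey_contrasts(fit, "condition")
        assert np.allclose(con.estimate, 0.0, atol=1e-8)

    def test_contrast_loop_sums_to_zero(self):
        tab = balanced_table(effects=(0.0, -5.0, -9.0), resid_sd=2.0, seed=8)
        fit = fit_mixed_model(tab)
        con = tukey_contrasts(fit, "condition").set_index(["level_a", "level_b"])
        loop = (con.loc[(0, 45), "estimate"] + con.loc[(45, 60), "estimate"]
                - con.loc[(0, 60), "estimate"])
        assert loop == pytest.approx(0.0, abs=1e-10)

    def test_adjusted_p_not_below_unadjusted_for_three_levels(self):
        tab = balanced_table(effects=(0.0, -2.0, -3.0), resid_sd=2.5, seed=12)
        fit = fit_mixed_model(tab, reml=True)
        con = tukey_contrasts(fit, "condition")
        df = con.attrs["df"]
        for _, row in con.iterrows():
            p_unadj = 2 * stats.t.sf(abs(row.t), df)
            assert row.p_tukey >= p_unadj - 1e-9

    def test_ls_means_match_cell_means_in_balanced_design(self):
        tab = balanced_table(effects=(0.0, -5.0, -10.0), resid_sd=0.0)
        fit = fit_mixed_model(tab)
        ls = tukey_contrasts(fit, "condition").attrs["ls_means"]
        cell = tab.groupby("condition")["value"].mean()
        for _, row in ls.iterrows():
            assert row.ls_mean == pytest.approx(cell[row.level], abs=1e-6)


class TestPercentChange:
    def test_uniform_halving(self):
        rows = []
        for i in range(6):
            base = 20.0 + i
            for cond, v in ((0, base), (45, base / 2), (60, base / 2)):
                rows.append({"participant": f"P{i}", "condition": cond,
                             "value": v})
        out = percent_change_summary(pd.DataFrame(rows))
        assert np.allclose(out.mean_pct_decrease, 50.0)
        assert np.allclose(out.sd_pct_decrease, 0.0)

    def test_zero_reference_excluded_with_warning(self):
        rows = [{"participant": "P0", "condition": c, "value": v}
                for c, v in ((0, 0.0), (45, 1.0), (60, 1.0))]
        rows += [{"participant": "P1", "condition": c, "value": v}
                 for c, v in ((0, 10.0), (45, 5.0), (60, 2.5))]
        with pytest.warns(UserWarning, match="zero reference"):
            out = percent_change_summary(pd.DataFrame(rows))
        assert out.loc[out.condition == 45, "mean_pct_decrease"].iloc[0] == \
            pytest.approx(50.0)
        assert (out.n == 1).all()

    def test_preset_effects_recovered(self):
        tab = simulate_endpoint_table(60, 30.0, 3.0, 1.0,
                                      factors={0: 1.0, 45: 0.526, 60: 0.342},
                                      seed=21)
        out = percent_change_summary(tab).set_index("condition")
        assert out.loc[45, "mean_pct_decrease"] == pytest.approx(47.4, abs=3.0)
        assert out.loc[60, "mean_pct_decrease"] == pytest.approx(65.8, abs=3.0)
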
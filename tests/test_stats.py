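"""Transforms, mixed models, marginal means and rmcorr."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capiflow as cf
from capiflow import stats as cstats

warnings.filterwarnings("ignore", module="statsmodels")


class TestBoxcox:
    def test_unit_input_is_zero(self):
        for lam in (-0.5, -0.3, 0.0, 0.7):
            assert cf.boxcox(1.0, lam) == 0.0

    def test_lambda_zero_limit_is_log(self):
        y = np.array([0.5, 2.0, 32.0])
        np.testing.assert_allclose(cf.boxcox(y, 1e-8), np.log(y), atol=1e-6)

    def test_reference_value(self):
        # (32^-0.3 - 1) / -0.3 evaluated directly at high precision
        assert cf.boxcox(32.0, -0.3) == pytest.approx(2.1548220313557542, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cf.boxcox(-1.0, -0.3)

    @given(
        st.floats(min_value=0.01, max_value=1e3),
        st.floats(min_value=-1.0, max_value=1.0),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_invertible_and_increasing(self, y, lam):
        # away from the saturation point -1/lambda, where float64 loses
        # the information needed to invert
        t = cf.boxcox(y, lam)
        assert cf.inv_boxcox(t, lam) == pytest.approx(y, rel=1e-9)
        assert cf.boxcox(y * 1.01, lam) > t


class TestFitMixed:
    def test_zero_rat_variance_detected(self):
        table, _ = cstats.simulate_speed_table(seed=1, rat_sd_log=0.0)
        fit = cf.fit_mixed(table)
        re_var = float(np.asarray(fit.result.cov_re).ravel()[0])
        assert re_var <= 1e-4 * float(fit.result.scale)
        assert fit.singular

    def test_layer_effect_recovered_within_2_se(self):
        hits = 0
        for seed in range(30):
            table, truth = cstats.simulate_speed_table(seed=200 + seed)
            fit = cf.fit_mixed(table)
            cols = fit.design_info.column_names
            i = [j for j, c in enumerate(cols) if "layer" in c][0]
            est, se = fit.fe_params[i], math.sqrt(fit.fe_cov[i, i])
            if abs(est - truth["layer_effect_log"]) <= 2 * se:
                hits += 1
        assert hits >= 27  # ~95% nominal; allow binomial slack at n=30

    def test_single_rat_rejected(self):
        table, _ = cstats.simulate_speed_table(seed=0, n_rats=1)
        with pytest.raises(ValueError):
            cf.fit_mixed(table)

    def test_shapiro_p_recorded(self):
        table, _ = cstats.simulate_speed_table(seed=3)
        fit = cf.fit_mixed(table)
        assert 0.0 <= fit.shapiro_p <= 1.0

    def test_diameter_model_nested_random_effects(self):
        rng = np.random.default_rng(0)
        rows = []
        for ri in range(4):
            for layer in ("SL", "DL"):
                for vt in ("C", "V3"):
                    for method in ("invivo", "histology"):
                        for j in range(3):
                            d = 8.0 + (2.0 if layer == "SL" else 0.0)
                            d += 4.0 if method == "invivo" else 0.0
                            rows.append(
                                {
                                    "rat_id": f"rat{ri}", "layer": layer,
                                    "vessel_type": vt,
                                    "vessel_id": f"{ri}{layer}{vt}{method}{j}",
                                    "window_index": 0,
                                    "value": float(d * rng.lognormal(0, 0.1)),
                                    "value_kind": "diameter_um",
                                    "method": method,
                                }
                            )
        fit = cf.fit_mixed(pd.DataFrame(rows), cstats.DIAMETER_MODEL)
        cols = fit.design_info.column_names
        i = [j for j, c in enumerate(cols) if "method" in c][0]
        assert fit.fe_params[i] != 0.0  # in vivo inflation picked up


class TestEmmeans:
    def test_identical_cells_give_equal_emms(self):
        rng = np.random.default_rng(5)
        rows = []
        for ri in range(4):
            for layer in ("SL", "DL"):
                for vt in ("C", "V3"):
                    for j in range(4):
                        rows.append(
                            {
                                "rat_id": f"rat{ri}", "layer": layer,
                                "vessel_type": vt,
                                "vessel_id": f"{ri}{layer}{vt}{j}",
                                "window_index": 0,
                                "value": float(1000 * rng.lognormal(0, 0.05)),
                                "value_kind": "speed_um_s", "method": "invivo",
                            }
                        )
        fit = cf.fit_mixed(pd.DataFrame(rows))
        emm = cf.emmeans_layer(fit)
        a, b = emm.by_layer["emm_transformed"]
        assert a == pytest.approx(b, abs=0.05)
        assert emm.contrast["estimate_transformed"] == pytest.approx(0.0, abs=0.05)

    def test_one_tailed_p_not_larger_than_two_tailed(self):
        table, _ = cstats.simulate_speed_table(seed=7)
        emm = cf.emmeans_layer(cf.fit_mixed(table))
        assert emm.contrast["p_one_tailed"] <= emm.contrast["p_two_tailed"] + 1e-15

    def test_backtransform_inverts_transform(self):
        table, _ = cstats.simulate_speed_table(seed=8)
        fit = cf.fit_mixed(table)
        emm = cf.emmeans_layer(fit)
        for _, row in emm.by_layer.iterrows():
            assert math.log(row["emm"]) == pytest.approx(
                row["emm_transformed"], abs=1e-12
            )

    def test_se_positive(self):
        table, _ = cstats.simulate_speed_table(seed=9)
        emm = cf.emmeans_layer(cf.fit_mixed(table))
        assert (emm.by_layer["se_transformed"] > 0).all()


class TestRmcorr:
    def test_exact_common_slope_gives_r_one(self):
        x = np.tile(np.arange(6.0), 3)
        offsets = np.repeat([0.0, 10.0, -5.0], 6)
        y = x + offsets
        sub = np.repeat(["a", "b", "c"], 6)
        res = cf.rmcorr(x + np.repeat([0, 100, 200], 6), y, sub)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_subject_offset_invariance(self):
        rng = np.random.default_rng(2)
        sub = np.repeat(np.arange(5), 7)
        x = rng.normal(size=35)
        y = 0.8 * x + rng.normal(size=35)
        base = cf.rmcorr(x, y, sub)
        shifted = cf.rmcorr(x + sub * 13.0, y - sub * 7.0, sub)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)
        assert shifted.p == pytest.approx(base.p, abs=1e-12)

    def test_opposite_between_subject_trend(self):
        # between-subject means anti-correlated, within-subject slope +1
        x = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])
        y = np.array([20.0, 21.0, 22.0, 0.0, 1.0, 2.0])
        sub = np.array(["a", "a", "a", "b", "b", "b"])
        assert cf.rmcorr(x, y, sub).r > 0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        sub = np.repeat([f"s{i}" for i in range(6)], 9)
        x = rng.normal(size=54) + np.repeat(rng.normal(0, 2, 6), 9)
        y = 0.4 * x + rng.normal(size=54)
        mine = cf.rmcorr(x, y, sub)
        ref = pg.rm_corr(
            pd.DataFrame({"x": x, "y": y, "s": sub}), x="x", y="y", subject="s"
        )
        assert mine.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert mine.df == int(ref["dof"].iloc[0])
        assert mine.p == pytest.approx(float(ref["pval"].iloc[0]), abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cf.rmcorr([1, 2], [1, 2], ["a", "a"])
        with pytest.raises(ValueError):
            cf.rmcorr([1.0] * 6, [1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)


def test_model_selection_prefers_true_fixed_effects():
    table, _ = cstats.simulate_speed_table(seed=42, vessels_per_cell=6)
    chosen = cstats.compare_fixed_effects(
        table,
        [
            cstats.ModelSpec(fixed=("C(layer)", "C(vessel_type)")),
            cstats.ModelSpec(fixed=("C(layer)",)),
        ],
    )
    assert chosen.fixed == ("C(layer)", "C(vessel_type)")
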
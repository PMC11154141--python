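"""Path engine: standardization, fitting, decomposition, inference, interactions."""

import numpy as np
import pandas as pd
import pytest

import brainpath as bp
from brainpath import mediation as med


SPEC2 = med.PathModelSpec("lifestyle", "cognition", ("bag", "connectivity"), ("age", "sex"))


def make_fake_fit(a1, a2, d21, b1, b2, cdir, se=0.01):
    """Hand-built two-mediator system with chosen edge coefficients."""
    spec = med.PathModelSpec("x", "y", ("m1", "m2"))
    eqs = {}

    def eq(outcome, names, coefs):
        k = len(names)
        eqs[outcome] = med._Equation(outcome, names, np.asarray(coefs, dtype=float),
                                     np.eye(k) * se**2)

    eq("m1", ["intercept", "x"], [0, a1])
    eq("m2", ["intercept", "x", "m1"], [0, a2, d21])
    eq("y", ["intercept", "x", "m1", "m2"], [0, cdir, b1, b2])
    total = cdir + a1 * b1 + a2 * b2 + a1 * d21 * b2
    eq("__total__", ["intercept", "x"], [0, total])
    return med.PathSystemFit(spec=spec, exposure_terms=["x"], equations=eqs,
                             edges={}, n=1000)


class TestStandardize:
    def test_hand_zscores(self):
        t = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        out = med.standardize_variables(t, ["v"])
        assert list(out["v"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self, path_data):
        once = med.standardize_variables(path_data, ["bag"])
        twice = med.standardize_variables(once, ["bag"])
        assert np.allclose(once["bag"], twice["bag"], atol=1e-12)

    def test_constant_column_error(self):
        with pytest.raises(ValueError, match="constant"):
            med.standardize_variables(pd.DataFrame({"v": [2.0, 2.0]}), ["v"])


class TestPathSystem:
    def test_matches_statsmodels_oracle(self, path_data):
        import statsmodels.api as sm

        fit = med.fit_path_system(SPEC2, path_data)
        d = med.standardize_variables(path_data, ["bag", "connectivity", "cognition"])
        zl = (d["lifestyle"] - d["lifestyle"].mean()) / d["lifestyle"].std(ddof=1)
        X = sm.add_constant(
            pd.DataFrame({
                "lifestyle": zl,
                "bag": d["bag"],
                "connectivity": d["connectivity"],
                "age": d["age"],
                "sex": (d["sex"] == "male").astype(float),
            })
        )
        ref = sm.OLS(d["cognition"], X).fit()
        assert fit.edge("bag", "cognition").beta == pytest.approx(ref.params["bag"])
        assert fit.edge("bag", "cognition").se == pytest.approx(ref.bse["bag"], rel=1e-9)
        assert fit.edge("lifestyle", "cognition").beta == pytest.approx(ref.params["lifestyle"])

    def test_rank_deficiency_error_names_columns(self, path_data):
        t = path_data.assign(dup=path_data["lifestyle"])
        spec = med.PathModelSpec("lifestyle", "cognition", ("bag",), ("dup",))
        with pytest.raises(ValueError, match="collinear"):
            med.fit_path_system(spec, t)

    def test_complete_case_handling(self, path_data):
        t = path_data.copy()
        t.loc[t.index[:50], "bag"] = np.nan
        fit = med.fit_path_system(SPEC2, t)
        assert fit.n == len(t) - 50

    def test_tertile_exposure_dummies(self, path_data):
        t = path_data.assign(
            tert=bp.assign_tertiles(path_data["lifestyle"])
        )
        spec = med.PathModelSpec("tert", "cognition", ("bag",), ("age",), "tertile")
        fit = med.fit_path_system(spec, t)
        assert fit.exposure_terms == ["tert[T2]", "tert[T3]"]
        # monotone dose-response under the default positive risk gradient
        assert abs(fit.edge("tert[T3]", "bag").beta) > abs(fit.edge("tert[T2]", "bag").beta)


class TestDecomposition:
    def test_worked_product_examples(self):
        """Published two-mediator coefficients reproduce the printed indirect
        effects: 0.271 x (-0.126) = -0.034 and (-0.412) x 0.058 = -0.024."""
        fit = make_fake_fit(a1=0.271, a2=-0.108, d21=-0.412, b1=-0.126, b2=0.058, cdir=-0.151)
        dec = med.decompose_serial(fit)["x"]
        assert dec.indirect["via_m1"].estimate == pytest.approx(-0.034, abs=5e-4)
        serial_unit = -0.412 * 0.058  # mediator-1's effect on the outcome via mediator-2
        assert serial_unit == pytest.approx(-0.024, abs=5e-4)
        assert dec.indirect["via_m1_m2"].estimate == pytest.approx(0.271 * serial_unit, rel=1e-9)

    def test_additivity_identity_on_fitted_systems(self, path_data):
        for spec in (
            SPEC2,
            med.PathModelSpec("lifestyle", "cognition", ("bag",), ("age", "sex")),
        ):
            fit = med.fit_path_system(spec, path_data)
            for term, dec in med.decompose_serial(fit).items():
                total_reduced = fit.total_effect(term)
                parts = dec.direct.estimate + dec.total_indirect.estimate
                assert abs(total_reduced - parts) < 1e-10
                assert abs(dec.total.estimate - parts) < 1e-10

    def test_path_tracing_matches_brute_force_enumeration(self, rng):
        """Oracle: enumerate every directed exposure->outcome path and multiply
        edge coefficients; must equal the engine's decomposition."""
        for rep in range(5):
            n = 700
            x = rng.normal(size=n)
            m1 = 0.4 * x + rng.normal(size=n)
            m2 = -0.3 * x + 0.5 * m1 + rng.normal(size=n)
            y = 0.2 * x - 0.4 * m1 + 0.3 * m2 + rng.normal(size=n)
            t = pd.DataFrame({"x": x, "m1": m1, "m2": m2, "y": y})
            spec = med.PathModelSpec("x", "y", ("m1", "m2"))
            fit = med.fit_path_system(spec, t)
            e = fit.edge
            paths = {
                "direct": e("x", "y").beta,
                "via_m1": e("x", "m1").beta * e("m1", "y").beta,
                "via_m2": e("x", "m2").beta * e("m2", "y").beta,
                "via_m1_m2": e("x", "m1").beta * e("m1", "m2").beta * e("m2", "y").beta,
            }
            dec = med.decompose_serial(fit)["x"]
            assert dec.direct.estimate == pytest.approx(paths["direct"], rel=1e-9)
            for k in ("via_m1", "via_m2", "via_m1_m2"):
                assert dec.indirect[k].estimate == pytest.approx(paths[k], rel=1e-9)
            assert dec.total.estimate == pytest.approx(sum(paths.values()), rel=1e-9)

    def test_zero_mediator_paths_collapse_to_direct(self):
        fit = make_fake_fit(a1=0.0, a2=0.0, d21=0.5, b1=-0.4, b2=0.3, cdir=-0.2)
        dec = med.decompose_serial(fit)["x"]
        assert dec.total.estimate == pytest.approx(dec.direct.estimate)
        assert dec.total_indirect.estimate == pytest.approx(0.0)
        assert dec.proportion_mediated_overall == pytest.approx(0.0)

    def test_scale_invariance(self, path_data):
        base = med.decompose_serial(med.fit_path_system(SPEC2, path_data))["lifestyle"]
        scaled = path_data.assign(
            bag=3.0 * path_data["bag"] + 7.0,
            cognition=0.5 * path_data["cognition"] - 2.0,
        )
        alt = med.decompose_serial(med.fit_path_system(SPEC2, scaled))["lifestyle"]
        assert alt.total.estimate == pytest.approx(base.total.estimate, abs=1e-10)
        for k in base.indirect:
            assert alt.indirect[k].estimate == pytest.approx(base.indirect[k].estimate, abs=1e-10)

    def test_external_denominator_reproduces_quoted_ratios(self):
        fit = make_fake_fit(a1=0.27, a2=-0.1, d21=-0.4, b1=-0.126, b2=0.058, cdir=-0.12)
        dec = med.decompose_serial(fit, external_total=-0.198)["x"]
        expected = 100 * fit.equations["m1"].coef[1] * fit.equations["y"].coef[2] / -0.198
        assert dec.proportion_mediated["via_m1"] == pytest.approx(expected)


class TestProportionMediated:
    @pytest.mark.parametrize(
        ("indirect", "total", "expected"),
        [(-0.049, -0.198, 24.7), (-0.006, -0.157, 3.8), (0.3, 0.3, 100.0)],
    )
    def test_published_ratios(self, indirect, total, expected):
        assert med.proportion_mediated(indirect, total) == pytest.approx(expected, abs=0.05)

    def test_zero_total_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(med.proportion_mediated(0.1, 0.0))

    def test_inconsistent_mediation_warns_negative(self):
        with pytest.warns(UserWarning, match="opposite"):
            pm = med.proportion_mediated(0.05, -0.2)
        assert pm < 0

    def test_full_mediation_when_direct_zero(self):
        fit = make_fake_fit(a1=0.5, a2=0.0, d21=0.0, b1=0.4, b2=0.0, cdir=0.0)
        dec = med.decompose_serial(fit)["x"]
        assert dec.proportion_mediated_overall == pytest.approx(100.0)


class TestDeltaMethod:
    def test_single_product_sobel_closed_form(self):
        a, b, sa, sb = 0.4, -0.3, 0.05, 0.07
        fit = make_fake_fit(a1=a, a2=0, d21=0, b1=b, b2=0, cdir=0.1)
        fit.equations["m1"].cov = np.diag([0.0, sa**2])
        fit.equations["y"].cov = np.diag([0.0, 0.01**2, sb**2, 0.01**2])
        dec = med.decompose_serial(fit)["x"]
        assert dec.indirect["via_m1"].se == pytest.approx(
            np.sqrt(a**2 * sb**2 + b**2 * sa**2), rel=1e-9
        )

    def test_delta_close_to_bootstrap(self, path_data):
        dec = med.decompose_serial(med.fit_path_system(SPEC2, path_data))["lifestyle"]
        boot = med.bootstrap_inference(SPEC2, path_data, n_boot=2000, seed=0)
        draws_ci = boot["components"]["via_bag[lifestyle]"]
        boot_se = (draws_ci[2] - draws_ci[1]) / (2 * 1.96)
        assert dec.indirect["via_bag"].se == pytest.approx(boot_se, rel=0.15)

    def test_partial_null_type_one_error(self):
        """With the mediator->outcome path zero but the exposure->mediator path
        active, the delta z-test rejects at close to its nominal 5% rate."""
        co = {"lifestyle_to_substrate": 0.3, "substrate_to_cognition": 0.0,
              "lifestyle_to_cognition": 0.0, "substrate_to_connectivity": 0.0,
              "lifestyle_to_connectivity": 0.0, "connectivity_to_cognition": 0.0}
        rejections = 0
        reps = 200
        for r in range(reps):
            d = bp.generate_path_dataset(800, coefficients=co, seed=50_000 + r)
            dec = med.decompose_serial(med.fit_path_system(SPEC2, d))["lifestyle"]
            rejections += dec.indirect["via_bag"].p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_inference_table_shape(self, path_data):
        fit = med.fit_path_system(SPEC2, path_data)
        table = med.delta_method_inference(fit)
        rows = table["lifestyle"]
        assert set(rows) == {
            "total", "direct", "total_indirect", "via_bag",
            "via_connectivity", "via_bag_connectivity",
        }
        for est, se, z, p in rows.values():
            assert se > 0 and 0 <= p <= 1
            assert z == pytest.approx(est / se)


class TestBootstrap:
    def test_deterministic_given_seed(self, path_data):
        a = med.bootstrap_inference(SPEC2, path_data, n_boot=300, seed=9)
        b = med.bootstrap_inference(SPEC2, path_data, n_boot=300, seed=9)
        assert a == b

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (400, 1600):
            d = bp.generate_path_dataset(n, seed=13)
            ci = med.bootstrap_inference(SPEC2, d, n_boot=500, seed=1)
            lo, hi = ci["components"]["total[lifestyle]"][1:]
            widths[n] = hi - lo
        ratio = widths[400] / widths[1600]
        assert 1.5 < ratio < 2.7  # ~ sqrt(4) = 2

    def test_minimum_resamples_enforced(self, path_data):
        with pytest.raises(ValueError, match="n_boot"):
            med.bootstrap_inference(SPEC2, path_data, n_boot=50)

    def test_fast_refit_agrees_with_engine(self, path_data):
        slow = med._component_table(med.fit_path_system(SPEC2, path_data))
        fast = med._FastPathData(SPEC2, path_data).components()
        for k, v in slow.items():
            assert fast[k] == pytest.approx(v, abs=1e-12)


class TestAdjustedRegressions:
    def _table(self, coefficients, n=4000, seed=3):
        d = bp.generate_path_dataset(n, coefficients=coefficients, seed=seed)
        return d.rename(columns={"lifestyle": "libra_score"}).assign(
            education="medium", glucose_status="normal"
        )

    def test_isolated_bag_effect_recovered(self):
        co = {"lifestyle_to_substrate": 0.0, "substrate_to_cognition": -0.16,
              "lifestyle_to_cognition": 0.0, "substrate_to_connectivity": 0.0,
              "lifestyle_to_connectivity": 0.0, "connectivity_to_cognition": 0.0}
        regs = med.fit_adjusted_regressions(self._table(co))
        assert regs["bag_to_cognition"]["bag"].beta == pytest.approx(-0.16, abs=0.03)

    def test_lifestyle_to_bag_recovered(self):
        co = {"lifestyle_to_substrate": 0.13}
        betas = [
            med.fit_adjusted_regressions(self._table(co, seed=s))["lifestyle_to_bag"][
                "libra_score"
            ].beta
            for s in range(5)
        ]
        assert np.mean(betas) == pytest.approx(0.13, abs=0.03)

    def test_null_quadratic_rarely_significant(self):
        hits = 0
        reps = 100
        for r in range(reps):
            regs = med.fit_adjusted_regressions(self._table(None, n=500, seed=r))
            hits += regs["lifestyle_to_cognition"]["libra_score^2"].p < 0.05
        assert hits / reps <= 0.12


class TestGroupInteraction:
    def test_identical_groups_give_zero_statistic(self, path_data):
        doubled = pd.concat(
            [path_data.assign(g="A"), path_data.assign(g="B")], ignore_index=True
        )
        res = med.test_group_interaction(doubled, "bag", "lifestyle", "g", ("age",))
        assert res.chi2 == pytest.approx(0.0, abs=1e-16)
        assert res.p == pytest.approx(1.0)

    def test_df_equals_number_of_product_terms(self, path_data):
        t = path_data.assign(g3=np.tile(["a", "b", "c"], len(path_data) // 3 + 1)[: len(path_data)])
        res = med.test_group_interaction(t, "bag", "lifestyle", "g3")
        assert res.df == 2

    def test_constant_group_error(self, path_data):
        with pytest.raises(ValueError, match="constant"):
            med.test_group_interaction(path_data.assign(g="x"), "bag", "lifestyle", "g")

    def test_sex_specific_effect_detected_with_power(self):
        detected = 0
        reps = 40
        for r in range(reps):
            d = bp.generate_path_dataset(
                5000, seed=80_000 + r, sex_specific_lifestyle_substrate=(0.20, 0.05)
            )
            res = med.test_group_interaction(d, "bag", "lifestyle", "sex", ("age",))
            detected += res.p < 0.05
        assert detected / reps >= 0.90
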
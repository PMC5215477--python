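import numpy as np
import pytest
from scipy import optimize

import crvi_bmd as cb
from crvi_bmd.continuous import (
    MODELS,
    ContinuousFit,
    compute_bmd_rootfind,
    fit_continuous_model,
)

DOSES = np.repeat([0.0, 0.3, 4.0, 60.0, 170.0, 520.0], 3)


def _manual_fit(model, params, sigma, doses=DOSES, gof_p=1.0):
    """Build a results object directly (for closed-form BMD checks)."""
    f = ContinuousFit(model=model, params=params, sigma=sigma, loglik=0.0,
                      aic=0.0, gof_p=gof_p, converged=True, doses=doses,
                      responses=np.zeros_like(doses))
    return f


class TestFitting:
    def test_noise_free_linear_interpolation(self):
        y = 10.0 + 0.5 * DOSES
        fit = fit_continuous_model(DOSES, y, "linear")
        assert fit.params["beta0"] == pytest.approx(10.0, abs=1e-8)
        assert fit.params["beta1"] == pytest.approx(0.5, abs=1e-10)
        assert fit.sigma == pytest.approx(0.0, abs=1e-8)

    def test_flat_data_null_fits(self):
        rng = np.random.default_rng(0)
        y = 8.0 + rng.normal(0, 0.2, len(DOSES))
        lin = fit_continuous_model(DOSES, y, "linear")
        hill = fit_continuous_model(DOSES, y, "hill")
        assert abs(lin.params["beta1"]) < 0.01
        assert abs(hill.params["v"]) < 0.5

    def test_hill_parameter_recovery_within_3se(self):
        # intercept 8, v 2, k 10, n 1, sigma 0.1; 6 doses x 50 reps
        d = np.repeat([0.0, 0.3, 4.0, 60.0, 170.0, 520.0], 50)
        truth = {"intercept": 8.0, "v": 2.0, "k": 10.0, "n": 1.0}
        ests = {p: [] for p in truth}
        for seed in range(8):
            rng = np.random.default_rng(seed)
            y = 8.0 + 2.0 * d / (10.0 + d) + rng.normal(0, 0.1, len(d))
            fit = fit_continuous_model(d, y, "hill")
            for p in truth:
                ests[p].append(fit.params[p])
        for p, v in truth.items():
            arr = np.asarray(ests[p])
            se = arr.std(ddof=1) / np.sqrt(len(arr))
            assert abs(arr.mean() - v) < 3 * max(se, 1e-6), p

    def test_fewer_than_three_doses_rejected(self):
        with pytest.raises(ValueError, match="distinct doses"):
            fit_continuous_model([0, 0, 1, 1], [1, 2, 3, 4], "linear")

    def test_aic_counts_variance_parameter(self):
        rng = np.random.default_rng(3)
        y = 8 + 0.001 * DOSES + rng.normal(0, 0.2, len(DOSES))
        for model, k_mean in [("linear", 2), ("power", 3), ("poly2", 3),
                              ("hill", 4)]:
            fit = fit_continuous_model(DOSES, y, model)
            assert fit.aic == pytest.approx(2 * (k_mean + 1) - 2 * fit.loglik)

    def test_ml_matches_refined_grid_search_oracle(self):
        # coarse parameter grid refined twice must not beat the optimizer
        rng = np.random.default_rng(11)
        for trial in range(5):
            y = (8.0 + rng.uniform(-2, 2) * DOSES / (rng.uniform(5, 200) + DOSES)
                 + rng.normal(0, 0.15, len(DOSES)))
            fit = fit_continuous_model(DOSES, y, "hill")

            def sse_at(k, n):
                frac = np.where(DOSES > 0,
                                DOSES ** n / (k ** n + DOSES ** n), 0.0)
                X = np.column_stack([np.ones_like(DOSES), frac])
                coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                return ((y - X @ coef) ** 2).sum()

            ks = np.geomspace(0.01, 5200, 25)
            ns = np.linspace(0.1, 18, 25)
            for _ in range(3):
                sses = [[sse_at(k, n) for n in ns] for k in ks]
                i, j = np.unravel_index(np.argmin(sses), (25, 25))
                best_k, best_n = ks[i], ns[j]
                ks = np.geomspace(ks[max(i - 1, 0)], ks[min(i + 1, 24)], 25)
                ns = np.linspace(ns[max(j - 1, 0)], ns[min(j + 1, 24)], 25)
            oracle_sse = sse_at(best_k, best_n)
            fit_sse = len(DOSES) * fit.sigma ** 2
            assert fit_sse <= oracle_sse * (1 + 1e-6)


class TestBmd:
    def test_linear_closed_form(self):
        fit = _manual_fit("linear", {"beta0": 10.0, "beta1": 0.5}, sigma=1.0)
        assert fit.bmd(1.349) == pytest.approx(2.698, abs=1e-12)

    def test_hill_algebraic_inversion(self):
        # shift 0.2698; bmd = 10 * 0.2698 / (2 - 0.2698)
        fit = _manual_fit("hill", {"intercept": 8.0, "v": 2.0, "k": 10.0,
                                   "n": 1.0}, sigma=0.2)
        assert fit.bmd(1.349) == pytest.approx(10 * 0.2698 / (2 - 0.2698),
                                               rel=1e-10)
        assert fit.bmd(1.349) == pytest.approx(1.5595, abs=2e-4)

    def test_flat_fit_has_no_bmd(self):
        fit = _manual_fit("linear", {"beta0": 10.0, "beta1": 0.0}, sigma=1.0)
        assert np.isnan(fit.bmd())

    def test_hill_shift_beyond_asymptote_undefined(self):
        fit = _manual_fit("hill", {"intercept": 8.0, "v": 0.1, "k": 10.0,
                                   "n": 1.0}, sigma=0.2)
        assert np.isnan(fit.bmd(1.349))

    @pytest.mark.parametrize("model,params", [
        ("linear", {"beta0": 8.0, "beta1": 0.004}),
        ("poly2", {"beta0": 8.0, "beta1": 0.002, "beta2": 1e-6}),
        ("power", {"gamma": 8.0, "beta": 0.01, "delta": 0.9}),
        ("hill", {"intercept": 8.0, "v": 1.5, "k": 40.0, "n": 1.3}),
    ])
    def test_closed_form_matches_root_finder(self, model, params):
        fit = _manual_fit(model, params, sigma=0.25)
        a, b = fit.bmd(1.349), compute_bmd_rootfind(fit, 1.349)
        assert a == pytest.approx(b, rel=1e-8)

    def test_decreasing_curve_uses_absolute_shift(self):
        fit = _manual_fit("linear", {"beta0": 10.0, "beta1": -0.5}, sigma=1.0)
        assert fit.bmd(1.349) == pytest.approx(2.698, abs=1e-12)


class TestBmdl:
    def test_bmdl_below_bmd_across_random_probes(self):
        rng = np.random.default_rng(21)
        checked = 0
        for _ in range(15):
            y = 8 + rng.uniform(0.001, 0.01) * DOSES + rng.normal(
                0, 0.2, len(DOSES))
            fit = fit_continuous_model(DOSES, y, "linear")
            bmd, bmdl = fit.bmd(), fit.bmdl()
            if np.isfinite(bmd) and np.isfinite(bmdl):
                assert bmdl <= bmd
                checked += 1
        assert checked >= 10

    def test_bmdl_approaches_bmd_with_many_replicates(self):
        d = np.repeat([0.0, 0.3, 4.0, 60.0, 170.0, 520.0], 500)
        rng = np.random.default_rng(4)
        y = 8 + 0.003 * d + rng.normal(0, 0.1, len(d))
        fit = fit_continuous_model(d, y, "linear")
        bmd, bmdl = fit.bmd(), fit.bmdl()
        assert (bmd - bmdl) / bmd < 0.05

    def test_profile_coverage_near_95_percent(self):
        # true BMD from a known linear model covered by [bmdl, inf)
        beta1, sigma = 0.004, 0.2
        true_bmd = 1.349 * sigma / beta1
        cover = 0
        n_sim = 150
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            y = 8 + beta1 * DOSES + rng.normal(0, sigma, len(DOSES))
            fit = fit_continuous_model(DOSES, y, "linear")
            bmdl = fit.bmdl()
            cover += bool(np.isfinite(bmdl) and bmdl <= true_bmd)
        assert cover / n_sim >= 0.90


class TestSelection:
    def test_lrt_gate_prefers_linear_over_poly2(self):
        rng = np.random.default_rng(5)
        y = 8 + 0.003 * DOSES + rng.normal(0, 0.15, len(DOSES))
        lin = fit_continuous_model(DOSES, y, "linear")
        pol = fit_continuous_model(DOSES, y, "poly2")
        best = cb.select_best_model([lin, pol], lowest_dose=0.3)
        assert best.model == "linear"
        assert pol.aic is not None  # poly2 fitted but gated out by the LRT

    def test_hill_k_rule_excludes_small_k(self):
        hill = fit_continuous_model(DOSES, 8 + 2 * DOSES / (0.05 + DOSES),
                                    "hill")
        assert hill.params["k"] < 0.3 / 3
        lin = fit_continuous_model(DOSES, 8 + 2 * DOSES / (0.05 + DOSES),
                                   "linear")
        best = cb.select_best_model([hill, lin], lowest_dose=0.3)
        assert best.model != "hill"

    def test_single_converged_model_selected(self):
        fit = fit_continuous_model(DOSES, 8 + 0.01 * DOSES, "linear")
        assert cb.select_best_model([fit], 0.3) is fit

    def test_no_eligible_model_returns_none(self):
        hill = fit_continuous_model(DOSES, 8 + 2 * DOSES / (0.05 + DOSES),
                                    "hill")
        assert cb.select_best_model([hill], lowest_dose=0.3) is None


class TestRetention:
    def _fit(self, gof_p=1.0):
        return _manual_fit("linear", {"beta0": 8.0, "beta1": 0.01},
                           sigma=0.2, gof_p=gof_p)

    def test_ratio_rule(self):
        ok, reasons = cb.apply_retention_filters(self._fit(), 0.3, 520.0,
                                                 bmd=25.0, bmdl=1.0)
        assert not ok and "ratio" in reasons

    def test_bmd_below_one_third_lowest(self):
        ok, reasons = cb.apply_retention_filters(self._fit(), 0.3, 520.0,
                                                 bmd=0.05, bmdl=0.04)
        assert not ok and "bmd_below_range" in reasons

    def test_bmd_above_highest(self):
        ok, reasons = cb.apply_retention_filters(self._fit(), 0.3, 520.0,
                                                 bmd=600.0, bmdl=400.0)
        assert not ok and "bmd_above_range" in reasons

    def test_gof_rule(self):
        ok, reasons = cb.apply_retention_filters(self._fit(gof_p=0.05),
                                                 0.3, 520.0,
                                                 bmd=30.0, bmdl=20.0)
        assert not ok and reasons == ["gof"]

    def test_all_rules_evaluated_order_independent(self):
        ok, reasons = cb.apply_retention_filters(self._fit(gof_p=0.01),
                                                 0.3, 520.0,
                                                 bmd=600.0, bmdl=10.0)
        assert set(reasons) == {"ratio", "bmd_above_range", "gof"}

    def test_passing_fit_retained(self):
        ok, reasons = cb.apply_retention_filters(self._fit(), 0.3, 520.0,
                                                 bmd=30.0, bmdl=20.0)
        assert ok and reasons == []


class TestScreen:
    def test_empty_pdeg_list_is_empty_success(self, rat_design):
        m, _ = cb.simulate_expression(rat_design, n_probes=50, seed=0)
        out = cb.run_continuous_screen(m, rat_design, [])
        assert len(out) == 0

    def test_planted_hill_responders_recovered(self, rat_design):
        m, truth = cb.simulate_expression(
            rat_design, n_probes=40, frac_responsive=0.5, sigma=0.1,
            curve_family_weights={"hill": 1.0}, amplitude=(1.5, 2.0), seed=12)
        probes = truth.responsive_probes()
        out = cb.run_continuous_screen(m, rat_design, probes)
        retained = out[out["retained"]]
        # the LRT lack-of-fit gate at p > 0.1 is anti-conservative at n=3
        # per dose, so some true responders are always shed; most survive
        assert len(retained) / len(probes) >= 0.7
        tb = truth.planted.set_index("probe_id")["true_bmd"]
        rel = np.abs(retained["bmd"].to_numpy()
                     - tb.reindex(retained["probe_id"]).to_numpy()) \
            / tb.reindex(retained["probe_id"]).to_numpy()
        assert np.median(rel) <= 0.25
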
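"""Global fitting: goodness of fit, initial guesses, parameter recovery,
steady-state affinity, uncertainty calibration and expression ranking."""

import math

import numpy as np
import pytest

from blifit import (
    FitModel,
    FitOptions,
    KineticParameters,
    NoiseModel,
    PartialDissociationParameters,
    Sensorgram,
    choose_model,
    default_schedule,
    fit_single_cycle,
    fit_steady_state,
    goodness_of_fit,
    initial_guess,
    parameter_uncertainty,
    rank_expression,
    schedule_for_affinity,
    simulate_loading,
    simulate_sensorgram,
)
from blifit.errors import DataError, DofError, GuessError
from blifit.fitting import _residual_fn

NM = 1e-9


class TestGoodnessOfFit:
    def test_zero_residuals(self):
        assert goodness_of_fit(np.zeros(100), 3) == 0.0

    def test_worked_example(self):
        # sqrt(4 * 0.01 / (4 - 2)) = sqrt(0.02) = 0.14142...
        assert goodness_of_fit([0.1, -0.1, 0.1, -0.1], p=2) == pytest.approx(
            0.14142, abs=5e-6
        )

    def test_no_residual_dof_is_an_error(self):
        with pytest.raises(DofError):
            goodness_of_fit([0.1, -0.1], p=2)


class TestInitialGuess:
    def test_noiseless_guess_within_factor_ten(self, five_well_schedule,
                                               mid_nanomolar_params):
        sg = simulate_sensorgram(five_well_schedule, mid_nanomolar_params)
        guess = initial_guess(sg, five_well_schedule)
        assert mid_nanomolar_params.k_on / 10 < guess.k_on < mid_nanomolar_params.k_on * 10
        assert mid_nanomolar_params.k_off / 10 < guess.k_off < mid_nanomolar_params.k_off * 10

    def test_guess_respects_bounds(self, five_well_schedule, mid_nanomolar_params):
        sg = simulate_sensorgram(
            five_well_schedule, mid_nanomolar_params, NoiseModel(sigma=0.01, seed=3)
        )
        options = FitOptions()
        guess = initial_guess(sg, five_well_schedule, options)
        assert options.k_on_bounds[0] <= guess.k_on <= options.k_on_bounds[1]
        assert options.k_off_bounds[0] <= guess.k_off <= options.k_off_bounds[1]
        assert options.r_max_bounds[0] <= guess.r_max <= options.r_max_bounds[1]

    def test_flat_trace_is_a_guess_error(self, five_well_schedule):
        clean = simulate_sensorgram(
            five_well_schedule,
            KineticParameters(k_on=2e5, k_off=1e-2, r_max=0.1),
        )
        flat = Sensorgram(clean.times, np.zeros(len(clean)),
                          step_index=clean.step_index)
        with pytest.raises(GuessError, match="signal"):
            initial_guess(flat, five_well_schedule)


class TestSingleCycleFit:
    def test_noiseless_standard_recovery(self, five_well_schedule,
                                         mid_nanomolar_params):
        """On noiseless synthetic data the global fit must return the
        generating rate constants essentially exactly."""
        sg = simulate_sensorgram(five_well_schedule, mid_nanomolar_params)
        fit = fit_single_cycle(sg, five_well_schedule)
        assert fit.converged
        assert abs(fit.base.k_on / mid_nanomolar_params.k_on - 1) < 1e-4
        assert abs(fit.base.k_off / mid_nanomolar_params.k_off - 1) < 1e-4
        assert fit.rmse <= 1e-9
        assert fit.n > fit.p == 3

    def test_noiseless_partial_global_recovery(self, five_well_schedule,
                                               mid_nanomolar_params):
        truth = PartialDissociationParameters(base=mid_nanomolar_params, phi=0.30)
        sg = simulate_sensorgram(five_well_schedule, truth)
        fit = fit_single_cycle(sg, five_well_schedule, FitModel.PARTIAL_GLOBAL)
        assert abs(fit.params.phi - 0.30) < 0.01
        assert abs(fit.base.k_on / mid_nanomolar_params.k_on - 1) < 1e-4

    def test_phi_zero_data_consistent_across_models(self, five_well_schedule,
                                                    mid_nanomolar_params):
        sg = simulate_sensorgram(five_well_schedule, mid_nanomolar_params)
        std = fit_single_cycle(sg, five_well_schedule, FitModel.STANDARD_1_1)
        par = fit_single_cycle(sg, five_well_schedule, FitModel.PARTIAL_GLOBAL)
        assert abs(std.base.k_on / par.base.k_on - 1) < 1e-3
        assert abs(std.base.k_off / par.base.k_off - 1) < 1e-3
        assert par.params.phi <= 0.01

    def test_rmse_matches_goodness_of_fit_exactly(self, five_well_schedule,
                                                  mid_nanomolar_params):
        sg = simulate_sensorgram(
            five_well_schedule, mid_nanomolar_params, NoiseModel(sigma=0.005, seed=1)
        )
        fit = fit_single_cycle(sg, five_well_schedule)
        assert fit.rmse == goodness_of_fit(fit.residuals, fit.p)
        assert fit.rmse_fraction_of_window > 0

    def test_bounds_respected_under_noise(self, five_well_schedule,
                                          mid_nanomolar_params):
        truth = PartialDissociationParameters(base=mid_nanomolar_params, phi=0.3)
        for seed in range(3):
            sg = simulate_sensorgram(
                five_well_schedule, truth, NoiseModel(sigma=0.01, seed=seed)
            )
            fit = fit_single_cycle(sg, five_well_schedule, FitModel.PARTIAL_GLOBAL,
                                   FitOptions(seed=seed))
            assert 0.0 <= fit.params.phi <= 0.95
            assert fit.base.k_on > 0 and fit.base.k_off > 0

    def test_dof_error_when_underdetermined(self, five_well_schedule,
                                            mid_nanomolar_params):
        clean = simulate_sensorgram(five_well_schedule, mid_nanomolar_params,
                                    grid=0.5)
        tiny = Sensorgram(clean.times[:3], clean.responses[:3],
                          step_index=clean.step_index[:3])
        with pytest.raises((DofError, GuessError)):
            fit_single_cycle(tiny, five_well_schedule)

    def test_objective_is_permutation_invariant(self, five_well_schedule,
                                                mid_nanomolar_params):
        """Shuffling sample order (times kept with samples) permutes the
        residual vector, so the sum of squares — and hence the optimum —
        is unchanged."""
        sg = simulate_sensorgram(
            five_well_schedule, mid_nanomolar_params, NoiseModel(sigma=0.005, seed=2)
        )
        mask = sg.kinetic_mask(five_well_schedule)
        times, obs = sg.times[mask], sg.responses[mask]
        perm = np.random.default_rng(0).permutation(times.size)
        fn = _residual_fn(times, obs, five_well_schedule, FitModel.STANDARD_1_1)
        fn_perm = _residual_fn(times[perm], obs[perm], five_well_schedule,
                               FitModel.STANDARD_1_1)
        theta = np.array([math.log10(2.3e5), math.log10(1.12e-2), math.log10(0.14)])
        np.testing.assert_allclose(fn(theta)[perm], fn_perm(theta), rtol=0, atol=0)

    def test_noiseless_recovery_across_affinity_span(self):
        """Designed-schedule fits recover randomly drawn rate constants to
        0.01% across K_D from picomolar to high-nanomolar."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            k_d = 10 ** rng.uniform(-12, -6)
            lo = max(1e-6, k_d * 1e4)
            hi = min(1.0, k_d * 1e7)
            k_off = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
            k_on = k_off / k_d
            truth = KineticParameters(k_on, k_off, 10 ** rng.uniform(-1.3, 0))
            sched = schedule_for_affinity(k_on, k_off)
            sg = simulate_sensorgram(sched, truth, grid=1.0)
            fit = fit_single_cycle(sg, sched, options=FitOptions(n_starts=1))
            assert abs(fit.base.k_on / truth.k_on - 1) < 1e-4, (k_on, k_off)
            assert abs(fit.base.k_off / truth.k_off - 1) < 1e-4, (k_on, k_off)


class TestLmfitCrossCheck:
    def test_independent_optimizer_agrees(self, five_well_schedule,
                                          mid_nanomolar_params):
        """An independently parametrised lmfit minimisation of the same
        piecewise model lands on the same optimum."""
        import lmfit

        from blifit.models import evaluate_trace

        sg = simulate_sensorgram(
            five_well_schedule, mid_nanomolar_params, NoiseModel(sigma=0.003, seed=5)
        )
        mask = sg.kinetic_mask(five_well_schedule)
        times, obs = sg.times[mask], sg.responses[mask]

        def resid(p):
            params = KineticParameters(p["k_on"].value, p["k_off"].value,
                                       p["r_max"].value)
            return evaluate_trace(times, five_well_schedule, params) - obs

        pars = lmfit.Parameters()
        pars.add("k_on", value=1e5, min=1e2, max=1e8)
        pars.add("k_off", value=1e-3, min=1e-7, max=1.0)
        pars.add("r_max", value=0.3, min=1e-6, max=10.0)
        out = lmfit.minimize(resid, pars, method="least_squares")

        fit = fit_single_cycle(sg, five_well_schedule)
        assert out.params["k_on"].value == pytest.approx(fit.base.k_on, rel=1e-3)
        assert out.params["k_off"].value == pytest.approx(fit.base.k_off, rel=1e-3)


class TestSteadyState:
    def make_points(self, r_max=0.2, k_d=100 * NM):
        c = np.array([25, 50, 100, 200, 400, 800, 1600]) * NM
        return c, r_max * c / (c + k_d)

    def test_exact_recovery(self):
        c, r = self.make_points()
        k_d, r_max = fit_steady_state(c, r)
        assert k_d == pytest.approx(100 * NM, rel=1e-4)
        assert r_max == pytest.approx(0.2, rel=1e-4)

    def test_scale_equivariance(self):
        c, r = self.make_points()
        k_d1, r_max1 = fit_steady_state(c, r)
        k_d2, r_max2 = fit_steady_state(c, 3.0 * r)
        assert k_d2 == pytest.approx(k_d1, rel=1e-6)
        assert r_max2 == pytest.approx(3.0 * r_max1, rel=1e-6)

    def test_two_points_is_a_data_error(self):
        with pytest.raises(DataError):
            fit_steady_state([100 * NM, 200 * NM], [0.1, 0.15])

    def test_proportional_points_unidentifiable(self):
        c = np.array([10, 20, 40, 80]) * NM
        with pytest.warns(UserWarning, match="unidentifiable"):
            with pytest.raises(DataError):
                fit_steady_state(c, 1e6 * c)  # pure Henry regime, no curvature


class TestParameterUncertainty:
    def test_noiseless_fit_has_negligible_errors(self, five_well_schedule,
                                                 mid_nanomolar_params):
        sg = simulate_sensorgram(five_well_schedule, mid_nanomolar_params)
        fit = fit_single_cycle(sg, five_well_schedule)
        se = parameter_uncertainty(fit, sg, five_well_schedule)
        assert se["k_on"] <= 1e-6 * fit.base.k_on
        assert se["k_off"] <= 1e-6 * fit.base.k_off
        assert se["r_max"] <= 1e-6 * fit.base.r_max

    def test_reported_se_calibrated_against_replicates(self):
        """Empirical spread of estimates across noisy replicates should sit
        within a factor of two of the mean reported asymptotic SE."""
        sched = default_schedule([50 * NM, 100 * NM, 200 * NM])
        truth = KineticParameters(k_on=2.3e5, k_off=1.12e-2, r_max=0.14)
        estimates, reported = [], []
        for seed in range(50):
            sg = simulate_sensorgram(sched, truth, NoiseModel(sigma=0.005, seed=seed),
                                     grid=1.0)
            fit = fit_single_cycle(sg, sched, options=FitOptions(n_starts=1, seed=seed))
            estimates.append([fit.base.k_on, fit.base.k_off])
            se = fit.standard_errors
            reported.append([se["k_on"], se["k_off"]])
        emp = np.std(np.array(estimates), axis=0, ddof=1)
        mean_se = np.mean(np.array(reported), axis=0)
        ratio = emp / mean_se
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0), ratio


class TestRankExpression:
    def make_loadings(self, concs, seed0=0, sigma=0.003):
        return [
            simulate_loading(c, 1e5, 0.15, 900.0,
                             NoiseModel(sigma=sigma, seed=seed0 + i),
                             label=f"binder_{i}")
            for i, c in enumerate(concs)
        ]

    def test_rank_matches_generating_concentration_ratio(self):
        traces = self.make_loadings([100 * NM, 50 * NM, 10 * NM])
        ranked = rank_expression(traces)
        assert [e.label for e in ranked] == ["binder_0", "binder_1", "binder_2"]
        assert ranked[0].k_obs == pytest.approx(1e5 * 100 * NM, rel=0.05)
        assert ranked[0].rank_score == ranked[0].k_obs

    def test_identical_traces_tie(self):
        sg = simulate_loading(50 * NM, 1e5, 0.15, 900.0, NoiseModel(), label="a")
        ranked = rank_expression([sg, sg])
        assert abs(ranked[0].rank_score - ranked[1].rank_score) <= 1e-9

    def test_saturation_flag(self):
        fast = simulate_loading(500 * NM, 1e5, 0.15, 900.0, label="fast")
        slow = simulate_loading(2 * NM, 1e5, 0.15, 900.0, label="slow")
        ranked = {e.label: e for e in rank_expression([fast, slow])}
        assert ranked["fast"].saturated
        assert not ranked["slow"].saturated

    def test_flat_trace_warns_and_reports_failure(self):
        t = np.arange(0, 600.0)
        flat = Sensorgram(t, np.zeros(t.size), label="dud")
        with pytest.warns(UserWarning, match="flat"):
            ranked = rank_expression([flat])
        assert not ranked[0].ok
        assert ranked[0].error is not None


class TestChooseModel:
    def test_prefers_parsimony_unless_partial_earns_it(self, five_well_schedule,
                                                       mid_nanomolar_params):
        truth = PartialDissociationParameters(base=mid_nanomolar_params, phi=0.3)
        noisy = NoiseModel(sigma=0.003, seed=9)
        sg_partial = simulate_sensorgram(five_well_schedule, truth, noisy)
        sg_std = simulate_sensorgram(five_well_schedule, mid_nanomolar_params, noisy)

        for sg, expect_partial in ((sg_partial, True), (sg_std, False)):
            std = fit_single_cycle(sg, five_well_schedule, FitModel.STANDARD_1_1)
            par = fit_single_cycle(sg, five_well_schedule, FitModel.PARTIAL_GLOBAL)
            chosen = choose_model(std, par)
            assert (chosen.model is FitModel.PARTIAL_GLOBAL) is expect_partial
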
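"""Gamma kernel, design construction, PRF/beta fitting, trace summaries."""

import numpy as np
import pytest

from pupilnum.prf_glm import (
    EpochAverage,
    PRFParams,
    average_epochs,
    build_design,
    difference_trace,
    fit_condition_betas,
    fit_prf,
    gamma_prf,
    window_mean,
)

FINE_T = np.arange(0.0, 30.0, 0.0005)

PARAM_BOX = [
    PRFParams(1, 10, 0), PRFParams(1, 800, 200), PRFParams(4, 250, 100),
    PRFParams(8, 100, 50), PRFParams(2, 400, 0), PRFParams(6, 60, 200),
]


class TestGammaKernel:
    @pytest.mark.parametrize("params", PARAM_BOX, ids=str)
    def test_unit_mass(self, params):
        h = gamma_prf(FINE_T, params)
        assert np.trapezoid(h, FINE_T) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("params", PARAM_BOX, ids=str)
    def test_mode_location(self, params):
        """Peak at delta + (n-1)*tau (mode of the shifted Gamma density)."""
        h = gamma_prf(FINE_T, params)
        assert FINE_T[np.argmax(h)] == pytest.approx(params.mode_s, abs=0.001)

    def test_causality_and_nonnegativity(self):
        p = PRFParams(4, 250, 100)
        h = gamma_prf(FINE_T, p)
        assert np.all(h[FINE_T < 0.1] == 0.0)
        assert np.all(h >= 0)

    @pytest.mark.parametrize("bad", [(0, 250, 100), (9, 250, 100), (4, 5, 100),
                                     (4, 900, 100), (4, 250, -1), (4, 250, 300)])
    def test_out_of_bounds_rejected(self, bad):
        with pytest.raises(ValueError):
            PRFParams(*bad)


class TestBuildDesign:
    def test_near_delta_kernel_sustained_is_boxcar(self):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(1, 10, 0))
        box = ((grid >= 0) & (grid < 6)).astype(float) / 6.0
        inside = (grid > 0.3) & (grid < 5.7)
        assert np.allclose(X[inside, 2], box[inside], atol=0.01)

    def test_onset_offset_are_time_translates(self):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(4, 250, 100))
        shift = int(round(6.0 / 0.05))
        assert np.allclose(X[shift:, 1], X[:-shift, 0], atol=1e-12)

    def test_causal_before_onset_plus_delay(self):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(4, 250, 100))
        assert np.all(X[grid < 0.1, :] == 0.0)

    def test_predictors_unit_integral_preconvolution(self):
        # beta of 1 on the sustained regressor integrates to ~kernel mass
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(1, 10, 0), t_end=20.0)
        assert np.trapezoid(X[:, 0], grid) == pytest.approx(1.0, abs=0.02)


class TestConditionBetas:
    def test_pure_sustained_trace(self):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(4, 250, 100))
        avg = EpochAverage(grid, 2.0 * X[:, 2], np.ones(len(grid), bool))
        fit = fit_condition_betas(avg, X)
        assert fit.betas == pytest.approx([0.0, 0.0, 2.0], abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_normal_equations_oracle(self, rng):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(3, 300, 50))
        y = X @ np.array([0.3, -0.2, 1.1]) + rng.normal(0, 0.05, len(grid))
        valid = rng.random(len(grid)) > 0.1
        fit = fit_condition_betas(EpochAverage(grid, y, valid), X)
        # independent route: solve the normal equations directly
        Xv, yv = X[valid], y[valid]
        oracle = np.linalg.solve(Xv.T @ Xv, Xv.T @ yv)
        assert fit.betas == pytest.approx(oracle, abs=1e-10)

    def test_pure_noise_low_r_squared(self, rng):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(4, 250, 100))
        r2 = [
            fit_condition_betas(
                EpochAverage(grid, rng.normal(0, 1, len(grid)), np.ones(len(grid), bool)), X
            ).r_squared
            for _ in range(20)
        ]
        assert np.mean(r2) < 0.1

    def test_grid_mismatch_rejected(self):
        grid, X = build_design((0.0, 6.0), 0.05, PRFParams(4, 250, 100))
        avg = EpochAverage(grid[:-1], np.zeros(len(grid) - 1), np.ones(len(grid) - 1, bool))
        with pytest.raises(ValueError, match="grid"):
            fit_condition_betas(avg, X)


class TestFitPRF:
    def test_exact_recovery_on_analysis_grid(self):
        true = PRFParams(4, 250, 100)
        grid, X = build_design((0.0, 6.0), 0.05, true)
        y = X @ np.array([-0.1, -0.05, -1.17])
        prf, fit = fit_prf(EpochAverage(grid, y, np.ones(len(grid), bool)), seed=0)
        assert prf.n == true.n
        assert prf.tau_ms == pytest.approx(true.tau_ms, rel=0.05)
        assert prf.delta_ms == pytest.approx(true.delta_ms, abs=10.0)
        assert fit.r_squared > 0.999

    @pytest.mark.parametrize("true", [PRFParams(2, 150, 30), PRFParams(5, 320, 160)], ids=str)
    def test_recovery_across_parameter_box(self, true):
        grid, X = build_design((0.0, 6.0), 0.05, true)
        y = X @ np.array([-0.08, -0.04, -0.9])
        prf, _ = fit_prf(EpochAverage(grid, y, np.ones(len(grid), bool)), seed=1)
        assert prf.n == true.n
        assert prf.tau_ms == pytest.approx(true.tau_ms, rel=0.05)
        assert prf.delta_ms == pytest.approx(true.delta_ms, abs=10.0)

    def test_beta_recovery_with_prf_fixed(self, rng):
        """50 noiseless simulations across the parameter box: betas match
        the generating weights to 1e-6 when the true kernel is supplied."""
        worst = 0.0
        for _ in range(50):
            true = PRFParams(
                int(rng.integers(1, 9)),
                float(rng.uniform(10, 800)),
                float(rng.uniform(0, 200)),
            )
            beta = rng.uniform(-1.5, 1.5, 3)
            grid, X = build_design((0.0, 6.0), 0.05, true)
            avg = EpochAverage(grid, X @ beta, np.ones(len(grid), bool))
            fit = fit_condition_betas(avg, X)
            worst = max(worst, np.abs(fit.betas - beta).max())
        assert worst < 1e-6

    def test_zero_trace_degenerate(self):
        grid = np.arange(-1, 7.025, 0.05)
        prf, fit = fit_prf(EpochAverage(grid, np.zeros(len(grid)), np.ones(len(grid), bool)))
        assert fit.degenerate and fit.betas == pytest.approx([0, 0, 0])

    def test_all_invalid_trace_rejected(self):
        grid = np.arange(-1, 7.025, 0.05)
        with pytest.raises(ValueError, match="invalid"):
            fit_prf(EpochAverage(grid, np.zeros(len(grid)), np.zeros(len(grid), bool)))

    def test_noisy_average_variance_explained(self):
        """60 trials of AR(1) noise at 0.05 mm, averaged: fit explains > 80%."""
        from pupilnum.preprocess import preprocess_session
        from pupilnum.synth import SimConfig, make_session_design, simulate_session

        cfg = SimConfig()  # noise_sd 0.05 default
        design = make_session_design(n_trials=60, numerosity=24, polarity="white",
                                     connectedness_seq=["isolated"] * 60, rng=7)
        trace, events = simulate_session(design, cfg, rng=7)
        avg = average_epochs(preprocess_session(trace, events))
        _, fit = fit_prf(avg, seed=7)
        assert fit.r_squared > 0.80


class TestTraceSummaries:
    def grid_avg(self, values, valid=None):
        grid = np.arange(-1, 7.025, 0.05)
        v = np.ones(len(grid), bool) if valid is None else valid
        return EpochAverage(grid, np.asarray(values, float), v)

    def test_difference_identity_and_antisymmetry(self):
        grid = np.arange(-1, 7.025, 0.05)
        d = np.sin(grid)
        a = self.grid_avg(d)
        assert np.allclose(difference_trace(a, self.grid_avg(d)).pupil, 0.0)
        out = difference_trace(self.grid_avg(d), self.grid_avg(-d))
        assert np.allclose(out.pupil, 2 * d)

    def test_difference_grid_mismatch(self):
        a = self.grid_avg(np.zeros(161))
        b = EpochAverage(np.arange(0, 8.05, 0.05), np.zeros(161), np.ones(161, bool))
        with pytest.raises(ValueError, match="grid"):
            difference_trace(a, b)

    def test_difference_orders_with_generating_gains(self):
        """Dark-minus-light window means follow the sustained gain ordering."""
        from pupilnum.preprocess import preprocess_session
        from pupilnum.synth import SimConfig, make_session_design, simulate_session

        cfg = SimConfig(noise_sd=0.0, blink_rate=0.0)
        means = {}
        for n, conn in cfg.sustained_gains:
            avgs = {}
            for pol in ("white", "black"):
                design = make_session_design(n_trials=2, numerosity=n, polarity=pol,
                                             connectedness_seq=[conn] * 2, rng=0)
                tr, ev = simulate_session(design, cfg, 0)
                avgs[pol] = average_epochs(preprocess_session(tr, ev))
            means[(n, conn)] = window_mean(difference_trace(avgs["black"], avgs["white"]))
        gains = cfg.sustained_gains
        order_by_gain = sorted(gains, key=gains.get)
        order_by_mean = sorted(means, key=means.get)
        assert order_by_gain == order_by_mean

    def test_window_mean_constant(self):
        assert window_mean(self.grid_avg(np.full(161, -0.3))) == pytest.approx(-0.3)

    def test_window_mean_ramp_analytic(self):
        grid = np.arange(-1, 7.025, 0.05)
        ramp = np.clip(grid, 0, 6) / 6.0  # 0 -> 1 over the 6 s stimulus
        avg = EpochAverage(grid, ramp, np.ones(len(grid), bool))
        # mean of t/6 over [1, 6): analytic 7/12
        assert window_mean(avg, 1.0, 6.0) == pytest.approx(7 / 12, abs=0.005)

    def test_window_mean_empty_window(self):
        with pytest.raises(ValueError, match="window"):
            window_mean(self.grid_avg(np.zeros(161)), 2.0, 2.0)

    def test_average_epochs_validity_weighting(self):
        from pupilnum.preprocess import Epoch

        grid = np.arange(-1, 7.025, 0.05)
        n = len(grid)
        e1 = Epoch(0, grid, np.full(n, 1.0), np.ones(n, bool))
        p2 = np.full(n, 3.0)
        v2 = np.ones(n, bool)
        v2[:10] = False
        e2 = Epoch(1, grid, p2, v2)
        avg = average_epochs([e1, e2])
        assert avg.pupil[0] == pytest.approx(1.0)  # only e1 valid there
        assert avg.pupil[-1] == pytest.approx(2.0)


def test_continuous_gamma_matches_factorial_form_at_integer_n():
    from pupilnum.prf_glm import gamma_prf_continuous

    t = np.arange(0, 5, 0.01)
    p = PRFParams(4, 250, 100)
    assert np.allclose(gamma_prf_continuous(t, 4.0, 250, 100), gamma_prf(t, p))
    # non-integer n interpolates smoothly between the integer kernels
    mid = gamma_prf_continuous(t, 4.5, 250, 100)
    assert np.trapezoid(mid, t) == pytest.approx(1.0, abs=1e-2)
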
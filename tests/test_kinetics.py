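"""Cascade populations, IRF convolution, global fitting and summaries."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import cumulative_trapezoid, quad, solve_ivp

from phycoflux.kinetics import (
    CompartmentModel,
    FitFailure,
    SpectralAmplitudes,
    TimeWavelengthSurface,
    band_decay_time,
    convolve_irf,
    convolved_populations,
    fit_global,
    population_terms,
    predict_surface,
    solve_populations,
    transfer_efficiency,
)
from phycoflux.synthetic_data import GroundTruth, simulate_surface

SIGMA_15 = 15.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def ode_populations(model: CompartmentModel, t: np.ndarray) -> np.ndarray:
    """Independent oracle: numerically integrate the cascade ODEs."""
    ka, kb, kc = model.rates

    def rhs(_, y):
        return [-ka * y[0], y[0] / model.tau_ab - kb * y[1], y[1] / model.tau_bc - kc * y[2]]

    sol = solve_ivp(rhs, (t[0], t[-1]), [1.0, 0.0, 0.0], t_eval=t, rtol=1e-11, atol=1e-13)
    return sol.y


class TestPopulations:
    def test_initial_condition(self):
        na, nb, nc = solve_populations(CompartmentModel(), np.array([0.0, 1.0]))
        assert (na[0], nb[0], nc[0]) == (1.0, 0.0, 0.0)

    def test_transfer_off_decouples_cascade(self):
        m = CompartmentModel(tau_ab=1e12, tau_da=1000.0)
        t = np.linspace(0.0, 500.0, 101)
        na, nb, nc = solve_populations(m, t)
        np.testing.assert_allclose(na, np.exp(-t / 1000.0), rtol=1e-6)
        assert np.max(nb) < 1e-9 and np.max(nc) < 1e-9

    @pytest.mark.parametrize(
        "model",
        [
            CompartmentModel(),  # default: k_A == k_B exactly (degenerate pair)
            CompartmentModel(tau_ab=30.0, tau_bc=80.0, tau_c=220.0),
            CompartmentModel(tau_ab=50.0, tau_bc=200.0, tau_c=1.0 / (1.0 / 200.0 + 1.0 / 1000.0)),
            CompartmentModel(tau_ab=47.0, tau_bc=47.0, tau_c=1.0 / (1.0 / 47.0 + 1.0 / 1000.0)),
        ],
        ids=["degenerate-AB", "distinct", "near-degenerate-BC", "triple-degenerate"],
    )
    def test_matches_ode_oracle(self, model):
        t = np.linspace(0.0, 500.0, 501)
        analytic = np.vstack(solve_populations(model, t))
        numeric = ode_populations(model, t)
        assert np.max(np.abs(analytic - numeric)) < 1e-8

    def test_nonnegative_and_zero_before_excitation(self):
        t = np.linspace(-50.0, 500.0, 400)
        for n in solve_populations(CompartmentModel(), t):
            assert np.all(n >= 0.0)
            assert np.all(n[t < 0] == 0.0)

    def test_conservation_with_loss_accounting(self):
        m = CompartmentModel(tau_ab=40.0, tau_bc=70.0)
        t = np.linspace(0.0, 500.0, 4001)
        na, nb, nc = solve_populations(m, t)
        loss_rate = na / m.tau_da + nb / m.tau_db + nc / m.tau_c
        lost = cumulative_trapezoid(loss_rate, t, initial=0.0)
        total = na + nb + nc + lost
        assert np.max(np.abs(total - 1.0)) < 1e-6

    def test_nonpositive_time_constant_rejected(self):
        with pytest.raises(ValueError):
            CompartmentModel(tau_ab=-5.0)
        with pytest.raises(ValueError):
            CompartmentModel(tau_c=0.0)


class TestIRFConvolution:
    def test_zero_width_is_identity(self):
        t = np.linspace(0.0, 300.0, 301)
        out = convolve_irf([(0, 0.01, 2.0)], t, 0.0, 0.0)
        np.testing.assert_array_equal(out, 2.0 * np.exp(-0.01 * t))

    def test_area_preserved(self):
        t = np.arange(-200.0, 3001.0, 0.5)
        terms = [(0, 1.0 / 80.0, 1.0), (1, 1.0 / 50.0, 0.02)]
        convolved = convolve_irf(terms, t, 15.0, 0.0)
        # analytic area of sum_p c t^p exp(-kt): sum_p c p! / k^(p+1)
        analytic = 1.0 * 80.0 + 0.02 * 50.0**2
        assert abs(np.trapezoid(convolved, t) - analytic) / analytic < 1e-6

    @pytest.mark.parametrize("power", [0, 1, 2])
    def test_matches_quadrature_oracle(self, power):
        k = 1.0 / 47.6
        t_check = np.array([-20.0, -5.0, 0.0, 5.0, 20.0, 100.0, 300.0, 500.0])
        closed = convolve_irf([(power, k, 1.0)], t_check, 15.0, 0.0)

        def direct(tt):
            def integrand(s):
                gauss = math.exp(-((tt - s) ** 2) / (2 * SIGMA_15**2))
                return s**power * math.exp(-k * s) * gauss / (SIGMA_15 * math.sqrt(2 * math.pi))

            mid = max(tt + 10 * SIGMA_15, 1.0)
            lo = max(0.0, tt - 10 * SIGMA_15)
            return quad(integrand, lo, mid, limit=400)[0] + quad(integrand, mid, np.inf)[0]

        oracle = np.array([direct(tt) for tt in t_check])
        assert np.max(np.abs(closed - oracle)) < 1e-6

    def test_t0_shifts_signal(self):
        t = np.linspace(-50.0, 500.0, 551)
        shifted = convolve_irf([(0, 0.02, 1.0)], t, 15.0, 30.0)
        base = convolve_irf([(0, 0.02, 1.0)], t - 30.0, 15.0, 0.0)
        np.testing.assert_allclose(shifted, base, atol=1e-12)


class TestPredictSurface:
    def test_zero_amplitudes_zero_surface(self, grids):
        t, w = grids
        amps = SpectralAmplitudes(w, np.zeros_like(w), np.zeros_like(w), np.zeros_like(w))
        surf = predict_surface(CompartmentModel(), amps, t, w)
        assert np.all(surf.intensity == 0.0)

    def test_single_compartment_is_rank_one(self, grids):
        t, w = grids
        amps = SpectralAmplitudes(w, np.linspace(1.0, 2.0, w.size), np.zeros_like(w), np.zeros_like(w))
        surf = predict_surface(CompartmentModel(), amps, t, w)
        assert np.linalg.matrix_rank(surf.intensity, tol=1e-10) == 1

    def test_grid_mismatch_rejected(self, grids):
        t, w = grids
        amps = SpectralAmplitudes(w[:-1], np.ones(w.size - 1), np.ones(w.size - 1), np.ones(w.size - 1))
        with pytest.raises(ValueError):
            predict_surface(CompartmentModel(), amps, t, w)


class TestGlobalFit:
    def test_noiseless_inverse_crime(self, truth, grids):
        t, w = grids
        _, clean = simulate_surface(replace(truth, noise_scale=0.0), t, w)
        start = CompartmentModel(tau_ab=50 * 1.3, tau_bc=50 * 0.7, tau_c=220 * 1.3)
        fit = fit_global(clean, start, n_starts=1)
        assert fit.converged
        for name, expected in [("tau_ab", 50.0), ("tau_bc", 50.0), ("tau_c", 220.0)]:
            assert abs(getattr(fit.model, name) - expected) / expected < 1e-3

    def test_variable_projection_matches_joint_fit(self, truth, coarse_grids):
        from scipy.optimize import least_squares

        t, w = coarse_grids
        noisy, _ = simulate_surface(replace(truth, noise_scale=0.05), t, w)
        vp = fit_global(noisy, n_starts=1)

        nw = w.size

        def joint_residual(x):
            model = replace(CompartmentModel(), tau_ab=np.exp(x[0]), tau_bc=np.exp(x[1]), tau_c=np.exp(x[2]))
            s = x[3:].reshape(3, nw)
            return (noisy.intensity - convolved_populations(model, t) @ s).ravel()

        x0 = np.concatenate(
            [np.log([60.0, 60.0, 250.0]), truth.amplitudes(w).as_matrix().ravel()]
        )
        sol = least_squares(joint_residual, x0, ftol=1e-12, xtol=1e-12, gtol=1e-12)
        ssr_joint = float(np.sum(sol.fun**2))
        assert abs(vp.ssr - ssr_joint) / ssr_joint < 1e-6

    def test_residual_whiteness_on_correct_model(self, truth, grids):
        """Sign-runs test on fit residuals passes at alpha=0.01 for >=95% of seeds."""
        t, w = grids
        passed = 0
        n_seeds = 20
        for s in range(n_seeds):
            noisy, _ = simulate_surface(replace(truth, seed=1000 + s), t, w)
            fit = fit_global(noisy, n_starts=1)
            r = fit.residual.ravel()
            signs = r > 0
            runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
            n1, n2 = int(signs.sum()), int((~signs).sum())
            mu = 2.0 * n1 * n2 / (n1 + n2) + 1.0
            var = (mu - 1.0) * (mu - 2.0) / (n1 + n2 - 1.0)
            z = (runs - mu) / np.sqrt(var)
            if abs(z) < 2.576:  # two-sided alpha = 0.01
                passed += 1
        assert passed >= 0.95 * n_seeds

    def test_rank_deficient_surface_warns(self):
        t = np.linspace(0.0, 100.0, 50)
        w = np.linspace(550.0, 600.0, 6)
        rank1 = np.outer(np.exp(-t / 50.0), np.ones(6))
        with pytest.warns(UserWarning, match="rank"):
            fit_global(TimeWavelengthSurface(t, w, rank1), n_starts=1, max_iter=5)

    def test_tie_transfer_shares_one_constant(self, truth, grids):
        t, w = grids
        noisy, _ = simulate_surface(truth, t, w)
        fit = fit_global(noisy, n_starts=1, tie_transfer=True)
        assert fit.model.tau_ab == fit.model.tau_bc

    def test_nonnegative_amplitude_option(self, truth, coarse_grids):
        t, w = coarse_grids
        noisy, _ = simulate_surface(truth, t, w)
        fit = fit_global(noisy, n_starts=1, nonneg_amplitudes=True)
        for s in (fit.amplitudes.s_a, fit.amplitudes.s_b, fit.amplitudes.s_c):
            assert np.all(s >= 0.0)


class TestTransferEfficiency:
    def test_frozen_values(self):
        assert transfer_efficiency(120.0, np.inf) == 1.0
        assert transfer_efficiency(77.0, 77.0) == pytest.approx(0.5)
        # the competing-rates formula at the measured 120 ps vs 1500 ps
        assert transfer_efficiency(120.0, 1500.0) == pytest.approx(0.925926, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            transfer_efficiency(0.0, 1500.0)
        with pytest.raises(ValueError):
            transfer_efficiency(120.0, -1.0)

    @given(
        tau_t=st.floats(1.0, 1e4),
        tau_d=st.floats(1.0, 1e4),
        bump=st.floats(1.01, 2.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotonicity(self, tau_t, tau_d, bump):
        base = transfer_efficiency(tau_t, tau_d)
        assert transfer_efficiency(tau_t * bump, tau_d) < base
        assert transfer_efficiency(tau_t, tau_d * bump) > base
        assert 0.0 < base < 1.0


class TestBandDecay:
    def test_single_exponential_self_fit(self):
        t = np.linspace(-20.0, 600.0, 311)
        w = np.linspace(560.0, 610.0, 11)
        decay = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / 100.0), 0.0)
        surf = TimeWavelengthSurface(t, w, np.outer(decay, np.ones(11)))
        assert band_decay_time(surf, (560.0, 610.0)) == pytest.approx(100.0, rel=0.01)

    def test_band_outside_grid_rejected(self, truth, grids):
        t, w = grids
        _, clean = simulate_surface(replace(truth, noise_scale=0.0), t, w)
        with pytest.raises(ValueError):
            band_decay_time(clean, (100.0, 200.0))

    def test_a_only_surface_returns_effective_lifetime(self, truth, grids):
        t, w = grids
        amps = truth.amplitudes(w)
        zeros = np.zeros_like(w)
        surf = predict_surface(truth.model, SpectralAmplitudes(w, amps.s_a, zeros, zeros), t, w)
        expected = 1.0 / (1.0 / 50.0 + 1.0 / 1000.0)  # 47.6 ps
        assert band_decay_time(surf, (560.0, 610.0)) == pytest.approx(expected, rel=0.05)

    def test_default_truth_pe_band_decays_in_about_120ps(self, truth, grids):
        """The full cascade's 560-610 nm emission decays with an effective
        ~120 ps time — the PE-to-core transfer time the experiment reports —
        because the B and C compartments retain residual PE emission."""
        t, w = grids
        noisy, _ = simulate_surface(truth, t, w)
        tau = band_decay_time(noisy, (560.0, 610.0))
        assert tau == pytest.approx(120.0, rel=0.15)

    def test_non_decaying_band_flagged(self):
        t = np.linspace(0.0, 100.0, 50)
        w = np.linspace(560.0, 610.0, 6)
        rising = np.outer(np.linspace(1.0, 2.0, 50), np.ones(6))
        with pytest.raises(FitFailure):
            band_decay_time(TimeWavelengthSurface(t, w, rising), (560.0, 610.0))
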
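"""Neural-mass forward model: dynamics, linearisation and spectra.

Oracles: a validated ODE integrator (scipy solve_ivp) for the drift and
fixed point, finite differences for the Jacobian, and the FFT of the
linearised impulse response for the transfer function.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from spectraldcm import (ConvergenceError, MassModelParams, NumericalError,
                         StabilityError, drift_mass, fixed_point, jacobian_mass,
                         one_over_f_spectrum, predict_csd_mass, sigmoid,
                         transfer_mass)
from spectraldcm.exceptions import ValidationError
from spectraldcm.mass import hz_to_angular, sigmoid_deriv


class TestSigmoid:
    def test_centred_at_zero(self):
        assert sigmoid(0.0, 0.54, 0.0) == 0.0

    def test_slope_at_origin_is_quarter_r(self):
        r = 0.54
        h = 1e-6
        num = (sigmoid(h, r, 0.0) - sigmoid(-h, r, 0.0)) / (2 * h)
        assert num == pytest.approx(r / 4.0, abs=1e-8)
        assert sigmoid_deriv(0.0, r, 0.0) == pytest.approx(0.135, abs=1e-12)

    def test_saturates_at_half(self):
        assert sigmoid(1e6, 0.54, 0.0) == pytest.approx(0.5, abs=1e-12)
        assert sigmoid(-1e6, 0.54, 0.0) == pytest.approx(-0.5, abs=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(v=st.floats(-15, 15), dv=st.floats(1e-2, 5),
           r=st.floats(0.05, 1.0), eta=st.floats(-5, 5))
    def test_strictly_increasing(self, v, dv, r, eta):
        # domain kept clear of exact floating-point saturation
        assert sigmoid(v + dv, r, eta) > sigmoid(v, r, eta)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValidationError):
            sigmoid(0.0, -1.0, 0.0)


class TestDrift:
    def test_origin_is_fixed_point(self, mass_1ch):
        assert np.allclose(drift_mass(np.zeros(8), mass_1ch, 0.0), 0.0)

    def test_uncoupled_damped_oscillator(self):
        p = MassModelParams(a={k: 0.0 for k in MassModelParams().a})
        state = np.zeros(8)
        state[0] = 1.0                       # v_1 = 1, v̇_1 = 0
        ds = drift_mass(state, p, 0.0)
        assert ds[4] == pytest.approx(-p.kappa[0] ** 2)

    def test_matches_ode_trajectory_derivative(self, mass_1ch):
        """drift equals centred finite differences of an integrated trajectory."""
        rng = np.random.default_rng(0)
        x0 = rng.normal(scale=0.5, size=8)
        sol = solve_ivp(lambda t, x: drift_mass(x, mass_1ch, 0.2), (0, 20), x0,
                        dense_output=True, rtol=1e-10, atol=1e-12)
        for t in (2.0, 7.5, 15.0):
            h = 1e-4
            num = (sol.sol(t + h) - sol.sol(t - h)) / (2 * h)
            assert np.allclose(num, drift_mass(sol.sol(t), mass_1ch, 0.2), atol=1e-5)

    def test_nonfinite_state_rejected(self, mass_1ch):
        with pytest.raises(NumericalError):
            drift_mass(np.full(8, np.nan), mass_1ch, 0.0)


class TestFixedPoint:
    def test_zero_input_gives_origin(self, mass_1ch):
        assert np.allclose(fixed_point(mass_1ch, 0.0), 0.0)

    def test_agrees_with_long_integration(self, mass_1ch):
        U0 = 0.1
        vstar = fixed_point(mass_1ch, U0)
        x0 = np.zeros(8)
        sol = solve_ivp(lambda t, x: drift_mass(x, mass_1ch, U0), (0, 3000), x0,
                        rtol=1e-11, atol=1e-13)
        assert np.allclose(sol.y[:4, -1], vstar, atol=1e-6)
        assert np.max(np.abs(drift_mass(np.r_[vstar, np.zeros(4)], mass_1ch, U0))) < 1e-9

    def test_budget_exhaustion_names_population(self, mass_1ch):
        with pytest.raises(ConvergenceError, match="population"):
            fixed_point(mass_1ch, 5.0, max_iter=1)


class TestJacobian:
    def test_uncoupled_eigenvalues(self):
        p = MassModelParams(a={k: 0.0 for k in MassModelParams().a})
        lam = np.linalg.eigvals(jacobian_mass(p))
        expect = np.sort(np.repeat(-p.kappa, 2))
        assert np.allclose(np.sort(lam.real), expect, atol=1e-12)
        assert np.allclose(lam.imag, 0.0, atol=1e-12)

    def test_matches_finite_differences(self, mass_1ch):
        J = jacobian_mass(mass_1ch)
        h = 1e-6
        for j in range(8):
            d = np.zeros(8)
            d[j] = h
            col = (drift_mass(d, mass_1ch, 0.0) - drift_mass(-d, mass_1ch, 0.0)) / (2 * h)
            assert np.allclose(col, J[:, j], rtol=1e-6, atol=1e-9)

    def test_input_coupling_entry(self, mass_1ch):
        # acceleration of population 1 couples to v_4 via kappa_1 * a14 * r/4
        J = jacobian_mass(mass_1ch, np.zeros(4))
        expect = mass_1ch.kappa[0] * mass_1ch.a["a14"] * mass_1ch.r / 4.0
        assert J[4, 3] == pytest.approx(expect)


class TestTransfer:
    def test_strictly_proper(self, mass_1ch):
        T = transfer_mass(mass_1ch, np.array([1e4]))
        assert np.abs(T[0, 0]) < 1e-6

    def test_single_population_closed_form(self):
        p = MassModelParams(a={k: 0.0 for k in MassModelParams().a})
        omega = hz_to_angular(np.arange(1.0, 100.0, 7.0))
        T = transfer_mass(p, omega)[:, 0]
        kappa = p.kappa[0]
        assert np.allclose(T, kappa / (1j * omega + kappa) ** 2, rtol=1e-10)

    def test_matches_fft_of_impulse_response(self, mass_2ch):
        """Time-domain oracle: T(ω) equals the DFT of C e^{Jt} B."""
        J = jacobian_mass(mass_2ch)
        B = np.zeros(8)
        B[4:] = mass_2ch.kappa * mass_2ch.u_weights
        C = np.zeros((2, 8))
        C[:, :4] = mass_2ch.Lw
        dt, N = 0.1, 1 << 16                       # ms; 6.55 s record
        lam, V = np.linalg.eig(J)
        coef = (C @ V) * np.linalg.solve(V, B)[None, :]     # (2, 8)
        t = np.arange(N) * dt
        h = np.real(np.exp(np.outer(t, lam)) @ coef.T)      # (N, 2)
        Tfft = np.fft.rfft(h, axis=0) * dt
        f_bins = np.fft.rfftfreq(N, d=dt / 1000.0)
        keep = (f_bins >= 1.0) & (f_bins <= 100.0)
        Tpred = transfer_mass(mass_2ch, hz_to_angular(f_bins[keep]))
        err = np.abs(Tfft[keep] - Tpred) / np.abs(Tpred)
        assert err.max() < 1e-3

    def test_unstable_system_raises(self):
        p = MassModelParams(a={**MassModelParams().a, "a14": 20.0, "a41": 20.0})
        with pytest.raises(StabilityError, match="shrink"):
            transfer_mass(p, np.array([0.1]))


class TestOneOverF:
    def test_values_and_limits(self):
        assert one_over_f_spectrum(np.log(1.0), np.log(2.0), 2.0) == pytest.approx(2.0)
        assert one_over_f_spectrum(0.3, -745.0, 1.7) == pytest.approx(np.exp(0.3))
        assert one_over_f_spectrum(0.3, 0.0, 1e12) == pytest.approx(np.exp(0.3))

    def test_requires_positive_omega(self):
        with pytest.raises(ValidationError):
            one_over_f_spectrum(0.0, 0.0, 0.0)


class TestPredictCSD:
    def test_hermitian_and_psd(self, mass_2ch, freqs):
        pred = predict_csd_mass(mass_2ch, freqs)
        assert np.allclose(pred.csd, np.conj(np.swapaxes(pred.csd, 1, 2)))
        for g in pred.csd:
            w = np.linalg.eigvalsh(g.real)
            assert w.min() > -1e-10
        gn = one_over_f_spectrum(mass_2ch.alpha_n, mass_2ch.beta_n, hz_to_angular(freqs))
        assert np.all(pred.auto_spectra() >= gn[:, None] - 1e-12)

    def test_observation_gain_scales_signal_quadratically(self, mass_2ch, freqs):
        gamma = 3.0
        scaled = mass_2ch.with_offsets({"lw": np.log(gamma)})
        g0 = predict_csd_mass(mass_2ch, freqs).csd
        g1 = predict_csd_mass(scaled, freqs).csd
        gn = one_over_f_spectrum(mass_2ch.alpha_n, mass_2ch.beta_n,
                                 hz_to_angular(freqs))[:, None, None]
        assert np.allclose(g1 - gn, gamma**2 * (g0 - gn), rtol=1e-10)

    def test_matches_welch_spectra_of_simulation(self, mass_2ch):
        """Stochastic oracle: Welch cross-spectra of a long linearised
        simulation driven by white input reproduce the predicted spectral
        shape (a single global scale absorbs the transform convention)."""
        from scipy.signal import StateSpace, lsim, csd as welch_csd

        params = mass_2ch.with_offsets({"beta_u": -30.0, "alpha_n": -30.0,
                                        "beta_n": -30.0})
        J = jacobian_mass(params)
        B = np.zeros((8, 1))
        B[4:, 0] = params.kappa * params.u_weights
        C = np.zeros((2, 8))
        C[:, :4] = params.Lw
        sys = StateSpace(J, B, C, np.zeros((2, 1)))
        rng = np.random.default_rng(11)
        dt = 0.5                                     # ms
        t = np.arange(int(120_000 / dt)) * dt        # 120 s
        u = rng.normal(size=t.size) / np.sqrt(dt)
        _, y, _ = lsim(sys, u, t)
        fs = 1000.0 / dt
        f, Pxx = welch_csd(y[:, 0], y[:, 0], fs=fs, nperseg=4096)
        _, Pyy = welch_csd(y[:, 1], y[:, 1], fs=fs, nperseg=4096)
        _, Pxy = welch_csd(y[:, 0], y[:, 1], fs=fs, nperseg=4096)
        keep = (f >= 4.0) & (f <= 100.0)
        pred = predict_csd_mass(params, f[keep])
        for emp, mod in [(Pxx[keep], pred.csd[:, 0, 0].real),
                         (Pyy[keep], pred.csd[:, 1, 1].real)]:
            ratio = emp / mod
            ratio /= np.median(ratio)
            assert np.corrcoef(np.log(emp), np.log(mod))[0, 1] > 0.95
            assert np.median(np.abs(np.log(ratio))) < 0.2
        # cross-spectrum: same scale, complex agreement up to sampling error
        # (scipy's csd(x, y) averages conj(X)·Y, i.e. the conjugate of our
        # T_l g_u T_m† convention)
        scale = np.median(Pxx[keep] / pred.csd[:, 0, 0].real)
        cc = np.abs(Pxy[keep] - scale * np.conj(pred.csd[:, 0, 1]))
        assert np.median(cc / np.abs(scale * pred.csd[:, 0, 1])) < 0.35
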
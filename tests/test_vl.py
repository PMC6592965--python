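"""Variational Laplace: likelihood, free energy, inversion.

The conjugate linear-Gaussian model is the exact oracle: its posterior and
log evidence are available in closed form, and the inversion — posed through
the same interface as the spectral models — must reproduce both.
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from spectraldcm import (CSDForwardModel, GaussianDensity, LinearForwardModel,
                         MassModelParams, NumericalError, VariationalLaplace,
                         free_energy, loglik_csd, predict_csd_mass, vl_invert)
from spectraldcm.exceptions import ValidationError
from spectraldcm.simulate import simulate_subject

from conftest import make_linear_problem


class TestLoglik:
    def test_zero_residual_is_normalisation_only(self, mass_1ch, freqs):
        pred = predict_csd_mass(mass_1ch, freqs)
        lam = 0.7
        n = pred.vector().size
        expect = 0.5 * n * lam - 0.5 * n * np.log(2 * np.pi)
        assert loglik_csd(pred, pred, lam) == pytest.approx(expect)

    def test_precision_residual_tradeoff(self, mass_1ch, freqs):
        pred = predict_csd_mass(mass_1ch, freqs)
        data, _ = simulate_subject(mass_1ch, freqs, noise_sd=1.0, seed=0)
        lls = [loglik_csd(data, pred, lam) for lam in (-2.0, 0.0, 4.0, 12.0)]
        assert lls[1] > lls[0]           # some precision helps
        assert lls[3] < lls[2]           # too much precision hurts

    def test_matches_dense_multivariate_normal(self, mass_1ch):
        toy_freqs = np.array([10.0, 20.0, 30.0])
        pred = predict_csd_mass(mass_1ch, toy_freqs)
        data, _ = simulate_subject(mass_1ch, toy_freqs, noise_sd=0.3, seed=1)
        lam = 1.1
        n = pred.vector().size
        expect = multivariate_normal.logpdf(
            data.vector(), mean=pred.vector(), cov=np.exp(-lam) * np.eye(n))
        assert loglik_csd(data, pred, lam) == pytest.approx(expect, abs=1e-10)

    def test_grid_mismatch_rejected(self, mass_1ch, freqs):
        pred = predict_csd_mass(mass_1ch, freqs)
        other = predict_csd_mass(mass_1ch, freqs + 1.0)
        with pytest.raises(ValidationError):
            loglik_csd(other, pred, 0.0)


class TestFreeEnergy:
    def test_zero_kl_when_q_equals_prior(self):
        rng = np.random.default_rng(3)
        prob = make_linear_problem(rng)
        model = LinearForwardModel(prob["A"], prob["names"])
        # flat likelihood: evaluate with data equal to the prior prediction
        y0 = prob["A"] @ prob["prior"].mean
        lam = -np.log(prob["sigma2"])
        F = free_energy(prob["prior"], prob["prior"], y0, model, lam)
        n = y0.size
        ll = 0.5 * n * lam - 0.5 * n * np.log(2 * np.pi)
        assert F == pytest.approx(ll, abs=1e-10)

    def test_linear_gaussian_evidence(self):
        rng = np.random.default_rng(4)
        prob = make_linear_problem(rng)
        model = LinearForwardModel(prob["A"], prob["names"])
        q = GaussianDensity(prob["names"], prob["post_mean"], prob["post_cov"])
        lam = -np.log(prob["sigma2"])
        F = free_energy(q, prob["prior"], prob["y"], model, lam)
        assert F == pytest.approx(prob["logev"], abs=1e-3)

    def test_occam_penalty_direction(self):
        rng = np.random.default_rng(5)
        prob = make_linear_problem(rng)
        model = LinearForwardModel(prob["A"], prob["names"])
        lam = -np.log(prob["sigma2"])
        q = GaussianDensity(prob["names"], prob["post_mean"], prob["post_cov"])
        F_good = free_energy(q, prob["prior"], prob["y"], model, lam)
        tight = GaussianDensity.iid(prob["names"], 5.0, 1e-4)   # mismatched prior
        F_bad = free_energy(q, tight, prob["y"], model, lam)
        assert F_bad < F_good


class TestInversion:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_conjugate_posterior_and_evidence(self, seed):
        rng = np.random.default_rng(100 + seed)
        prob = make_linear_problem(rng, p=rng.integers(2, 6))
        model = LinearForwardModel(prob["A"], prob["names"])
        res = vl_invert(prob["y"], model, prob["prior"],
                        estimate_noise=False,
                        lambda_init=-np.log(prob["sigma2"]))
        assert np.allclose(res.posterior.mean, prob["post_mean"], atol=1e-6)
        assert np.allclose(res.posterior.cov, prob["post_cov"], atol=1e-6)
        assert res.free_energy == pytest.approx(prob["logev"], abs=1e-3)

    def test_self_fit_stays_at_prior_mean(self, mass_1ch, freqs):
        model = CSDForwardModel(mass_1ch, ("a14", "a41"), freqs)
        data, _ = simulate_subject(mass_1ch, freqs, noise_sd=0.0, seed=0)
        res = vl_invert(data, model)
        assert np.allclose(res.posterior.mean, 0.0, atol=1e-3)
        assert np.isfinite(res.free_energy)

    def test_trajectory_monotone_and_posterior_spd(self, mass_1ch, freqs):
        model = CSDForwardModel(mass_1ch, ("a11", "a14"), freqs)
        data, _ = simulate_subject(
            mass_1ch.with_offsets({"a11": 0.3, "a14": -0.2}), freqs, 0.5, seed=2)
        res = vl_invert(data, model)
        assert np.all(np.diff(res.trajectory) >= -1e-9)
        w = np.linalg.eigvalsh(res.posterior.cov)
        assert w.min() > 0

    def test_bit_identical_reproducibility(self, mass_1ch, freqs):
        model = CSDForwardModel(mass_1ch, ("a11", "a14"), freqs)
        data, _ = simulate_subject(mass_1ch, freqs, 0.5, seed=3)
        r1 = vl_invert(data, model)
        r2 = vl_invert(data, model)
        assert np.array_equal(r1.posterior.mean, r2.posterior.mean)
        assert np.array_equal(r1.posterior.cov, r2.posterior.cov)
        assert r1.free_energy == r2.free_energy

    def test_unstable_prior_mean_raises(self, freqs):
        bad = MassModelParams(a={**MassModelParams().a, "a14": 20.0, "a41": 20.0})
        model = CSDForwardModel(bad, ("a14",), freqs)
        data, _ = simulate_subject(MassModelParams(), freqs, 0.5, seed=0)
        with pytest.raises(NumericalError, match="prior"):
            vl_invert(data, model)

    def test_sklearn_params_roundtrip(self):
        est = VariationalLaplace(max_iter=10, tol_nats=0.5)
        params = est.get_params()
        assert params["max_iter"] == 10
        est2 = VariationalLaplace().set_params(**params)
        assert est2.tol_nats == 0.5

    def test_noise_precision_recovered(self, mass_1ch, freqs):
        noise_sd = 0.5
        data, _ = simulate_subject(mass_1ch, freqs, noise_sd, seed=4)
        model = CSDForwardModel(mass_1ch, ("a14", "a41"), freqs)
        res = vl_invert(data, model)
        lam_true = -2 * np.log(noise_sd)
        assert res.hyper_posterior.mean[0] == pytest.approx(lam_true, abs=0.6)
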
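"""Bayesian model reduction and parametric empirical Bayes.

reduce_model is checked for exactness against direct conjugate refitting on
linear-Gaussian problems; the PEB layer is checked for its fixed points
(single subject, identical subjects), invariances (subject ordering) and
bookkeeping (Kronecker dimensions of the second-level parameter space).
"""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from spectraldcm import (GaussianDensity, HierarchicalSpec, InversionResult,
                         NumericalError, PEB, bayes_factor,
                         bayesian_model_average, peb_fit, reduce_model,
                         search_model_space)
from spectraldcm.exceptions import ValidationError
from spectraldcm.types import ScoredModel


def conjugate_world(rng, n=25, p=5, sigma2=0.3):
    """Linear-Gaussian problem: returns (prior, posterior, A, y, evidence fn)."""
    A = rng.normal(size=(n, p))
    y = A @ rng.normal(size=p) + rng.normal(scale=np.sqrt(sigma2), size=n)
    names = tuple(f"b{i}" for i in range(p))
    prior = GaussianDensity(names, rng.normal(size=p) * 0.2,
                            np.diag(rng.uniform(0.5, 2.0, p)))

    def refit(pr):
        H = A.T @ A / sigma2 + pr.precision()
        cov = np.linalg.inv(H)
        mean = cov @ (A.T @ y / sigma2 + pr.precision() @ pr.mean)
        ev = multivariate_normal.logpdf(
            y, mean=A @ pr.mean, cov=sigma2 * np.eye(n) + A @ pr.cov @ A.T)
        return GaussianDensity(names, mean, cov), float(ev)

    posterior, ev_full = refit(prior)
    return prior, posterior, ev_full, refit, names


class TestReduceModel:
    def test_identity_reduction(self):
        rng = np.random.default_rng(0)
        prior, post, _, _, _ = conjugate_world(rng)
        red_post, dF = reduce_model(prior, post, prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(red_post.mean, post.mean)
        assert np.allclose(red_post.cov, post.cov)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_conjugate_refit(self, seed):
        rng = np.random.default_rng(200 + seed)
        prior, post, ev_full, refit, names = conjugate_world(
            rng, p=int(rng.integers(3, 9)))
        reduced_prior = prior
        for i in rng.choice(len(names), size=2, replace=False):
            reduced_prior = reduced_prior.with_variance(names[i], 1e-8, mean=0.0)
        red_post, dF = reduce_model(prior, post, reduced_prior)
        direct_post, ev_red = refit(reduced_prior)
        assert abs(dF - (ev_red - ev_full)) <= 1e-6
        assert np.max(np.abs(red_post.mean - direct_post.mean)) <= 1e-8

    def test_clamping_limit(self):
        rng = np.random.default_rng(7)
        prior, post, _, _, names = conjugate_world(rng)
        clamped = prior.with_variance(names[0], 1e-12, mean=0.4)
        red_post, _ = reduce_model(prior, post, clamped)
        assert red_post.mean[0] == pytest.approx(0.4, abs=1e-4)

    def test_incompatible_reduction_raises(self):
        names = ("a", "b")
        prior = GaussianDensity.iid(names, 0.0, 0.01)       # tight prior
        post = GaussianDensity.iid(names, 0.0, 0.02)
        wide = GaussianDensity.iid(names, 0.0, 10.0)
        with pytest.raises(NumericalError, match="incompatible"):
            reduce_model(prior, post, wide)


class TestBayesFactor:
    @pytest.mark.parametrize("fi,fj,value,label", [
        (1.0, 1.0, 0.0, "weak"),
        (30.0, 4.0, 26.0, "strong"),
        (4.0, 30.0, -26.0, "strong"),
        (5.9, 3.0, 2.9, "weak"),
    ])
    def test_value_and_label(self, fi, fj, value, label):
        v, l = bayes_factor(fi, fj)
        assert v == pytest.approx(value)
        assert l == label

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            bayes_factor(np.inf, 0.0)


def make_subjects(rng, thetas, names, obs_sd=0.1, prior_var=0.25):
    """InversionResults emulating first-level fits around given parameters."""
    prior = GaussianDensity.iid(names, 0.0, prior_var)
    subs = []
    for th in thetas:
        p = len(names)
        Sq = np.linalg.inv(np.eye(p) / obs_sd**2 + prior.precision())
        muq = Sq @ ((np.asarray(th) + rng.normal(scale=obs_sd, size=p)) / obs_sd**2)
        subs.append(InversionResult(
            posterior=GaussianDensity(names, muq, Sq),
            hyper_posterior=GaussianDensity(("lambda0",), [0.0], [[1.0]]),
            free_energy=0.0, trajectory=[0.0], prediction=None,
            prior=prior, n_data=50))
    return subs


class TestPEB:
    names = tuple(f"a{i}" for i in range(4))

    def test_single_subject_group_mean(self):
        rng = np.random.default_rng(1)
        th = np.array([0.3, -0.2, 0.1, 0.0])
        subs = make_subjects(rng, [th], self.names, obs_sd=0.05)
        res = peb_fit(subs, HierarchicalSpec(np.ones((1, 1))))
        group_mean = res.beta_posterior.mean[:4]
        assert np.allclose(group_mean, subs[0].posterior.mean, atol=0.1)

    def test_identical_subjects_shrinkage(self):
        th = np.array([0.3, -0.2, 0.1, 0.0])
        one = make_subjects(np.random.default_rng(9), [th], self.names)[0]
        res_by_n = {}
        for N in (4, 16):
            subs = [one] * N                       # literally shared posterior
            res = peb_fit(subs, HierarchicalSpec(np.ones((N, 1))))
            res_by_n[N] = res
            assert np.allclose(res.beta_posterior.mean[:4],
                               one.posterior.mean, atol=0.05)
        var4 = np.diag(res_by_n[4].beta_posterior.cov)[:4]
        var16 = np.diag(res_by_n[16].beta_posterior.cov)[:4]
        assert np.all(var16 < var4)

    def test_subject_ordering_invariance(self):
        rng = np.random.default_rng(3)
        N = 8
        x = rng.normal(size=N)
        thetas = [np.r_[0.4 * xi, 0, 0, 0] + rng.normal(scale=0.1, size=4)
                  for xi in x]
        subs = make_subjects(np.random.default_rng(5), thetas, self.names)
        X = np.column_stack([np.ones(N), x])
        res1 = peb_fit(subs, HierarchicalSpec(X, ("mean", "x")))
        perm = np.random.default_rng(0).permutation(N)
        res2 = peb_fit([subs[i] for i in perm],
                       HierarchicalSpec(X[perm], ("mean", "x")))
        assert np.allclose(res1.beta_posterior.mean, res2.beta_posterior.mean,
                           atol=1e-8)
        assert res1.free_energy == pytest.approx(res2.free_energy, abs=1e-6)

    def test_trajectory_monotone(self):
        rng = np.random.default_rng(4)
        subs = make_subjects(rng, [rng.normal(scale=0.3, size=4) for _ in range(6)],
                             self.names)
        res = peb_fit(subs, HierarchicalSpec(np.ones((6, 1))))
        assert np.all(np.diff(res.trajectory) >= -1e-9)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6), 2 * np.arange(6)])
        with pytest.raises(ValidationError, match="collinear"):
            HierarchicalSpec(X, ("mean", "x", "x2"))

    def test_kronecker_bookkeeping(self):
        """1 constant + 3 covariates over 10 parameters: 40 second-level
        parameters, 30 of them group effects."""
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(8), rng.normal(size=(8, 3))])
        spec = HierarchicalSpec(X, ("mean", "c1", "c2", "c3"))
        params = tuple(f"g{i}" for i in range(10))
        assert len(spec.second_level_names(params)) == 40
        assert len(spec.group_effect_names(params)) == 30

    def test_estimator_api(self):
        est = PEB(max_iter=8)
        assert est.get_params()["max_iter"] == 8


class TestSearchAndAverage:
    def _fitted_peb(self, beta_scale=0.0, seed=6):
        rng = np.random.default_rng(seed)
        names = tuple(f"a{i}" for i in range(4))
        N = 12
        x = rng.normal(size=N)
        thetas = [np.r_[beta_scale * xi, 0, 0, 0]
                  + rng.normal(scale=0.1, size=4) for xi in x]
        subs = make_subjects(np.random.default_rng(seed + 1), thetas, names)
        X = np.column_stack([np.ones(N), x])
        return peb_fit(subs, HierarchicalSpec(X, ("mean", "x")))

    def test_single_full_mask_has_probability_one(self):
        res = self._fitted_peb()
        scored, incl = search_model_space(res, [res.group_effect_names])
        assert len(scored) == 1
        assert scored[0].probability == pytest.approx(1.0)

    def test_null_data_prefers_empty_model(self):
        res = self._fitted_peb(beta_scale=0.0)
        scored, incl = search_model_space(res)
        best = max(scored, key=lambda s: s.free_energy)
        assert best.mask == ()
        assert all(v < 0.5 for v in incl.values())

    def test_true_effect_detected(self):
        res = self._fitted_peb(beta_scale=0.6)
        scored, incl = search_model_space(res)
        assert incl["x:a0"] > 0.9
        probs = [s.probability for s in scored]
        assert sum(probs) == pytest.approx(1.0)
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_empty_space_rejected(self):
        res = self._fitted_peb()
        with pytest.raises(ValidationError, match="empty"):
            search_model_space(res, [])

    def test_bma_single_model_unchanged(self):
        res = self._fitted_peb()
        scored, _ = search_model_space(res, [res.group_effect_names])
        bma = bayesian_model_average(scored)
        assert np.allclose(bma.mean, scored[0].posterior.mean)
        assert np.allclose(bma.cov, scored[0].posterior.cov)

    def test_bma_symmetric_mixture(self):
        names = ("a",)
        m = 0.7
        models = [
            ScoredModel(("a",), 0.0, GaussianDensity(names, [m], [[0.1]]), 0.5),
            ScoredModel((), 0.0, GaussianDensity(names, [-m], [[0.1]]), 0.5),
        ]
        bma = bayesian_model_average(models)
        assert bma.mean[0] == pytest.approx(0.0)
        assert bma.cov[0, 0] == pytest.approx(0.1 + m**2)
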
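"""Self-contained benchmark studies over synthetic data.

Each function sets up a study with known ground truth, runs the relevant
part of the pipeline from scratch and returns summary metrics.  The test
suite asserts on these metrics and the reproduction script reports them;
every study is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal

from .bmr import reduce_model
from .field import FieldModelParams, kernel_ft_field, predict_csd_field
from .laminar import layer_assignment_comparison
from .mass import MassModelParams, hz_to_angular, jacobian_mass, predict_csd_mass, transfer_mass
from .peb import HierarchicalSpec, peb_fit, search_model_space
from .simulate import laminar_template, simulate_group, simulate_laminar, simulate_subject
from .types import GaussianDensity
from .vl import CSDForwardModel, LinearForwardModel, vl_invert

__all__ = [
    "linear_gaussian_problem",
    "bookkeeping_counts",
    "bmr_exactness",
    "evidence_exactness",
    "gain_recovery",
    "laminar_swap_study",
    "peb_recovery_study",
    "forward_validity",
]

#: coarse grid used by the fitting studies (2 Hz over 4-100 Hz)
STUDY_FREQS = np.arange(4.0, 101.0, 2.0)


def _two_channel_base() -> MassModelParams:
    """Observation reading the fast (ch 0) and slow (ch 1) principal
    populations — the configuration in which both resonant loops are
    identifiable."""
    return MassModelParams(Lw=((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 1.0, 0.0)))


def linear_gaussian_problem(rng, n=25, p=4, sigma2=0.5, prior_var=2.0):
    """A linear-Gaussian regression with conjugate posterior and exact
    log evidence (the oracle for inversion and reduction checks)."""
    A = rng.normal(size=(n, p))
    theta = rng.normal(size=p)
    y = A @ theta + rng.normal(scale=np.sqrt(sigma2), size=n)
    names = tuple(f"b{i}" for i in range(p))
    prior = GaussianDensity.iid(names, 0.0, prior_var)
    H = A.T @ A / sigma2 + prior.precision()
    cov = np.linalg.inv(H)
    mean = cov @ (A.T @ y / sigma2 + prior.precision() @ prior.mean)
    logev = multivariate_normal.logpdf(
        y, mean=A @ prior.mean, cov=sigma2 * np.eye(n) + A @ prior.cov @ A.T)
    return {
        "A": A, "y": y, "sigma2": sigma2, "prior": prior,
        "post_mean": mean, "post_cov": cov, "logev": float(logev), "names": names,
    }


# ---------------------------------------------------------------------------
# Structural bookkeeping
# ---------------------------------------------------------------------------

def bookkeeping_counts() -> dict:
    """Second-level parameter counts for a constant + 3 covariates design
    over the field model's intrinsic connections."""
    field = FieldModelParams()
    n_intrinsic = len(field.alpha)
    X = np.column_stack([np.ones(8), np.arange(8.0), np.arange(8.0) ** 2,
                         np.sin(np.arange(8.0))])
    spec = HierarchicalSpec(X, ("mean", "c1", "c2", "c3"))
    params = tuple(sorted(field.alpha))
    return {
        "n_intrinsic_connections": n_intrinsic,
        "n_second_level": len(spec.second_level_names(params)),
        "n_group_effects": len(spec.group_effect_names(params)),
    }


# ---------------------------------------------------------------------------
# Exactness studies
# ---------------------------------------------------------------------------

def bmr_exactness(n_problems: int = 50, seed: int = 0) -> dict:
    """reduce_model vs direct conjugate refit on random linear-Gaussian
    problems with <= 8 parameters and 2 clamped coefficients."""
    max_dF = 0.0
    max_mean = 0.0
    for i in range(n_problems):
        rng = np.random.default_rng([seed, i])
        p = int(rng.integers(3, 9))
        prob = linear_gaussian_problem(rng, p=p)
        prior = GaussianDensity(prob["names"], rng.normal(size=p) * 0.2,
                                np.diag(rng.uniform(0.5, 2.0, p)))
        H = prob["A"].T @ prob["A"] / prob["sigma2"] + prior.precision()
        cov = np.linalg.inv(H)
        mean = cov @ (prob["A"].T @ prob["y"] / prob["sigma2"]
                      + prior.precision() @ prior.mean)
        post = GaussianDensity(prob["names"], mean, cov)
        reduced_prior = prior
        for j in rng.choice(p, size=2, replace=False):
            reduced_prior = reduced_prior.with_variance(prob["names"][j], 1e-8, mean=0.0)
        red_post, dF = reduce_model(prior, post, reduced_prior)
        # direct conjugate refit under the reduced prior
        Hr = prob["A"].T @ prob["A"] / prob["sigma2"] + reduced_prior.precision()
        covr = np.linalg.inv(Hr)
        meanr = covr @ (prob["A"].T @ prob["y"] / prob["sigma2"]
                        + reduced_prior.precision() @ reduced_prior.mean)
        ev = lambda pr: multivariate_normal.logpdf(
            prob["y"], mean=prob["A"] @ pr.mean,
            cov=prob["sigma2"] * np.eye(prob["y"].size) + prob["A"] @ pr.cov @ prob["A"].T)
        dF_direct = ev(reduced_prior) - ev(prior)
        max_dF = max(max_dF, abs(dF - dF_direct))
        max_mean = max(max_mean, float(np.max(np.abs(red_post.mean - meanr))))
    return {"n_problems": n_problems, "max_delta_f_error": max_dF,
            "max_posterior_mean_error": max_mean}


def evidence_exactness(n_problems: int = 10, seed: int = 0) -> dict:
    """vl_invert vs analytic log evidence on linear-Gaussian problems
    (noise precision fixed at its true value)."""
    max_err = 0.0
    for i in range(n_problems):
        rng = np.random.default_rng([seed, i])
        prob = linear_gaussian_problem(rng, p=int(rng.integers(2, 7)))
        model = LinearForwardModel(prob["A"], prob["names"])
        res = vl_invert(prob["y"], model, prob["prior"], estimate_noise=False,
                        lambda_init=-np.log(prob["sigma2"]))
        max_err = max(max_err, abs(res.free_energy - prob["logev"]))
    return {"n_problems": n_problems, "max_evidence_error_nats": max_err}


# ---------------------------------------------------------------------------
# Recovery studies
# ---------------------------------------------------------------------------

def gain_recovery(n_runs: int = 10, seed: int = 0, level: float = 0.90) -> dict:
    """Two perturbed connection gains (one per resonant loop) recovered from
    noisy single-subject spectra: credible-interval coverage and
    truth-vs-posterior-mean correlation."""
    base = _two_channel_base()
    names = ("a14", "a32")
    covered = 0
    truths, means = [], []
    for i in range(n_runs):
        rng = np.random.default_rng([seed, i])
        th = rng.normal(0.0, 0.25, size=2)
        params = base.with_offsets(dict(zip(names, th)))
        data, _ = simulate_subject(params, STUDY_FREQS, noise_sd=0.5,
                                   seed=int(rng.integers(2**31 - 1)))
        res = vl_invert(data, CSDForwardModel(base, names, STUDY_FREQS))
        ok = all(res.credible_interval(n, level)[0] <= t <= res.credible_interval(n, level)[1]
                 for n, t in zip(names, th))
        covered += ok
        truths.extend(th)
        means.extend(res.posterior.mean)
    corr = float(np.corrcoef(truths, means)[0, 1])
    return {"n_runs": n_runs, "n_covered": covered, "correlation": corr}


def laminar_swap_study(n_seeds: int = 10, seed: int = 0) -> dict:
    """Synthetic superficial/deep pairs: does the correct channel-to-layer
    designation win the model comparison, and is the evidence antisymmetric
    under relabelling?"""
    model = CSDForwardModel(laminar_template(), ("kappa1", "kappa3", "a14", "a32"),
                            STUDY_FREQS, channel_names=("sup", "deep"))
    n_correct = 0
    dfs = []
    antisym = 0.0
    for i in range(n_seeds):
        rng = np.random.default_rng([seed, i])
        data, _ = simulate_laminar(freqs=STUDY_FREQS, noise_sd=0.5,
                                   seed=int(rng.integers(2**31 - 1)))
        res = layer_assignment_comparison(data, model)
        dfs.append(res.delta_f)
        n_correct += res.delta_f > 3.0
        if i == 0:
            res_sw = layer_assignment_comparison(data.swap_channels(), model)
            antisym = abs(res.delta_f + res_sw.delta_f)
    return {"n_seeds": n_seeds, "n_correct": n_correct,
            "min_delta_f": float(min(dfs)), "mean_delta_f": float(np.mean(dfs)),
            "antisymmetry_error": antisym}


def peb_recovery_study(seed: int = 0, n_subjects: int = 16,
                       effect: float = 0.5, re_sd: float = 0.1) -> dict:
    """One covariate raising two of the ten connection gains across a
    cohort: are exactly those two effects selected by the model-space
    search?"""
    from .mass import GAIN_NAMES

    base = _two_channel_base()
    names = GAIN_NAMES
    rng = np.random.default_rng(seed)
    # winsorized standard-normal phenotype: extreme scores would push the
    # near-critical slow loop past its stability margin
    x = np.clip(rng.normal(size=n_subjects), -1.8, 1.8)
    X = np.column_stack([np.ones(n_subjects), x - x.mean()])
    beta = np.zeros(2 * len(names))
    true_effects = ("a23", "a32")
    for nm in true_effects:
        beta[len(names) + names.index(nm)] = effect
    datasets, _ = simulate_group(n_subjects, X, beta, re_sd, base, names,
                                 STUDY_FREQS, noise_sd=0.5,
                                 seed=int(rng.integers(2**31 - 1)))
    subs = [vl_invert(d, CSDForwardModel(base, names, STUDY_FREQS))
            for d in datasets]
    res = peb_fit(subs, HierarchicalSpec(X, ("mean", "pheno")))
    scored, incl = search_model_space(res)
    true_names = tuple(f"pheno:{n}" for n in true_effects)
    true_incl = [incl[n] for n in true_names]
    null_incl = [v for k, v in incl.items() if k not in true_names]
    return {
        "n_subjects": n_subjects,
        "min_true_inclusion": float(min(true_incl)),
        "median_null_inclusion": float(np.median(null_incl)),
        "max_null_inclusion": float(max(null_incl)),
        "n_models_scored": len(scored),
    }


# ---------------------------------------------------------------------------
# Forward-model validity
# ---------------------------------------------------------------------------

def forward_validity() -> dict:
    """Hermitian/PSD checks, transfer function vs FFT-of-impulse-response
    oracle, and kernel Fourier transform vs quadrature."""
    from scipy.integrate import quad

    params = _two_channel_base()
    freqs = np.arange(4.0, 101.0, 1.0)
    pred = predict_csd_mass(params, freqs)
    herm = float(np.max(np.abs(pred.csd - np.conj(np.swapaxes(pred.csd, 1, 2)))))
    min_eig = float(min(np.linalg.eigvalsh(g.real).min() for g in pred.csd))

    # transfer function vs DFT of the impulse response C e^{Jt} B
    J = jacobian_mass(params)
    B = np.zeros(8)
    B[4:] = params.kappa * params.u_weights
    C = np.zeros((2, 8))
    C[:, :4] = params.Lw
    dt, N = 0.1, 1 << 16
    lam, V = np.linalg.eig(J)
    coef = (C @ V) * np.linalg.solve(V, B)[None, :]
    t = np.arange(N) * dt
    h = np.real(np.exp(np.outer(t, lam)) @ coef.T)
    Tfft = np.fft.rfft(h, axis=0) * dt
    f_bins = np.fft.rfftfreq(N, d=dt / 1000.0)
    keep = (f_bins >= 1.0) & (f_bins <= 100.0)
    Tpred = transfer_mass(params, hz_to_angular(f_bins[keep]))
    transfer_err = float(np.max(np.abs(Tfft[keep] - Tpred) / np.abs(Tpred)))

    # kernel FT vs quadrature on a 20-point (k, omega) grid
    alpha, c, s = 0.8, 0.6, 3.0
    kernel_err = 0.0
    for k in np.linspace(0.0, 2.5, 5):
        for om in np.linspace(0.01, 0.6, 4):
            re, _ = quad(lambda x: alpha * np.exp(-c * x)
                         * (np.cos((om / s + k) * x) + np.cos((om / s - k) * x)),
                         0, np.inf, limit=400)
            im, _ = quad(lambda x: -alpha * np.exp(-c * x)
                         * (np.sin((om / s + k) * x) + np.sin((om / s - k) * x)),
                         0, np.inf, limit=400)
            kernel_err = max(kernel_err,
                             abs(kernel_ft_field(alpha, c, s, k, om) - (re + 1j * im)))

    # field prediction shares the invariants
    fpred = predict_csd_field(FieldModelParams(), freqs[::4])
    herm = max(herm, float(np.max(np.abs(
        fpred.csd - np.conj(np.swapaxes(fpred.csd, 1, 2))))))

    return {
        "max_hermitian_asymmetry": herm,
        "min_real_part_eigenvalue": min_eig,
        "max_transfer_rel_error": transfer_err,
        "max_kernel_ft_error": float(kernel_err),
    }
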
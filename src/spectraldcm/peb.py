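"""Parametric empirical Bayes: hierarchical inference over subjects.

Subject-level parameters are modelled as Gaussian deviations from a group
linear model,

    θ_i = (x_i ⊗ W) β + ε_i,   ε_i ~ N(0, Σ₂(γ)),

with x_i the i-th row of a between-subject design matrix X (constant first
column, mean-centred covariates) and W a within-subject weight matrix
(identity by default).  The key computational device is Bayesian model
reduction: for any candidate empirical prior N((x_i ⊗ W)β, Σ₂) the change in
each subject's evidence follows in closed form from the posterior of its
full inversion, so the second-level free energy F⁽²⁾ can be optimised over
(β, γ) without revisiting the first level.  ΔF_i is exactly quadratic in β,
so given the random-effect log-precision γ the Gaussian posterior over β is
available in one step; γ is then updated by damped Newton ascent on the
(profile) second-level free energy, with rejected steps never lowering the
recorded trajectory.

Model-space search scores on/off combinations of group-effect parameters
with the same reduction machinery (exhaustive up to 16 free effects, greedy
backward pruning beyond that) and reports softmax model posteriors and
per-parameter inclusion probabilities; Bayesian model averaging
moment-matches the mixture of reduced posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from .bmr import reduce_model
from .exceptions import NumericalError, ValidationError
from .types import GaussianDensity, InversionResult, PEBResult, ScoredModel

__all__ = [
    "HierarchicalSpec",
    "PEB",
    "peb_fit",
    "search_model_space",
    "bayesian_model_average",
]

#: switched-off parameters keep this prior variance (numerically safe clamp)
OFF_VARIANCE = 1e-8
#: exhaustive search is used up to this many free group effects
EXHAUSTIVE_LIMIT = 16


# ---------------------------------------------------------------------------
# Hierarchical specification
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalSpec:
    """Second-level design: X (subjects × covariates, constant first column),
    optional within-subject weights W, β prior and random-effect settings.

    Covariate columns (all but the first) are mean-centred so the constant
    encodes the group mean.
    """

    X: np.ndarray
    covariate_names: tuple = None
    W: np.ndarray = None
    beta_prior: GaussianDensity = None
    re_base_precision: float = 16.0
    gamma_prior_var: float = 16.0

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if X.ndim != 2:
            raise ValidationError("X must be a 2-D design matrix")
        if not np.allclose(X[:, 0], X[0, 0]) or X[0, 0] == 0:
            raise ValidationError("first column of X must be a nonzero constant")
        # mean-centre covariates so the constant is the group mean
        if X.shape[1] > 1 and X.shape[0] > 1:
            X = X.copy()
            X[:, 1:] -= X[:, 1:].mean(axis=0)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify collinear columns by rank-increase scan
            bad = []
            cols = [0]
            for j in range(1, X.shape[1]):
                if np.linalg.matrix_rank(X[:, cols + [j]]) == len(cols):
                    bad.append(j)
                else:
                    cols.append(j)
            names = self.covariate_names or tuple(range(X.shape[1]))
            raise ValidationError(
                f"design matrix is rank deficient; collinear columns: "
                f"{[names[j] for j in bad]}"
            )
        if self.covariate_names is None:
            names = ("mean",) + tuple(f"cov{j}" for j in range(1, X.shape[1]))
        else:
            names = tuple(self.covariate_names)
        if len(names) != X.shape[1]:
            raise ValidationError("covariate_names must match columns of X")
        self.X = X
        self.covariate_names = names

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def second_level_names(self, param_names) -> tuple:
        """Names of all second-level parameters: one per (covariate, first-level
        parameter) pair, ordered covariate-major (Kronecker convention)."""
        return tuple(f"{c}:{p}" for c in self.covariate_names for p in param_names)

    def group_effect_names(self, param_names) -> tuple:
        """Second-level parameters describing between-subject effects (all
        covariate columns except the constant)."""
        return tuple(f"{c}:{p}" for c in self.covariate_names[1:] for p in param_names)


# ---------------------------------------------------------------------------
# PEB estimator
# ---------------------------------------------------------------------------

class PEB(BaseEstimator):
    """Parametric-empirical-Bayes group model as an estimator.

    Parameters
    ----------
    spec : HierarchicalSpec
        Between-subject design and second-level priors.
    max_iter, tol_nats : int, float
        Damped-Newton budget and convergence threshold for the random-effect
        log-precision γ.

    Attributes
    ----------
    beta_posterior_ : GaussianDensity over second-level parameters.
    gamma_posterior_ : GaussianDensity over the random-effect log-precision.
    free_energy_ : float
    trajectory_ : ndarray (non-decreasing over accepted iterations)
    subject_empirical_priors_ : list of GaussianDensity
    """

    def __init__(self, spec=None, *, max_iter=32, tol_nats=0.01):
        self.spec = spec
        self.max_iter = max_iter
        self.tol_nats = tol_nats

    # -- internals ----------------------------------------------------------

    def _subject_stats(self, subject_results):
        names = tuple(subject_results[0].posterior.names)
        stats = []
        for res in subject_results:
            if tuple(res.posterior.names) != names or tuple(res.prior.names) != names:
                raise ValidationError("all subjects must share first-level parameter names")
            Pq = res.posterior.precision()
            P0 = res.prior.precision()
            stats.append({
                "Pq": Pq, "P0": P0,
                "muq": res.posterior.mean, "mu0": res.prior.mean,
                "k": Pq @ res.posterior.mean - P0 @ res.prior.mean,
                "quad": (res.posterior.mean @ Pq @ res.posterior.mean
                         - res.prior.mean @ P0 @ res.prior.mean),
                "ld_Pq": np.linalg.slogdet(Pq)[1],
                "ld_P0": np.linalg.slogdet(P0)[1],
            })
        return names, stats

    def _free_energy(self, gamma, stats, M_rows, Pb0, mub0, ld_Sb0):
        """Profile second-level free energy at γ (β handled in closed form)."""
        spec = self.spec
        p1 = stats[0]["Pq"].shape[0]
        Pi2 = np.exp(gamma) * spec.re_base_precision * np.eye(p1)
        ld_Pi2 = np.linalg.slogdet(Pi2)[1]
        pb = Pb0.shape[0]

        A_sum = np.zeros((pb, pb))
        b_sum = np.zeros(pb)
        const = 0.0
        sub_terms = []
        for st, M in zip(stats, M_rows):
            Pstar = st["Pq"] + Pi2 - st["P0"]
            w = np.linalg.eigvalsh(0.5 * (Pstar + Pstar.T))
            if w.min() <= 0:
                raise NumericalError(
                    "subject posterior incompatible with the random-effect prior"
                )
            ld_Pstar = np.linalg.slogdet(Pstar)[1]
            Pstar_inv = np.linalg.inv(Pstar)
            k = st["k"]
            A_i = M.T @ (Pi2 - Pi2 @ Pstar_inv @ Pi2) @ M
            b_i = M.T @ (Pi2 @ (Pstar_inv @ k))
            c_i = (0.5 * (st["ld_Pq"] + ld_Pi2 - st["ld_P0"] - ld_Pstar)
                   - 0.5 * (st["quad"] - k @ Pstar_inv @ k))
            A_sum += A_i
            b_sum += b_i
            const += c_i
            sub_terms.append((A_i, b_i))

        Pb = A_sum + Pb0
        wb = np.linalg.eigvalsh(0.5 * (Pb + Pb.T))
        if wb.min() <= 0:
            raise NumericalError("second-level posterior precision not positive definite")
        Sb = np.linalg.inv(Pb)
        mub = Sb @ (b_sum + Pb0 @ mub0)

        # expected first-level contribution under q(β), plus β prior/entropy
        F = const + b_sum @ mub - 0.5 * mub @ A_sum @ mub - 0.5 * np.trace(Sb @ A_sum)
        db = mub - mub0
        F += -0.5 * db @ Pb0 @ db - 0.5 * ld_Sb0
        F += -0.5 * np.linalg.slogdet(Pb)[1]
        # γ prior (entropy/curvature of γ handled by the caller's Laplace step)
        F += -0.5 * gamma**2 / spec.gamma_prior_var - 0.5 * np.log(spec.gamma_prior_var)
        return float(F), mub, 0.5 * (Sb + Sb.T), Pi2

    # -- sklearn API --------------------------------------------------------

    def fit(self, subject_results, y=None):
        spec = self.spec
        if spec is None:
            raise ValidationError("PEB requires a HierarchicalSpec")
        if len(subject_results) == 0:
            raise ValidationError("no subject results supplied")
        if spec.n_subjects != len(subject_results):
            raise ValidationError(
                f"design has {spec.n_subjects} rows but {len(subject_results)} "
                "subject results were supplied"
            )
        names, stats = self._subject_stats(subject_results)
        p1 = len(names)
        W = np.eye(p1) if spec.W is None else np.asarray(spec.W, dtype=float)
        if W.shape != (p1, p1):
            raise ValidationError("W must be (p, p) for p first-level parameters")
        M_rows = [np.kron(x_i, W) for x_i in spec.X]        # each p1 x (c*p1)

        b_names = spec.second_level_names(names)
        if spec.beta_prior is not None:
            bp = spec.beta_prior
            if tuple(bp.names) != b_names:
                raise ValidationError("beta_prior names do not match the design")
        else:
            # group-mean block inherits the subjects' first-level prior;
            # covariate blocks get the same scale
            cov0 = subject_results[0].prior.cov
            bp = GaussianDensity(
                b_names,
                np.tile(subject_results[0].prior.mean, spec.n_covariates)
                * np.repeat([1.0] + [0.0] * (spec.n_covariates - 1), p1),
                np.kron(np.eye(spec.n_covariates), cov0),
            )
        Pb0 = bp.precision()
        ld_Sb0 = bp.logdet_cov()

        gamma = 0.0
        F_cur, mub, Sb, Pi2 = self._free_energy(gamma, stats, M_rows, Pb0, bp.mean, ld_Sb0)
        traj = [F_cur]
        step = 1.0
        n_small = 0
        eps = 1e-3
        for _ in range(int(self.max_iter)):
            Fp, *_ = self._free_energy(gamma + eps, stats, M_rows, Pb0, bp.mean, ld_Sb0)
            Fm, *_ = self._free_energy(gamma - eps, stats, M_rows, Pb0, bp.mean, ld_Sb0)
            g1 = (Fp - Fm) / (2 * eps)
            h2 = (Fp - 2 * F_cur + Fm) / eps**2
            dg = -g1 / h2 if h2 < -1e-12 else np.sign(g1)
            dg = np.clip(dg, -4.0, 4.0) * step
            accepted = False
            for _ in range(6):
                try:
                    F_new, mub_new, Sb_new, Pi2_new = self._free_energy(
                        gamma + dg, stats, M_rows, Pb0, bp.mean, ld_Sb0)
                except NumericalError:
                    F_new = -np.inf
                if F_new >= F_cur - 1e-12:
                    accepted = True
                    break
                dg /= 2.0
            if not accepted:
                break
            dF = F_new - F_cur
            gamma += dg
            F_cur, mub, Sb, Pi2 = F_new, mub_new, Sb_new, Pi2_new
            traj.append(F_cur)
            n_small = n_small + 1 if abs(dF) < self.tol_nats else 0
            if n_small >= 2:
                break

        # Laplace variance of γ from the numerical curvature of the profile F
        Fp, *_ = self._free_energy(gamma + eps, stats, M_rows, Pb0, bp.mean, ld_Sb0)
        Fm, *_ = self._free_energy(gamma - eps, stats, M_rows, Pb0, bp.mean, ld_Sb0)
        h2 = (Fp - 2 * F_cur + Fm) / eps**2
        var_g = -1.0 / h2 if h2 < -1e-8 else self.spec.gamma_prior_var
        F_cur += 0.5 * np.log(max(var_g, 1e-12))    # γ entropy (Laplace)

        Sigma2 = np.linalg.inv(Pi2)
        self.beta_posterior_ = GaussianDensity(b_names, mub, Sb)
        self.gamma_posterior_ = GaussianDensity(("gamma0",), [gamma], [[var_g]])
        self.beta_prior_ = bp
        self.free_energy_ = float(F_cur)
        self.trajectory_ = np.asarray(traj)
        self.subject_empirical_priors_ = [
            GaussianDensity(names, M @ mub, Sigma2) for M in M_rows
        ]
        self.param_names_ = names
        self.group_effect_names_ = spec.group_effect_names(names)
        return self

    def result(self) -> PEBResult:
        return PEBResult(
            beta_posterior=self.beta_posterior_,
            gamma_posterior=self.gamma_posterior_,
            free_energy=self.free_energy_,
            trajectory=self.trajectory_,
            subject_empirical_priors=self.subject_empirical_priors_,
            beta_prior=self.beta_prior_,
            group_effect_names=self.group_effect_names_,
        )


def peb_fit(subject_results, spec: HierarchicalSpec, **settings) -> PEBResult:
    """Fit the hierarchical (empirical Bayes) model over subject inversions;
    thin functional wrapper over :class:`PEB`."""
    est = PEB(spec=spec, **settings)
    est.fit(list(subject_results))
    return est.result()


# ---------------------------------------------------------------------------
# Model-space search and averaging
# ---------------------------------------------------------------------------

def _reduced_prior_for_mask(beta_prior: GaussianDensity, free_names, mask) -> GaussianDensity:
    """Clamp the free effects NOT in ``mask`` to near-zero-variance priors."""
    reduced = beta_prior
    for name in free_names:
        if name not in mask:
            reduced = reduced.with_variance(name, OFF_VARIANCE, mean=0.0)
    return reduced


def _score_mask(peb: PEBResult, free_names, mask):
    reduced_prior = _reduced_prior_for_mask(peb.beta_prior, free_names, mask)
    post, dF = reduce_model(peb.beta_prior, peb.beta_posterior, reduced_prior)
    return ScoredModel(mask=tuple(mask), free_energy=float(dF), posterior=post)


def search_model_space(peb: PEBResult, candidate_masks=None):
    """Score combinations of second-level group effects by model reduction.

    Without explicit ``candidate_masks``: exhaustive over all on/off
    combinations of the free group effects when there are at most 16 of
    them, otherwise greedy backward pruning down to 16 followed by an
    exhaustive sweep of the survivors.

    Returns
    -------
    scored : list of ScoredModel, with softmax-normalised ``probability``.
    inclusion : dict mapping each free effect to its inclusion probability.
    """
    free = tuple(peb.group_effect_names)
    if candidate_masks is not None:
        masks = [tuple(m) for m in candidate_masks]
        if not masks:
            raise ValidationError("empty model space")
        for m in masks:
            unknown = set(m) - set(peb.beta_posterior.names)
            if unknown:
                raise ValidationError(f"mask names not in the model: {sorted(unknown)}")
        free = tuple(sorted(set().union(*[set(m) for m in masks]) | set(free)))
    else:
        if not free:
            raise ValidationError("empty model space: no group effects to search")
        active = list(free)
        if len(active) > EXHAUSTIVE_LIMIT:
            # greedy backward pruning: repeatedly switch off the effect whose
            # removal costs the least evidence
            while len(active) > EXHAUSTIVE_LIMIT:
                best_name, best_dF = None, -np.inf
                for name in active:
                    mask = tuple(n for n in active if n != name)
                    dF = _score_mask(peb, free, mask).free_energy
                    if dF > best_dF:
                        best_name, best_dF = name, dF
                active.remove(best_name)
        masks = []
        for r in range(len(active) + 1):
            masks.extend(combinations(active, r))

    scored = [_score_mask(peb, free, m) for m in masks]
    fe = np.array([s.free_energy for s in scored])
    prob = np.exp(fe - fe.max())
    prob /= prob.sum()
    for s, p in zip(scored, prob):
        s.probability = float(p)
    inclusion = {
        name: float(sum(s.probability for s in scored if name in s.mask))
        for name in free
    }
    return scored, inclusion


def bayesian_model_average(scored_models) -> GaussianDensity:
    """Moment-matched mixture of reduced posteriors weighted by model
    probability (softmax of free energies if probabilities are unset)."""
    scored = list(scored_models)
    if not scored:
        raise ValidationError("no scored models to average")
    w = np.array([s.probability for s in scored], dtype=float)
    if np.any(~np.isfinite(w)):
        fe = np.array([s.free_energy for s in scored])
        w = np.exp(fe - fe.max())
    w = w / w.sum()
    names = scored[0].posterior.names
    mean = sum(wi * s.posterior.mean for wi, s in zip(w, scored))
    cov = sum(
        wi * (s.posterior.cov + np.outer(s.posterior.mean - mean, s.posterior.mean - mean))
        for wi, s in zip(w, scored)
    )
    return GaussianDensity(names, mean, cov)
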
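"""Core data containers shared across the package.

The containers are deliberately small: a named Gaussian density (used for
priors, posteriors and reduced priors alike), a frequency-resolved complex
cross-spectral array, depth-resolved LFP traces, and result records for
single-subject inversion and group (empirical Bayes) inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "GaussianDensity",
    "SpectralData",
    "SpectralPrediction",
    "DepthLFP",
    "InversionResult",
    "PEBResult",
    "LaminarAssignment",
    "stack_csd",
    "unstack_csd",
    "hermitian_from_upper",
]


# ---------------------------------------------------------------------------
# Gaussian density over named parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianDensity:
    """A multivariate Gaussian over named parameters.

    Parameters
    ----------
    names : tuple of str
        Ordered parameter labels.
    mean : ndarray, shape (p,)
    cov : ndarray, shape (p, p)
        Symmetric positive semidefinite covariance.
    """

    names: tuple
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        names = tuple(self.names)
        mean = np.asarray(self.mean, dtype=float).ravel()
        cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if len(names) != mean.size:
            raise ValidationError(
                f"GaussianDensity: {len(names)} names but mean of size {mean.size}"
            )
        if cov.shape != (mean.size, mean.size):
            raise ValidationError(
                f"GaussianDensity: cov shape {cov.shape} does not match dimension {mean.size}"
            )
        if not np.allclose(cov, cov.T, atol=1e-10 * (1.0 + np.abs(cov).max())):
            raise ValidationError("GaussianDensity: covariance is not symmetric")
        cov = 0.5 * (cov + cov.T)
        # smallest eigenvalue may be ~0 for clamped (reduced) priors
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValidationError("GaussianDensity: covariance is not positive semidefinite")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    # -- constructors -------------------------------------------------------

    @classmethod
    def iid(cls, names: Sequence[str], mean: float | Sequence[float] = 0.0,
            var: float | Sequence[float] = 1.0) -> "GaussianDensity":
        """Independent Gaussian with shared or per-name mean/variance."""
        names = tuple(names)
        p = len(names)
        mean = np.broadcast_to(np.asarray(mean, dtype=float), (p,)).copy()
        var = np.broadcast_to(np.asarray(var, dtype=float), (p,)).copy()
        return cls(names, mean, np.diag(var))

    # -- basic operations ---------------------------------------------------

    @property
    def dim(self) -> int:
        return self.mean.size

    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    def logdet_cov(self) -> float:
        sign, logdet = np.linalg.slogdet(self.cov)
        if sign <= 0:
            raise ValidationError("GaussianDensity: covariance is singular or indefinite")
        return logdet

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"parameter {name!r} not in density") from None

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.mean))

    def with_variance(self, name: str, var: float,
                      mean: float | None = None) -> "GaussianDensity":
        """Return a copy with one marginal clamped to (mean, var), decorrelated."""
        i = self.index_of(name)
        cov = self.cov.copy()
        cov[i, :] = 0.0
        cov[:, i] = 0.0
        cov[i, i] = var
        m = self.mean.copy()
        if mean is not None:
            m[i] = mean
        return GaussianDensity(self.names, m, cov)

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.cov, size=size,
                                       method="cholesky" if _is_pd(self.cov) else "svd")


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


# ---------------------------------------------------------------------------
# Cross-spectral data
# ---------------------------------------------------------------------------

def _validate_csd(freqs, csd, channel_names, require_hermitian=True):
    freqs = np.asarray(freqs, dtype=float).ravel()
    csd = np.asarray(csd, dtype=complex)
    if csd.ndim == 1:
        csd = csd[:, None, None]
    if csd.ndim != 3 or csd.shape[1] != csd.shape[2]:
        raise ValidationError(f"csd must be (n_freq, n_ch, n_ch); got {csd.shape}")
    if csd.shape[0] != freqs.size:
        raise ValidationError("csd first axis must match number of frequencies")
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must be strictly positive (Hz)")
    if np.any(np.diff(freqs) <= 0):
        raise ValidationError("frequencies must be strictly increasing")
    nc = csd.shape[1]
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(nc))
    channel_names = tuple(channel_names)
    if len(channel_names) != nc:
        raise ValidationError("channel_names length must match csd channels")
    if require_hermitian:
        scale = max(np.abs(csd).max(), 1e-300)
        if not np.allclose(csd, np.conj(np.swapaxes(csd, 1, 2)), atol=1e-8 * scale):
            raise ValidationError("csd is not Hermitian at every frequency")
    return freqs, csd, channel_names


@dataclass(frozen=True)
class SpectralData:
    """Complex cross-spectral densities over frequency.

    ``csd[f, l, m]`` is the cross-spectrum between channels *l* and *m* at
    ``freqs[f]`` (Hz).  The array is Hermitian in its channel axes at every
    frequency.
    """

    freqs: np.ndarray
    csd: np.ndarray
    channel_names: tuple = None

    def __post_init__(self):
        freqs, csd, names = _validate_csd(self.freqs, self.csd, self.channel_names)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "csd", csd)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.csd.shape[1]

    @property
    def n_freqs(self) -> int:
        return self.freqs.size

    def auto_spectra(self) -> np.ndarray:
        """Real auto-spectra, shape (n_freq, n_ch)."""
        return np.real(np.einsum("fii->fi", self.csd))

    def vector(self) -> np.ndarray:
        """Stacked real/imaginary parts of the upper triangle (see stack_csd)."""
        return stack_csd(self.csd)

    def swap_channels(self, i: int = 0, j: int = 1) -> "SpectralData":
        """Return a copy with channels *i* and *j* exchanged (data and labels)."""
        perm = list(range(self.n_channels))
        perm[i], perm[j] = perm[j], perm[i]
        csd = self.csd[:, perm][:, :, perm]
        names = tuple(self.channel_names[p] for p in perm)
        return SpectralData(self.freqs.copy(), csd, names)


# forward-model predictions share the container
SpectralPrediction = SpectralData


def stack_csd(csd: np.ndarray) -> np.ndarray:
    """Stack a Hermitian (n_freq, n_ch, n_ch) array into a real vector.

    Ordering: for each frequency, pairs (i, j) with i <= j in row-major order;
    the real part always, followed by the imaginary part for i < j.
    """
    csd = np.asarray(csd, dtype=complex)
    nf, nc, _ = csd.shape
    parts = []
    for i in range(nc):
        for j in range(i, nc):
            parts.append(csd[:, i, j].real)
            if i != j:
                parts.append(csd[:, i, j].imag)
    # interleave per-frequency: build (nf, n_terms) then ravel
    return np.column_stack(parts).ravel()


def unstack_csd(vec: np.ndarray, n_freqs: int, n_channels: int) -> np.ndarray:
    """Inverse of :func:`stack_csd`; returns a Hermitian (nf, nc, nc) array."""
    nc = n_channels
    n_terms = nc + nc * (nc - 1)  # nc real diagonals + 2 per off-diagonal pair
    mat = np.asarray(vec, dtype=float).reshape(n_freqs, n_terms)
    csd = np.zeros((n_freqs, nc, nc), dtype=complex)
    col = 0
    for i in range(nc):
        for j in range(i, nc):
            if i == j:
                csd[:, i, i] = mat[:, col]
                col += 1
            else:
                z = mat[:, col] + 1j * mat[:, col + 1]
                csd[:, i, j] = z
                csd[:, j, i] = np.conj(z)
                col += 2
    return csd


def hermitian_from_upper(csd: np.ndarray) -> np.ndarray:
    """Symmetrise: rebuild the lower triangle by conjugation, realify diagonals."""
    csd = np.array(csd, dtype=complex, copy=True)
    nc = csd.shape[1]
    for i in range(nc):
        csd[:, i, i] = csd[:, i, i].real
        for j in range(i + 1, nc):
            csd[:, j, i] = np.conj(csd[:, i, j])
    return csd


# ---------------------------------------------------------------------------
# Depth-resolved LFP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthLFP:
    """Laminar-probe LFP: contacts ordered superficial to deep.

    ``v[c, t]`` is the potential (mV) at contact *c* and time ``times[t]`` (ms);
    ``depths`` are contact positions in µm and must be (near-)equally spaced.
    """

    times: np.ndarray
    depths: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float).ravel()
        depths = np.asarray(self.depths, dtype=float).ravel()
        v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if depths.size < 3:
            raise ValidationError("DepthLFP requires at least 3 contacts")
        dz = np.diff(depths)
        if np.any(dz <= 0):
            raise ValidationError("contact depths must be strictly increasing")
        if (dz.max() - dz.min()) > 0.01 * dz.mean():
            raise ValidationError("contact spacing must be uniform within 1%")
        if v.shape != (depths.size, times.size):
            raise ValidationError(
                f"v must be (n_contacts, n_times) = {(depths.size, times.size)}; got {v.shape}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "v", v)

    @property
    def spacing(self) -> float:
        """Contact spacing in µm."""
        return float(np.diff(self.depths).mean())


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass
class InversionResult:
    """Output of a variational-Laplace model inversion.

    ``trajectory`` holds the free energy after every accepted iteration and is
    non-decreasing by construction of the ascent.
    """

    posterior: GaussianDensity
    hyper_posterior: GaussianDensity
    free_energy: float
    trajectory: np.ndarray
    prediction: SpectralPrediction | None
    prior: GaussianDensity
    n_data: int

    def __post_init__(self):
        self.trajectory = np.asarray(self.trajectory, dtype=float).ravel()
        if self.trajectory.size and np.any(np.diff(self.trajectory) < -1e-9):
            raise ValidationError("free-energy trajectory must be non-decreasing")

    def credible_interval(self, name: str, level: float = 0.90) -> tuple:
        """Central credible interval for one parameter."""
        from scipy.stats import norm

        i = self.posterior.index_of(name)
        m = self.posterior.mean[i]
        sd = np.sqrt(self.posterior.cov[i, i])
        z = norm.ppf(0.5 + level / 2.0)
        return (m - z * sd, m + z * sd)


@dataclass
class ScoredModel:
    """One reduced model scored during a model-space search."""

    mask: tuple               # names of second-level parameters switched ON
    free_energy: float
    posterior: GaussianDensity
    probability: float = np.nan


@dataclass
class PEBResult:
    """Output of parametric-empirical-Bayes group inference."""

    beta_posterior: GaussianDensity
    gamma_posterior: GaussianDensity
    free_energy: float
    trajectory: np.ndarray
    subject_empirical_priors: list
    beta_prior: GaussianDensity
    group_effect_names: tuple
    scored_models: list = field(default_factory=list)

    def __post_init__(self):
        self.trajectory = np.asarray(self.trajectory, dtype=float).ravel()


@dataclass
class LaminarAssignment:
    """Superficial/deep layer designation by Bayesian model comparison.

    ``delta_f`` is the log-evidence (free-energy) difference of the candidate
    channel-to-layer mappings: positive values favour ``channel_to_layer``.
    """

    channel_to_layer: dict
    free_energies: dict
    delta_f: float
    results: dict | None = None
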
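"""Neural-field forward model on a bounded cortical patch.

The field variant replaces the point-source connection gains of the mass
model with distance-dependent connectivity kernels α exp(−c|x|) conducted at
finite speed s.  Working in the spatial-frequency domain, each retained
cosine mode k contributes an independently linearised system whose effective
coupling is the kernel's Fourier transform

    K̂(k, ω) = 2 α (c + iω/s) / ((c + iω/s)² + k²)

normalised so that K̂(0, 0) recovers the point-source gain α.  A Gaussian
lead field L(k, φ) = exp(−φ² k² / 2) and population weights Q map the modal
responses to the (single, by default) observed channel, and the predicted
cross-spectrum sums the per-mode contributions.

Units: spatial decays c in mm⁻¹, wavenumbers k in mm⁻¹, conduction speed s
in m/s (= mm/ms), lead-field dispersion φ in mm; temporal frequencies are
rad/ms as in :mod:`.mass`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .exceptions import StabilityError, ValidationError
from .mass import hz_to_angular, one_over_f_spectrum, sigmoid_deriv
from .types import SpectralPrediction

__all__ = [
    "KERNEL_NAMES",
    "FieldModelParams",
    "kernel_ft_field",
    "transfer_field",
    "predict_csd_field",
]

#: Named intrinsic connectivity kernels, α_qp = "to q from p".
KERNEL_NAMES = ("a11", "a14", "a12", "a22", "a21", "a23", "a33", "a41", "a32", "a44")

# Kernel amplitudes (a.u.): printed values are amplitudes x 10^3.
_DEFAULT_ALPHA = {
    "a11": 0.108, "a14": 0.045, "a12": 0.00189,
    "a22": 0.162, "a21": 0.018, "a23": 0.045, "a33": 0.036,
    "a41": 0.018, "a32": 0.009, "a44": 0.018,
}

# Connection signs: population 2 carries no dipole (inhibitory), so its
# efferents (a12, a32) are negative; self-connections are inhibitory
# (recurrent gain control); remaining cross-connections are excitatory.
# The sign matrix is configuration-supplied; this is the documented default.
_DEFAULT_SIGNS = {
    "a11": -1, "a14": +1, "a12": -1,
    "a22": -1, "a21": +1, "a23": +1, "a33": -1,
    "a41": +1, "a32": -1, "a44": -1,
}


@dataclass(frozen=True)
class FieldModelParams:
    """Parameters of the four-population neural-field model (single source).

    Defaults follow the canonical-microcircuit field model: rate constants
    (1/2, 1/35, 1/35, 1/2) ms⁻¹, kernel decays 0.6 mm⁻¹ off-diagonal and
    2 mm⁻¹ on-diagonal, conduction speed 3 m/s, lead-field dispersion
    √2/16 mm and population dipole weights (0.2, 0, 0.2, 0.6).
    """

    kappa: np.ndarray = (0.5, 1.0 / 35.0, 1.0 / 35.0, 0.5)    # ms^-1
    alpha: Mapping[str, float] = None                          # kernel amplitudes
    signs: Mapping[str, int] = None                            # connection signs
    c_offdiag: float = 0.6                                     # mm^-1
    c_diag: float = 2.0                                        # mm^-1
    s: float = 3.0                                             # m/s == mm/ms
    r: float = 0.54                                            # mV^-1
    eta: float = 0.0                                           # mV
    phi: float = np.sqrt(2.0) / 16.0                           # mm
    q: np.ndarray = (0.2, 0.0, 0.2, 0.6)                       # dipole weights
    u_weights: np.ndarray = (1.0, 0.0, 0.0, 0.0)
    alpha_u: float = 0.0
    beta_u: float = 0.0
    alpha_n: float = -4.0
    beta_n: float = -4.0
    patch_length: float = 10.0                                 # mm
    n_modes: int = 32

    def __post_init__(self):
        kappa = np.asarray(self.kappa, dtype=float).ravel()
        if kappa.shape != (4,) or np.any(kappa <= 0):
            raise ValidationError("kappa must be 4 positive rate constants")
        alpha = dict(_DEFAULT_ALPHA if self.alpha is None else self.alpha)
        unknown = set(alpha) - set(KERNEL_NAMES)
        if unknown:
            raise ValidationError(f"unknown kernel amplitudes: {sorted(unknown)}")
        for name in KERNEL_NAMES:
            alpha.setdefault(name, _DEFAULT_ALPHA[name])
            if alpha[name] < 0:
                raise ValidationError(f"kernel amplitude {name} must be non-negative")
        signs = dict(_DEFAULT_SIGNS if self.signs is None else self.signs)
        if set(signs) != set(KERNEL_NAMES) or any(s not in (-1, 1) for s in signs.values()):
            raise ValidationError("signs must map every kernel name to +1 or -1")
        if self.c_offdiag <= 0 or self.c_diag <= 0:
            raise ValidationError("kernel decays c must be positive")
        if self.s <= 0:
            raise ValidationError("conduction speed s must be positive")
        if self.r <= 0:
            raise ValidationError("sigmoid slope r must be positive")
        if self.n_modes < 1:
            raise ValidationError("n_modes must be >= 1")
        if self.patch_length <= 0:
            raise ValidationError("patch_length must be positive")
        q = np.asarray(self.q, dtype=float).ravel()
        if q.shape != (4,) or not np.all(np.isfinite(q)):
            raise ValidationError("q must be 4 finite population weights")
        u_w = np.asarray(self.u_weights, dtype=float).ravel()
        if u_w.shape != (4,):
            raise ValidationError("u_weights must have 4 entries")
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "signs", signs)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "u_weights", u_w)

    # -- derived ------------------------------------------------------------

    def decay(self, name: str) -> float:
        """Spatial decay c_qp for a named kernel (on- vs off-diagonal)."""
        return self.c_diag if name[1] == name[2] else self.c_offdiag

    def wavenumbers(self) -> np.ndarray:
        """Retained cosine-mode wavenumbers k_j = jπ/patch_length, j=0..n_modes-1."""
        return np.arange(self.n_modes) * np.pi / self.patch_length

    def with_offsets(self, offsets: Mapping[str, float]) -> "FieldModelParams":
        """Log-scale offsets: multiplicative for kappa/alpha/s/phi, additive for
        the log-stored spectral amplitudes."""
        kappa = self.kappa.copy()
        alpha = dict(self.alpha)
        updates = {}
        for name, dv in offsets.items():
            if name in KERNEL_NAMES:
                alpha[name] = alpha[name] * float(np.exp(dv))
            elif name.startswith("kappa") and name[5:] in "1234" and len(name) == 6:
                kappa[int(name[5]) - 1] *= float(np.exp(dv))
            elif name in ("alpha_u", "beta_u", "alpha_n", "beta_n"):
                updates[name] = getattr(self, name) + float(dv)
            elif name in ("s", "phi"):
                updates[name] = getattr(self, name) * float(np.exp(dv))
            else:
                raise ValidationError(f"unknown parameter name {name!r}")
        return replace(self, kappa=kappa, alpha=alpha, **updates)


# ---------------------------------------------------------------------------
# Kernel Fourier transform
# ---------------------------------------------------------------------------

def kernel_ft_field(alpha: float, c: float, s: float, k, omega):
    """Fourier transform of the delayed exponential kernel.

    ∫ α exp(−c|x|) exp(−iω|x|/s) exp(−ikx) dx = 2α(c + iω/s) / ((c + iω/s)² + k²).

    ``c`` in mm⁻¹, ``s`` in mm/ms, ``k`` in mm⁻¹, ``omega`` in rad/ms.
    """
    if c <= 0 or s <= 0:
        raise ValidationError("kernel_ft_field requires c > 0 and s > 0")
    k = np.asarray(k, dtype=float)
    gamma = c + 1j * np.asarray(omega, dtype=float) / s
    out = 2.0 * alpha * gamma / (gamma**2 + k**2)
    return out if np.ndim(out) else complex(out)


def _modal_gain_matrix(params: FieldModelParams, k: float, omega: float) -> np.ndarray:
    """Signed effective 4x4 gain matrix at wavenumber k and frequency omega.

    Each kernel's point-source gain α_qp is modulated by the normalised
    kernel transform K̂(k,ω)/K̂(0,0), so k = 0, ω = 0 recovers α_qp.
    """
    G = np.zeros((4, 4), dtype=complex)
    for name in KERNEL_NAMES:
        qi, pi = int(name[1]) - 1, int(name[2]) - 1
        a = params.alpha[name]
        if a == 0.0:
            continue
        c = params.decay(name)
        norm = kernel_ft_field(a, c, params.s, k, omega) / (2.0 * a / c)
        G[qi, pi] += params.signs[name] * a * norm
    return G


def _modal_jacobian(params: FieldModelParams, k: float, omega: float) -> np.ndarray:
    """8x8 (complex) Jacobian of the mode-k linearisation at the origin."""
    sd = sigmoid_deriv(0.0, params.r, params.eta)
    S = _modal_gain_matrix(params, k, omega) * sd
    kap = params.kappa
    J = np.zeros((8, 8), dtype=complex)
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = kap[:, None] * S - np.diag(kap**2)
    J[4:, 4:] = -2.0 * np.diag(kap)
    return J


def transfer_field(params: FieldModelParams, k: float, omega,
                   check_stability: bool = True) -> np.ndarray:
    """Per-mode transfer function T(k, ω) = L(k, φ) Q (iωI − J(k))⁻¹ B.

    Returns a complex array (n_omega, n_channels); one channel by default.
    Stability is checked on the delay-free (ω = 0) modal linearisation.
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if check_stability:
        J0 = _modal_jacobian(params, k, 0.0).real
        lam = np.linalg.eigvals(J0)
        if np.max(lam.real) >= 0:
            raise StabilityError(
                f"field model unstable at wavenumber k={k:.4g} mm^-1 "
                f"(max Re eigenvalue {np.max(lam.real):.3g} >= 0)"
            )
    B = np.zeros(8)
    B[4:] = params.kappa * params.u_weights
    lead = np.exp(-0.5 * params.phi**2 * k**2)
    C = np.zeros((1, 8))
    C[0, :4] = lead * params.q
    out = np.empty((omega.size, 1), dtype=complex)
    for i, w in enumerate(omega):
        A = 1j * w * np.eye(8) - _modal_jacobian(params, k, w)
        out[i] = C @ np.linalg.solve(A, B)
    return out


def predict_csd_field(params: FieldModelParams, freqs, channel_names=None) -> SpectralPrediction:
    """Predicted cross-spectral density of the field model on a Hz grid.

    ĝ_lm(ω) = Σ_k T_l(k,ω) g_u(ω) T_m(k,ω)† + g_n(ω) over the retained
    cosine modes.
    """
    freqs = np.asarray(freqs, dtype=float).ravel()
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must be positive (Hz)")
    omega = hz_to_angular(freqs)
    gu = one_over_f_spectrum(params.alpha_u, params.beta_u, omega)
    gn = one_over_f_spectrum(params.alpha_n, params.beta_n, omega)
    nc = 1
    csd = np.zeros((freqs.size, nc, nc), dtype=complex)
    for k in params.wavenumbers():
        T = transfer_field(params, k, omega)                 # (nf, 1)
        csd += gu[:, None, None] * (T[:, :, None] * np.conj(T[:, None, :]))
    csd = csd + gn[:, None, None]
    csd = 0.5 * (csd + np.conj(np.swapaxes(csd, 1, 2)))
    return SpectralPrediction(freqs, csd, channel_names)
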
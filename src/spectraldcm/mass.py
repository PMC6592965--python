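"""Neural-mass forward model of coupled neuronal populations.

Four populations (two fast, two slow, by their postsynaptic rate constants)
interact through sigmoid firing-rate coupling.  Each population's mean
depolarization v_q obeys second-order (synaptic convolution) dynamics

    v̈_q = κ_q f_q(v, U) − 2 κ_q v̇_q − κ_q² v_q

where f_q mixes the presynaptic firing rates σ(v_p) through signed connection
gains a_qp, and exogenous input U enters the populations selected by
``u_weights``.  The firing-rate sigmoid is centred so σ(0) = 0, which makes
the origin a fixed point for U = 0 and permits exact linearisation there.

Predicted cross-spectra follow from the linearised transfer function
T(ω) = C (iωI − J)⁻¹ B driven by a white-plus-pink input spectrum, with a
white-plus-pink channel-noise floor added to every cross-spectral element.

Units: rate constants κ are stored in ms⁻¹ and dynamics are evaluated on a
millisecond time axis, so angular frequencies are rad/ms internally
(ω = 2π f / 1000 for f in Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.special import expit

from .exceptions import ConvergenceError, NumericalError, StabilityError, ValidationError
from .types import SpectralPrediction

__all__ = [
    "GAIN_NAMES",
    "MassModelParams",
    "sigmoid",
    "sigmoid_deriv",
    "drift_mass",
    "fixed_point",
    "jacobian_mass",
    "transfer_mass",
    "one_over_f_spectrum",
    "predict_csd_mass",
    "hz_to_angular",
]

#: Named connection gains of the four-population circuit, a_qp = "to q from p".
GAIN_NAMES = ("a11", "a14", "a23", "a22", "a32", "a31", "a33", "a34", "a41", "a44")

_DEFAULT_GAINS = {
    # fast pair (populations 1 and 4): negative feedback loop resonating in
    # the gamma band for kappa = 1/2 ms^-1
    "a11": 0.5, "a14": 2.0, "a41": 1.8, "a44": 0.2,
    # slow pair (populations 2 and 3): low-frequency resonance for
    # kappa = 1/35 ms^-1, kept inside its stability margin
    "a23": 0.3, "a22": 0.5, "a32": 0.25, "a33": 0.5,
    # cross-couplings from the fast pair into population 3
    "a31": 0.3, "a34": 0.6,
}


def hz_to_angular(freqs_hz) -> np.ndarray:
    """Convert frequencies in Hz to angular frequency in rad/ms."""
    return 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / 1000.0


@dataclass(frozen=True)
class MassModelParams:
    """Parameters of the four-population neural-mass model.

    Positive quantities (rate constants, connection gains, observation
    weights) are adjusted multiplicatively via :meth:`with_offsets`, i.e. they
    are treated as log-scalings of these base values, so Gaussian priors on
    the offsets act multiplicatively and positivity is automatic.  The
    input/noise spectral amplitudes ``alpha_u``/``beta_u``/``alpha_n``/
    ``beta_n`` are stored on the log scale directly.
    """

    kappa: np.ndarray = (0.5, 1.0 / 35.0, 1.0 / 35.0, 0.5)   # ms^-1
    a: Mapping[str, float] = None                             # connection gains
    r: float = 0.54                                           # sigmoid slope, mV^-1
    eta: float = 0.0                                          # sigmoid inflection, mV
    Lw: np.ndarray = ((1.0, 0.0, 0.0, 0.0),)                  # channels x 4, a.u.
    u_weights: np.ndarray = (1.0, 0.0, 0.0, 0.0)              # input routing
    alpha_u: float = 0.0                                      # log white input
    beta_u: float = 0.0                                       # log pink input
    alpha_n: float = -4.0                                     # log white channel noise
    beta_n: float = -4.0                                      # log pink channel noise

    def __post_init__(self):
        kappa = np.asarray(self.kappa, dtype=float).ravel()
        if kappa.shape != (4,):
            raise ValidationError("kappa must have 4 entries")
        if np.any(kappa <= 0):
            raise ValidationError("rate constants kappa must be strictly positive")
        a = dict(_DEFAULT_GAINS if self.a is None else self.a)
        unknown = set(a) - set(GAIN_NAMES)
        if unknown:
            raise ValidationError(f"unknown connection gains: {sorted(unknown)}")
        for name in GAIN_NAMES:
            a.setdefault(name, _DEFAULT_GAINS[name])
            if a[name] < 0:
                raise ValidationError(f"connection gain {name} must be non-negative")
        if self.r <= 0:
            raise ValidationError("sigmoid slope r must be positive")
        Lw = np.atleast_2d(np.asarray(self.Lw, dtype=float))
        if Lw.shape[1] != 4:
            raise ValidationError("Lw must have 4 columns (one per population)")
        u_w = np.asarray(self.u_weights, dtype=float).ravel()
        if u_w.shape != (4,):
            raise ValidationError("u_weights must have 4 entries")
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "Lw", Lw)
        object.__setattr__(self, "u_weights", u_w)

    # -- derived ------------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.Lw.shape[0]

    def gain_matrix(self) -> np.ndarray:
        """Signed 4x4 matrix G with f = G @ sigma(v) + u_weights * U."""
        a = self.a
        return np.array([
            [-a["a11"], 0.0,        0.0,        a["a14"]],
            [0.0,       -a["a22"],  a["a23"],   0.0],
            [-a["a31"], -a["a32"],  -a["a33"],  a["a34"]],
            [-a["a41"], 0.0,        0.0,        -a["a44"]],
        ])

    # -- log-scaling interface ----------------------------------------------

    def with_offsets(self, offsets: Mapping[str, float]) -> "MassModelParams":
        """Apply named log-scale offsets and return new parameters.

        Multiplicative (via exp) for ``kappa1..kappa4``, the ten connection
        gains, ``lw`` (whole observation matrix) and ``r``; additive for the
        log-stored spectral amplitudes ``alpha_u``/``beta_u``/``alpha_n``/
        ``beta_n`` and for ``eta``.
        """
        kappa = self.kappa.copy()
        a = dict(self.a)
        Lw = self.Lw.copy()
        updates = {}
        for name, dv in offsets.items():
            if name in GAIN_NAMES:
                a[name] = a[name] * float(np.exp(dv))
            elif name.startswith("kappa") and name[5:] in "1234" and len(name) == 6:
                kappa[int(name[5]) - 1] *= float(np.exp(dv))
            elif name in ("alpha_u", "beta_u", "alpha_n", "beta_n", "eta"):
                updates[name] = getattr(self, name) + float(dv)
            elif name == "lw":
                Lw = Lw * float(np.exp(dv))
            elif name == "r":
                updates["r"] = self.r * float(np.exp(dv))
            else:
                raise ValidationError(f"unknown parameter name {name!r}")
        return replace(self, kappa=kappa, a=a, Lw=Lw, **updates)


# ---------------------------------------------------------------------------
# Firing-rate sigmoid
# ---------------------------------------------------------------------------

def sigmoid(v, r: float = 0.54, eta: float = 0.0):
    """Centred logistic firing rate: 1/(1+e^{−r(v−η)}) − 1/(1+e^{rη}).

    The subtraction makes σ(0) = 0 so the origin is a fixed point of the
    unforced dynamics; σ is strictly increasing and saturates without
    overflow.
    """
    if r <= 0:
        raise ValidationError("sigmoid slope r must be positive")
    v = np.asarray(v, dtype=float)
    out = expit(r * (v - eta)) - expit(-r * eta)
    return out if out.ndim else float(out)


def sigmoid_deriv(v, r: float = 0.54, eta: float = 0.0):
    """Derivative dσ/dv = r s(1−s) with s the uncentred logistic."""
    s = expit(r * (np.asarray(v, dtype=float) - eta))
    out = r * s * (1.0 - s)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def drift_mass(state, params: MassModelParams, U: float = 0.0) -> np.ndarray:
    """Time derivative of the 8-dim state (v_1..v_4, v̇_1..v̇_4), per ms."""
    state = np.asarray(state, dtype=float).ravel()
    if state.shape != (8,):
        raise ValidationError("state must be an 8-vector (v, v̇ per population)")
    if not np.all(np.isfinite(state)):
        raise NumericalError("non-finite state: numerical blow-up in mass-model dynamics")
    v, w = state[:4], state[4:]
    sig = sigmoid(v, params.r, params.eta)
    f = params.gain_matrix() @ sig + params.u_weights * U
    k = params.kappa
    return np.concatenate([w, k * f - 2.0 * k * w - k**2 * v])


def fixed_point(params: MassModelParams, U0: float = 0.0,
                max_iter: int = 100, tol: float = 1e-12) -> np.ndarray:
    """Equilibrium depolarizations v* with drift((v*, 0), U0) = 0.

    Newton iteration from the origin on h(v) = f(v, U0) − κ v.
    """
    v = np.zeros(4)
    G = params.gain_matrix()
    k = params.kappa
    for _ in range(max_iter):
        sig = sigmoid(v, params.r, params.eta)
        h = G @ sig - k * v + params.u_weights * U0
        if not np.all(np.isfinite(h)):
            q = int(np.argmax(~np.isfinite(h))) + 1
            raise ConvergenceError(f"fixed-point search diverged for population {q}")
        if np.max(np.abs(h)) < tol:
            return v
        Jh = G * sigmoid_deriv(v, params.r, params.eta)[None, :] - np.diag(k)
        try:
            step = np.linalg.solve(Jh, -h)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular Jacobian in fixed-point search") from exc
        v = v + step
        if np.max(np.abs(v)) > 1e6:
            q = int(np.argmax(np.abs(v))) + 1
            raise ConvergenceError(f"fixed-point search diverged for population {q}")
    q = int(np.argmax(np.abs(h))) + 1
    raise ConvergenceError(
        f"fixed-point iteration did not converge (largest residual in population {q})"
    )


def jacobian_mass(params: MassModelParams, vstar=None) -> np.ndarray:
    """8x8 Jacobian of drift_mass at the fixed point ``vstar`` (default origin).

    Block structure [[0, I], [κ∘(∂f/∂v) − κ²I, −2κI]].
    """
    vstar = np.zeros(4) if vstar is None else np.asarray(vstar, dtype=float).ravel()
    S = params.gain_matrix() * sigmoid_deriv(vstar, params.r, params.eta)[None, :]
    k = params.kappa
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = k[:, None] * S - np.diag(k**2)
    J[4:, 4:] = -2.0 * np.diag(k)
    return J


def _check_stable(J: np.ndarray, what: str = "mass model") -> None:
    lam = np.linalg.eigvals(J)
    if np.max(lam.real) >= 0:
        raise StabilityError(
            f"{what}: linearised system is unstable (max Re eigenvalue "
            f"{np.max(lam.real):.3g} >= 0); consider shrinking connection gains "
            f"or tightening their priors"
        )


def transfer_mass(params: MassModelParams, omega, vstar=None,
                  check_stability: bool = True) -> np.ndarray:
    """Input-to-channel transfer function T(ω) = C (iωI − J)⁻¹ B.

    ``omega`` is angular frequency in rad/ms (scalar or vector).  B injects
    the exogenous input into the v̇ equations scaled by κ (routed by
    ``u_weights``); C reads the population depolarizations through the
    observation weights Lw.  Returns a complex array (n_omega, n_channels).
    """
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    if vstar is None:
        vstar = fixed_point(params, 0.0)
    J = jacobian_mass(params, vstar)
    if check_stability:
        _check_stable(J)
    B = np.zeros(8)
    B[4:] = params.kappa * params.u_weights
    C = np.zeros((params.n_channels, 8))
    C[:, :4] = params.Lw
    A = 1j * omega[:, None, None] * np.eye(8)[None] - J[None]
    X = np.linalg.solve(A, np.broadcast_to(B, (omega.size, 8))[..., None])[..., 0]
    return X @ C.T


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def one_over_f_spectrum(alpha: float, beta: float, omega):
    """White-plus-pink spectral density exp(α) + exp(β)/ω (log-scale storage).

    ``omega`` is angular frequency (rad/ms internally) and must be positive.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValidationError("one_over_f_spectrum requires omega > 0")
    out = np.exp(alpha) + np.exp(beta) / omega
    return out if out.ndim else float(out)


def predict_csd_mass(params: MassModelParams, freqs, channel_names=None) -> SpectralPrediction:
    """Predicted cross-spectral density of the mass model on a Hz grid.

    g_lm(ω) = T_l(ω) g_u(ω) T_m(ω)* + g_n(ω), with the channel-noise term
    g_n added to every element.  The result is Hermitian with real
    auto-spectra bounded below by the noise floor.
    """
    freqs = np.asarray(freqs, dtype=float).ravel()
    if np.any(freqs <= 0):
        raise ValidationError("frequencies must be positive (Hz)")
    omega = hz_to_angular(freqs)
    T = transfer_mass(params, omega)                         # (nf, nc)
    gu = one_over_f_spectrum(params.alpha_u, params.beta_u, omega)
    gn = one_over_f_spectrum(params.alpha_n, params.beta_n, omega)
    csd = gu[:, None, None] * (T[:, :, None] * np.conj(T[:, None, :]))
    csd = csd + gn[:, None, None]
    # exact Hermitian symmetry (construction guarantees it up to rounding)
    csd = 0.5 * (csd + np.conj(np.swapaxes(csd, 1, 2)))
    return SpectralPrediction(freqs, csd, channel_names)
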
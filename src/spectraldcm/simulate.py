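"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: single-subject
cross-spectra (forward prediction plus complex Gaussian observation noise),
multi-subject cohorts whose first-level parameters follow a second-level
linear model with Gaussian random effects, two-channel laminar spectra with
spectrally distinct superficial (gamma) and deep (low-frequency) layers, and
depth-resolved LFP profiles carrying an injected current sink.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import StabilityError, ValidationError
from .field import FieldModelParams, predict_csd_field
from .mass import MassModelParams, predict_csd_mass
from .types import DepthLFP, GaussianDensity, SpectralData, unstack_csd

__all__ = [
    "GroundTruth",
    "DEFAULT_FREQS",
    "default_freqs",
    "simulate_subject",
    "simulate_group",
    "laminar_template",
    "simulate_laminar",
    "simulate_depth_lfp",
]

#: default frequency grid: 4–100 Hz at 1 Hz, covering the gamma band with margin
DEFAULT_FREQS = np.arange(4.0, 101.0, 1.0)

#: default cohort size for group simulations
DEFAULT_N_SUBJECTS = 16

#: default between-subject random-effect SD on the log-scaled parameters
DEFAULT_RE_SD = 0.1


def default_freqs() -> np.ndarray:
    return DEFAULT_FREQS.copy()


@dataclass
class GroundTruth:
    """What the generator actually used: per-subject parameters (log-scale
    offsets), second-level effects, random-effect SD and the seed."""

    subject_params: list
    beta: np.ndarray | None
    re_sd: float
    seed: int


def _predict(params, freqs, channel_names=None):
    if isinstance(params, MassModelParams):
        return predict_csd_mass(params, freqs, channel_names)
    if isinstance(params, FieldModelParams):
        return predict_csd_field(params, freqs, channel_names)
    raise ValidationError("params must be MassModelParams or FieldModelParams")


def simulate_subject(params, freqs=None, noise_sd: float = 0.5, seed: int = 0,
                     channel_names=None):
    """Cross-spectra from a forward model plus i.i.d. Gaussian noise.

    Noise of SD ``noise_sd`` is added to the stacked real/imaginary parts of
    the upper-triangular cross-spectra and Hermitian symmetry is restored by
    construction; ``noise_sd = 0`` returns the prediction exactly.
    """
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float).ravel()
    pred = _predict(params, freqs, channel_names)
    vec = pred.vector()
    rng = np.random.default_rng(seed)
    noisy = vec + rng.normal(0.0, noise_sd, size=vec.size) if noise_sd > 0 else vec
    csd = unstack_csd(noisy, pred.n_freqs, pred.n_channels)
    data = SpectralData(freqs, csd, pred.channel_names)
    truth = GroundTruth(subject_params=[params], beta=None, re_sd=0.0, seed=seed)
    return data, truth


def simulate_group(n_subjects: int = DEFAULT_N_SUBJECTS, X=None, beta=None,
                   re_sd: float = DEFAULT_RE_SD, base_params=None,
                   param_names=None, freqs=None, noise_sd: float = 0.5,
                   seed: int = 0):
    """Multi-subject cohort with second-level structure on the parameters.

    Each subject's log-scale parameter offsets are drawn as

        θ_i = (x_i ⊗ I) β + ε_i,   ε_i ~ N(0, re_sd² I),

    over the named first-level parameters, then passed through
    :func:`simulate_subject`.  ``beta`` is ordered covariate-major to match
    the Kronecker convention of the PEB layer.  Unstable draws are resampled
    up to 10 times before raising.
    """
    if base_params is None:
        base_params = MassModelParams()
    if param_names is None:
        raise ValidationError("param_names (first-level parameter names) are required")
    param_names = tuple(param_names)
    p = len(param_names)
    X = np.ones((n_subjects, 1)) if X is None else np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n_subjects:
        raise ValidationError("rows of X must equal n_subjects")
    beta = np.zeros(X.shape[1] * p) if beta is None else np.asarray(beta, dtype=float).ravel()
    if beta.size != X.shape[1] * p:
        raise ValidationError("beta must have cols(X) * len(param_names) entries")
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float).ravel()

    rng = np.random.default_rng(seed)
    datasets, offsets = [], []
    for i in range(n_subjects):
        mean_i = np.kron(X[i], np.eye(p)) @ beta
        for attempt in range(10):
            theta_i = mean_i + (rng.normal(0.0, re_sd, size=p) if re_sd > 0 else 0.0)
            params_i = base_params.with_offsets(dict(zip(param_names, theta_i)))
            try:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                data_i, _ = simulate_subject(params_i, freqs, noise_sd, seed=sub_seed)
                break
            except StabilityError:
                if attempt == 9:
                    raise
        datasets.append(data_i)
        offsets.append(theta_i)
    truth = GroundTruth(subject_params=offsets, beta=beta, re_sd=re_sd, seed=seed)
    return datasets, truth


# ---------------------------------------------------------------------------
# Laminar two-channel generator
# ---------------------------------------------------------------------------

#: superficial (fast) motif defaults: gamma-band resonance
DEFAULT_SUP = {"kappa_e": 0.35, "kappa_i": 0.35, "g_ei": 2.8, "g_ie": 2.5,
               "g_ee": 0.5, "g_ii": 0.2}
#: deep (slow) motif defaults: low-frequency response
DEFAULT_DEEP = {"kappa_e": 1.0 / 35.0, "kappa_i": 1.0 / 35.0, "g_ei": 0.3,
                "g_ie": 0.3, "g_ee": 0.5, "g_ii": 0.5}

_MOTIF_KEYS = ("kappa_e", "kappa_i", "g_ei", "g_ie", "g_ee", "g_ii")


def laminar_template(sup_params=None, deep_params=None, cross_gain: float = 1.0,
                     alpha_u: float = 0.0, beta_u: float = -4.0,
                     alpha_n: float = -4.0, beta_n: float = -4.0) -> MassModelParams:
    """Two-channel mass model: superficial channel reads the fast principal
    population (1), deep channel the slow principal population (3).

    Each layer is a mirrored principal/interneuron motif — populations (1, 4)
    superficial and (3, 2) deep — parameterised by its principal and
    interneuron rate constants and four gains.  Exogenous input drives both
    principal populations, so the channels share input even with the
    superficial→deep cross-connections (scaled by ``cross_gain``) removed;
    with ``sup_params == deep_params`` and ``cross_gain = 0`` the two
    subsystems are exact mirrors and the auto-spectra coincide.
    """
    sup = {**DEFAULT_SUP, **(sup_params or {})}
    deep = {**DEFAULT_DEEP, **(deep_params or {})}
    for d, label in ((sup, "sup_params"), (deep, "deep_params")):
        unknown = set(d) - set(_MOTIF_KEYS)
        if unknown:
            raise ValidationError(f"unknown keys in {label}: {sorted(unknown)}")
    if cross_gain < 0:
        raise ValidationError("cross_gain must be non-negative")
    gains = {
        "a14": sup["g_ei"], "a41": sup["g_ie"], "a11": sup["g_ee"], "a44": sup["g_ii"],
        "a32": deep["g_ei"], "a23": deep["g_ie"], "a33": deep["g_ee"], "a22": deep["g_ii"],
        "a31": 0.3 * cross_gain, "a34": 0.6 * cross_gain,
    }
    return MassModelParams(
        kappa=(sup["kappa_e"], deep["kappa_i"], deep["kappa_e"], sup["kappa_i"]),
        a=gains,
        Lw=((1.0, 0.0, 0.0, 0.0), (0.0, 0.0, 1.0, 0.0)),
        u_weights=(1.0, 0.0, 1.0, 0.0),
        alpha_u=alpha_u, beta_u=beta_u,
        alpha_n=alpha_n, beta_n=beta_n,
    )


def simulate_laminar(sup_params=None, deep_params=None, cross_gain: float = 1.0,
                     freqs=None, noise_sd: float = 0.5, seed: int = 0):
    """Two-channel (superficial/deep) laminar cross-spectra.

    Defaults produce a gamma-band peak in the superficial auto-spectrum and
    a low-frequency deep auto-spectrum.  Returns (SpectralData, GroundTruth).
    """
    params = laminar_template(sup_params, deep_params, cross_gain)
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, dtype=float).ravel()
    data, truth = simulate_subject(params, freqs, noise_sd, seed,
                                   channel_names=("sup", "deep"))
    truth.subject_params = [params]
    return data, truth


# ---------------------------------------------------------------------------
# Depth-LFP generator
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_rows, n_times):
    """Temporal 1/f-amplitude noise per contact, unit SD.

    The spectrum is flattened below a low-frequency shoulder (the 3rd rFFT
    bin) so the baseline is stationary over the record — without it, 1/f
    wander makes baseline z-scores meaningless for onset detection.
    """
    white = rng.normal(size=(n_rows, n_times))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_times)
    f = np.maximum(f, f[min(6, len(f) - 1)])
    spec /= np.sqrt(f)
    out = np.fft.irfft(spec, n=n_times, axis=1)
    sd = out.std(axis=1, keepdims=True)
    return out / np.where(sd > 0, sd, 1.0)


def simulate_depth_lfp(n_contacts: int = 24, sink_contact: int = 7,
                       onset_ms: float = 20.0, amplitude: float = 2.0,
                       noise_sd: float = 0.05, seed: int = 0,
                       spacing_um: float = 100.0) -> DepthLFP:
    """Depth-resolved LFP with an injected sink at one contact.

    A negative depth-Gaussian (SD 1.5 contacts) ramps on at ``onset_ms`` and
    decays over ~50 ms, superposed on pink noise; the negative curvature at
    the bump centre makes the current source density there a sink.  Times run
    −50..150 ms at 1 ms; contacts are 0-based, superficial to deep.
    """
    if not (0 <= sink_contact < n_contacts):
        raise ValidationError("sink_contact must lie on the probe")
    rng = np.random.default_rng(seed)
    times = np.arange(-50.0, 150.0, 1.0)
    depths = np.arange(n_contacts) * spacing_um
    v = noise_sd * _pink_noise(rng, n_contacts, times.size) if noise_sd > 0 else \
        np.zeros((n_contacts, times.size))
    if amplitude != 0.0:
        contact_idx = np.arange(n_contacts)
        depth_profile = np.exp(-0.5 * ((contact_idx - sink_contact) / 1.5) ** 2)
        t = times - onset_ms
        gate = np.clip(t / 5.0, 0.0, 1.0) * np.exp(-np.clip(t, 0.0, None) / 50.0)
        v = v - amplitude * depth_profile[:, None] * gate[None, :]
    return DepthLFP(times=times, depths=depths, v=v)
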
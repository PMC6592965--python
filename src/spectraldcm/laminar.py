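"""Laminar-probe analyses: current source density and layer assignment.

Two distinct tools share this module.  The first is classical current
source density (CSD, spatial sense): the negative second spatial difference
of depth-resolved LFPs localises transmembrane current sinks, and the
earliest suprathreshold sink marks the granular (input) layer, anchoring the
probe's contacts to cortical depth.  The second is model-based: given
two-channel spectra from a superficial and a deep contact, the
superficial/deep designation is treated as a model-comparison problem — the
same mass model is inverted with the two candidate channel-to-layer
mappings and the free-energy difference scores the assignment.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SpectralDCMError, ValidationError
from .types import DepthLFP, LaminarAssignment, SpectralData
from .vl import CSDForwardModel, vl_invert

__all__ = [
    "NoSinkFound",
    "csd_profile",
    "first_active_sink",
    "layer_assignment_comparison",
]


class NoSinkFound(SpectralDCMError):
    """No contact crossed the sink threshold for the required duration."""


def csd_profile(lfp: DepthLFP) -> np.ndarray:
    """Current source density at the interior contacts.

    CSD_i(t) = −(v_{i−1} − 2 v_i + v_{i+1}) / Δz², with Δz the contact
    spacing; negative values are sinks.  Row *i* of the result corresponds
    to probe contact *i + 1*.  Affine depth profiles map to exactly zero.
    """
    if not isinstance(lfp, DepthLFP):
        raise ValidationError("csd_profile expects a DepthLFP")
    v = lfp.v
    dz2 = lfp.spacing**2
    return -(v[:-2] - 2.0 * v[1:-1] + v[2:]) / dz2


def first_active_sink(csd: np.ndarray, times, baseline_window, z_thresh: float = 3.5,
                      min_consecutive: int = 5, contact_offset: int = 1):
    """Earliest suprathreshold current sink across contacts.

    Each row of ``csd`` is z-scored against its own mean/SD inside
    ``baseline_window = (t0, t1)`` (ms, must precede the response); a sink is
    the first time at which z < −``z_thresh`` for at least
    ``min_consecutive`` consecutive samples.  Returns ``(contact, onset_ms)``
    where ``contact`` indexes the original probe (interior row i maps to
    contact i + ``contact_offset``).  Raises :class:`NoSinkFound` when no
    contact qualifies.
    """
    csd = np.atleast_2d(np.asarray(csd, dtype=float))
    times = np.asarray(times, dtype=float).ravel()
    if csd.shape[1] != times.size:
        raise ValidationError("csd columns must match the time axis")
    t0, t1 = float(baseline_window[0]), float(baseline_window[1])
    if t1 <= t0:
        raise ValidationError("baseline window must satisfy t0 < t1")
    base = (times >= t0) & (times < t1)
    if base.sum() < 2:
        raise ValidationError("baseline window contains fewer than 2 samples")
    if t1 > times[-1]:
        raise ValidationError("baseline window must precede the response window")
    mu = csd[:, base].mean(axis=1, keepdims=True)
    sd = csd[:, base].std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd <= 0, np.inf, sd)
    z = (csd - mu) / sd

    post = times >= t1
    best = None
    for row in range(z.shape[0]):
        active = (z[row] < -z_thresh) & post
        run = 0
        for idx in range(times.size):
            run = run + 1 if active[idx] else 0
            if run >= min_consecutive:
                onset = times[idx - min_consecutive + 1]
                if best is None or onset < best[1]:
                    best = (row + contact_offset, float(onset))
                break
    if best is None:
        raise NoSinkFound(
            f"no contact stayed below z = -{z_thresh} for {min_consecutive} samples"
        )
    return best


def layer_assignment_comparison(data: SpectralData, model: CSDForwardModel,
                                prior=None, **settings) -> LaminarAssignment:
    """Assign two recorded channels to superficial/deep model populations.

    The forward model must observe two channels (row 0 superficial, row 1
    deep).  The data are inverted twice — once as given and once with the
    channels swapped — and the free-energy difference ΔF = F_given − F_swapped
    is the assignment evidence: ΔF > 0 favours mapping data channel 0 to the
    superficial row.  Relabelling the input channels flips the sign of ΔF
    exactly, since it merely exchanges the two fits.
    """
    if data.n_channels != 2:
        raise ValidationError("layer assignment requires exactly two channels")
    res_given = vl_invert(data, model, prior, **settings)
    res_swapped = vl_invert(data.swap_channels(0, 1), model, prior, **settings)
    dF = res_given.free_energy - res_swapped.free_energy
    ch = data.channel_names
    if dF >= 0:
        mapping = {ch[0]: "superficial", ch[1]: "deep"}
    else:
        mapping = {ch[0]: "deep", ch[1]: "superficial"}
    return LaminarAssignment(
        channel_to_layer=mapping,
        free_energies={
            f"{ch[0]}=superficial,{ch[1]}=deep": res_given.free_energy,
            f"{ch[0]}=deep,{ch[1]}=superficial": res_swapped.free_energy,
        },
        delta_f=float(dF),
        results={"given": res_given, "swapped": res_swapped},
    )
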
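"""Dispatch helpers over the mass- and field-model forward predictions."""

from __future__ import annotations

from .exceptions import ValidationError
from .field import FieldModelParams, predict_csd_field
from .mass import MassModelParams, predict_csd_mass
from .types import SpectralPrediction

__all__ = ["predict_csd"]


def predict_csd(model, freqs, channel_names=None) -> SpectralPrediction:
    """Predicted cross-spectral density for either forward-model family."""
    if isinstance(model, MassModelParams):
        return predict_csd_mass(model, freqs, channel_names)
    if isinstance(model, FieldModelParams):
        return predict_csd_field(model, freqs, channel_names)
    raise ValidationError("model must be MassModelParams or FieldModelParams")
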
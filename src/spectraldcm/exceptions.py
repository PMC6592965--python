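"""Exception hierarchy.

Validation problems (bad inputs, malformed files, inconsistent shapes) raise
:class:`ValidationError`; numerical failures of an otherwise well-posed
computation (unstable linearisation, non-convergence, indefinite precision)
raise :class:`NumericalError` or a subclass.  The CLI maps the former to exit
code 2 and the latter to exit code 1.
"""


class SpectralDCMError(Exception):
    """Base class for all package errors."""


class ValidationError(SpectralDCMError, ValueError):
    """Invalid input data, configuration or file contents."""


class NumericalError(SpectralDCMError, RuntimeError):
    """A numerical procedure failed (instability, divergence, indefiniteness)."""


class StabilityError(NumericalError):
    """The linearised system has eigenvalues with non-negative real part."""


class ConvergenceError(NumericalError):
    """An iterative scheme exhausted its iteration budget."""
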
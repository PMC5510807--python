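"""Exception hierarchy for analysis failures.

These mirror the failure modes an operator meets in practice: a movie with
no periodic signal, an edge whose metachronal coordination is too poor to
carry a measurable wave, or a tracer that never crosses the observation
window.
"""


class CiliaflowError(Exception):
    """Base class for all package-specific failures."""


class NoDominantFrequency(CiliaflowError):
    """The grey-level power spectrum has no peak standing out of the floor."""


class NoMeasurablePeriod(CiliaflowError):
    """The kymograph autocorrelation shows no repeat above threshold."""


class WavelengthNotMeasurable(CiliaflowError):
    """Phase-versus-abscissa regression too poor (or flat) to define a wave."""


class TracerExited(CiliaflowError):
    """A tracer left the channel through the wall or the stagnant lid."""

    def __init__(self, message, exit_point=None):
        super().__init__(message)
        self.exit_point = exit_point


class TracerStalled(CiliaflowError):
    """A tracer failed to cross the observation window within the time cap."""


class SolverError(CiliaflowError):
    """Flow solve did not meet its residual tolerances."""
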
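"""Exception hierarchy for screenkit."""


class ScreenKitError(Exception):
    """Base class for all screenkit errors."""


class InvalidParameterError(ScreenKitError, ValueError):
    """A parameter is outside its documented domain."""


class SimulationError(ScreenKitError):
    """A stochastic simulation reached an unrecoverable state (e.g. extinction)."""


class LibraryMismatchError(ScreenKitError):
    """Samples quantified against different shRNA libraries were combined."""

    def __init__(self, message, offending_ids=()):
        super().__init__(message)
        self.offending_ids = list(offending_ids)


class NoGrowthError(ScreenKitError):
    """Every well negative at every dose: clonogenic frequency indistinguishable from 0."""


class SaturatedError(ScreenKitError):
    """Every well positive at every dose: frequency not resolvable, lower doses needed."""
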
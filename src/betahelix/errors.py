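"""Exception types shared across the toolkit."""


class BetaHelixError(Exception):
    """Base class for all toolkit errors."""


class InvalidSequenceError(BetaHelixError, ValueError):
    """A sequence contains a letter outside the 20 standard amino acids."""


class LayoutError(BetaHelixError, ValueError):
    """A rung layout violates its structural invariants."""


class DomainError(BetaHelixError, ValueError):
    """A numeric argument is outside the physically meaningful domain."""


class AnalysisError(BetaHelixError, RuntimeError):
    """An analysis could not produce a well-defined result on this input."""


class NoTransitionError(AnalysisError):
    """A melt curve shows no detectable unfolding transition."""


class IsodichroicNotFoundError(AnalysisError):
    """No common crossing exists in a family of spectra."""


class IllDefinedIsodichroicError(AnalysisError):
    """Pairwise spectral crossings spread beyond the accepted tolerance."""


class NoPeriodicityError(AnalysisError):
    """A height profile has no spectral peak above the noise floor."""


class InsufficientDataError(AnalysisError, ValueError):
    """Too few observations for the requested fit."""


class ResampleRequiredError(AnalysisError, ValueError):
    """Input is not on the uniform grid the method requires."""


class EmptyRegionError(AnalysisError, ValueError):
    """A region selector matched no atom pairs."""


class PiUndefinedError(AnalysisError):
    """Net charge never crosses zero; no isoelectric point exists."""
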
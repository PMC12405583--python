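"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`DCTurnoverError`, so callers (and the CLI) can catch one type.
"""


class DCTurnoverError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DCTurnoverError, ValueError):
    """Input data violate a precondition (too few time points, bad schema, ...)."""


class FitFailureError(DCTurnoverError, RuntimeError):
    """An optimiser failed to converge after bounded restarts."""


class NoSteadyStateError(DCTurnoverError, ValueError):
    """Model 1 requested with efflux <= proliferation: no finite steady state."""


class ResolutionError(DCTurnoverError, ValueError):
    """Age-grid spacing too coarse for the requested simulation."""


class ConfigError(DCTurnoverError, ValueError):
    """Invalid generator or run configuration (unknown keys, infeasible packing)."""
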
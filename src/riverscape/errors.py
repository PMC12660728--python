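"""Exception hierarchy.

Everything user-facing derives from :class:`RiverscapeError` so the CLI can
map any library failure to a single-line, machine-parsable error class.
"""


class RiverscapeError(Exception):
    """Base class for all riverscape errors."""


class ValidationError(RiverscapeError, ValueError):
    """Invalid argument or malformed configuration; names the offending field."""


class DataError(RiverscapeError):
    """Input data violates a contract (mismatched names, non-ultrametric tree ...)."""


class ConfigurationError(RiverscapeError):
    """Inconsistent analysis setup, e.g. ages outside the tiled time-slice span."""


class UnderflowError(RiverscapeError):
    """Likelihood underflowed to zero everywhere; suggests rescaling."""


class OptimizationError(RiverscapeError):
    """All optimizer starts failed to produce a finite likelihood."""


class SimulationError(RiverscapeError):
    """A rejection-sampling simulation exhausted its attempt budget."""
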
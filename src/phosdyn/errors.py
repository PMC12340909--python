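"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: config errors -> 2, data-format
errors -> 3, numerical failures -> 4.
"""


class PhosdynError(Exception):
    """Base class for all package errors."""


class ConfigError(PhosdynError):
    """Invalid or inconsistent configuration."""


class DataFormatError(PhosdynError):
    """Malformed or incomplete input data."""


class NumericalError(PhosdynError):
    """A numerical procedure failed (non-convergence, degeneracy)."""
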
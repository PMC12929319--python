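"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, data 3, convergence 4).
"""


class HsuvmixError(Exception):
    """Base class for all package errors."""


class ConfigError(HsuvmixError):
    """Invalid configuration: bad probabilities, missing family parameters, N < 2, ..."""


class DataError(HsuvmixError):
    """Invalid data: utilities out of range, malformed profiles, schema violations."""


class InvalidProfileError(DataError):
    """An EQ-5D-3L profile with a level outside {1, 2, 3}."""


class ValueSetParseError(ConfigError):
    """A value-set file that does not follow the documented schema."""


class ConvergenceError(HsuvmixError):
    """Optimiser failed to converge; carries best-so-far diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NumericalError(HsuvmixError):
    """Non-finite quantities encountered during likelihood evaluation."""
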
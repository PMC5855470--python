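"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: DataError -> 1, ConfigError -> 2.
"""


class OdormixError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OdormixError):
    """Invalid configuration (bad weights, bad grid, bad rule string...)."""


class DataError(OdormixError):
    """Malformed or inconsistent data (schema, lengths, unknown compounds...)."""


class FitError(OdormixError):
    """A statistics fit could not be performed (too few samples, zero variance)."""


class TrainingError(OdormixError):
    """Network training diverged; carries the epoch at which it happened."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
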
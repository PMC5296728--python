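"""Exception types shared across the package."""


class PulsedecodeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PulsedecodeError, ValueError):
    """A numeric or structural parameter violates its contract."""


class SignalRangeError(PulsedecodeError, ValueError):
    """A time point falls outside the domain of a signal or trajectory."""


class CalibrationError(PulsedecodeError, RuntimeError):
    """A requested output mean cannot be reached by the free rate constant."""


class ConfigError(PulsedecodeError, ValueError):
    """A configuration file failed validation; ``errors`` lists every violation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class UndefinedCorrelationError(PulsedecodeError, ValueError):
    """Pearson correlation requested for a constant column."""
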
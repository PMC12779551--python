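"""Exception hierarchy shared across the pipeline stages."""


class MnscreenError(Exception):
    """Base class for all package errors."""


class ParameterError(MnscreenError, ValueError):
    """A model or generator parameter violates its constraints."""


class InputError(MnscreenError, ValueError):
    """Malformed or empty input data."""


class ConfigError(MnscreenError, ValueError):
    """An analysis configuration value is invalid."""


class SchemaError(InputError):
    """A required column is missing from a tabular input."""

    def __init__(self, missing_columns, path=None):
        self.missing_columns = list(missing_columns)
        self.path = path
        where = f" in {path}" if path else ""
        super().__init__(
            f"missing required column(s){where}: {', '.join(self.missing_columns)}"
        )


class QuantificationError(MnscreenError):
    """A well series cannot yield a phenotype (all failed or all zero)."""


class ReferenceDayError(MnscreenError):
    """The requested normalization reference day is absent or failed."""


class InsufficientDataError(MnscreenError):
    """Not enough observations for the requested statistic."""


class TraceError(MnscreenError, ValueError):
    """A fluorescence trace is degenerate (e.g. non-positive baseline)."""


class DetectionError(MnscreenError):
    """Event detection cannot proceed (e.g. zero-variance trace)."""


class UndefinedStatisticError(MnscreenError):
    """A test or ratio is undefined for the given inputs."""
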
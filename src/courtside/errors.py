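"""Exception hierarchy shared across the pipeline stages."""


class CourtsideError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CourtsideError, ValueError):
    """Invalid configuration value (bad probability, nonpositive count, ...)."""


class SchemaError(CourtsideError, ValueError):
    """Input file does not conform to the documented CSV dialect."""


class DuplicateKeyError(SchemaError):
    """A key that must be unique (e.g. player-date in game logs) repeats."""


class DegenerateDesignError(CourtsideError, ValueError):
    """Regression design has no usable variation (e.g. constant predictor)."""


class CollinearDesignError(CourtsideError, ValueError):
    """Regression design is numerically collinear."""


class AgreementUndefinedError(CourtsideError, ValueError):
    """Cross-source agreement requested on an empty event set."""
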
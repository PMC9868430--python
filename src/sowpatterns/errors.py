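"""Exception hierarchy shared across the package."""


class SowPatternsError(Exception):
    """Base class for package-specific errors."""


class ConfigError(SowPatternsError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputDataError(SowPatternsError, ValueError):
    """Malformed or incomplete input data (streams, tables, files)."""


class FitError(SowPatternsError, RuntimeError):
    """A model could not be estimated (e.g. no events in a survival fit)."""


class RankDeficiencyError(FitError):
    """Design matrix is not full rank (collinear terms)."""


class PipelineError(SowPatternsError, RuntimeError):
    """A pipeline stage is missing one of its input artifacts."""
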
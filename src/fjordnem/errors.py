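"""Exception hierarchy shared across the pipeline.

Config problems and data problems are kept distinct so the command-line
layer can map them to different exit codes.
"""


class FjordNemError(Exception):
    """Base class for all package errors."""


class ConfigError(FjordNemError):
    """Invalid or missing configuration (exit code 2 in the CLI)."""


class DataError(FjordNemError):
    """Invalid or insufficient input data (exit code 3 in the CLI)."""


class FormatError(DataError):
    """A table could not be parsed (e.g. a required column is missing)."""


class ValidationError(DataError):
    """A value violates a domain invariant (negative depth, NaN salinity...)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class EmptyPoolError(DataError):
    """No samples match a (region, water mass, tracer) pooling request."""
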
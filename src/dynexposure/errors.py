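"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: config errors -> 2, data/format
errors -> 3, compute errors -> 4.
"""


class DynExposureError(Exception):
    """Base class for all package errors."""


class ConfigError(DynExposureError):
    """Invalid configuration (bad scenario parameters, missing paths...)."""


class DataError(DynExposureError):
    """Input data violates a contract (empty group, all stations flagged...)."""


class FormatError(DataError):
    """A file could not be parsed as its declared format."""


class UnsupportedCRSError(FormatError):
    """Raster is not in a geographic (degree) coordinate system."""


class AmbiguityError(DataError):
    """Duplicate records where the schema requires uniqueness."""


class DomainError(DynExposureError):
    """A value lies outside the mathematical domain of an operation."""


class ComputeError(DynExposureError):
    """A computation failed despite valid inputs."""
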
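"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
DegenerateDataError (numeric degeneracy) -> 4.
"""


class CordmapperError(Exception):
    """Base class for all package errors."""


class ConfigError(CordmapperError):
    """Invalid run configuration or parameters."""


class DataError(CordmapperError):
    """Malformed, inconsistent or out-of-range input data."""


class ReferenceError_(DataError):
    """A record references an entity that does not exist (e.g. orphan cell)."""


class ValidationError(DataError):
    """A field violates its documented range or type."""


class DegenerateDataError(CordmapperError):
    """Data cannot support the requested computation (singular covariance,
    zero variance, undersized sample)."""
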
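"""Exception hierarchy for the array-dPCR pipeline.

Every stage raises a subclass of :class:`ArrayDPCRError` so callers (and the
CLI) can attribute a failure to a stage by type.
"""


class ArrayDPCRError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ArrayDPCRError, ValueError):
    """An argument violates a documented precondition."""


class ConfigError(ArrayDPCRError):
    """A configuration file or object is malformed or inconsistent."""


class GridNotFoundError(ArrayDPCRError):
    """The partition grid could not be located in the reference-dye image."""


class EstimationError(ArrayDPCRError):
    """Too little usable data to estimate a model (e.g. illumination field)."""


class SaturationError(ArrayDPCRError):
    """All partitions positive: the Poisson estimate is unbounded.

    Carries the standard remedy — dilute the sample and rerun.
    """


class SchemaError(ArrayDPCRError):
    """A CSV table does not conform to the documented column schema."""
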
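"""Exception hierarchy for the pipeline.

Errors are split by what the caller can do about them: fix the input
table (SchemaError / IntegrityError), fix array shapes (DimensionError),
fix a parameter (ParameterError), or inspect degenerate data
(DegenerateDataError).
"""


class GradasymError(Exception):
    """Base class for all package errors."""


class SchemaError(GradasymError):
    """An input table is missing a required column or has a bad dtype."""


class IntegrityError(GradasymError):
    """An input table violates a structural invariant (duplicates, bad homolog map)."""


class DimensionError(GradasymError):
    """Array shape does not match the parcellation or a paired array."""


class ParameterError(GradasymError):
    """A parameter is outside its documented domain."""


class DegenerateDataError(GradasymError):
    """Numerically degenerate input: constant signal, zero-variance map, singular covariance."""


class DesignError(GradasymError):
    """A statistical design matrix is rank deficient or otherwise unusable."""
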
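"""Exception taxonomy shared across the package.

The CLI maps these onto exit codes: usage/parameter problems, schema or
data problems, estimation failures, and I/O failures are distinguished so
pipelines can react programmatically.
"""


class SynthcohortError(Exception):
    """Base class for all package errors."""


class ParameterError(SynthcohortError, ValueError):
    """An argument value is outside its documented domain."""


class SchemaError(SynthcohortError, ValueError):
    """A schema is malformed or data do not match the declared schema."""


class CohortParseError(SchemaError):
    """A cell value in a cohort file does not conform to its variable kind."""


class EstimationError(SynthcohortError, RuntimeError):
    """A statistical estimator could not produce a result."""
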
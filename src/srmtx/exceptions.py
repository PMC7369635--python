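"""Exception hierarchy.

Validation problems (bad configuration, mismatched inputs) are distinguished
from computational failures so the CLI can map them to distinct exit codes.
"""


class SrmtxError(Exception):
    """Base class for package errors."""


class InvalidConfigError(SrmtxError, ValueError):
    """A configuration value violates its documented constraints."""


class DegenerateInputError(SrmtxError, ValueError):
    """An input is degenerate for the requested operation (e.g. constant)."""


class EstimationError(SrmtxError, RuntimeError):
    """A model fit cannot be carried out (e.g. collinear covariates)."""


class PipelineValidationError(SrmtxError, ValueError):
    """Cross-file consistency check failed before any computation ran."""
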
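"""Exception hierarchy for abfekit.

All validation problems derive from :class:`ValidationError` so that the CLI
can map them uniformly to exit code 2; estimator convergence failures derive
from :class:`ConvergenceError` (exit code 3).
"""


class AbfekitError(Exception):
    """Base class for all abfekit errors."""


class ValidationError(AbfekitError, ValueError):
    """Invalid input data, parameters or file contents."""


class FormatError(ValidationError):
    """A file does not conform to the canonical TSV/JSON formats."""


class ScheduleMismatchError(ValidationError):
    """A λ value in a file does not match the supplied schedule."""


class CompletenessError(ValidationError):
    """The (λ, replica) grid of an ensemble is not rectangular."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but degenerate for the requested operation."""


class ConvergenceError(AbfekitError, RuntimeError):
    """An iterative estimator failed to converge; check distribution overlap."""
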
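"""Exception hierarchy used across the package.

Two families map onto the pipeline exit codes: :class:`InputError` (bad or
inconsistent input data, exit code 2) and :class:`PreconditionError`
(statistical preconditions violated, e.g. a constant map, exit code 3).
"""


class MaplinkError(Exception):
    """Base class for all package errors."""


class InputError(MaplinkError):
    """Invalid, missing, or inconsistent input data."""


class PreconditionError(MaplinkError):
    """A statistical precondition is not met (constant map, too few points...)."""
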
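"""Exception hierarchy.

Each family carries a distinct process exit code so shell pipelines can
tell input problems from validation and numerical failures.
"""


class MultiTransError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(MultiTransError):
    """Missing, unreadable, or malformed input files."""

    exit_code = 2


class ParseError(InputError):
    """A file was readable but did not conform to the expected dialect."""


class ValidationError(MultiTransError):
    """Inputs parsed but violate a contract (shape, range, ordering...)."""

    exit_code = 3


class EmptyPanelError(ValidationError):
    """Filtering removed every marker."""


class NumericalError(MultiTransError):
    """A numerical operation failed (singular covariance, non-PSD block...)."""

    exit_code = 4
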
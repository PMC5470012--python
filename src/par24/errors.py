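"""Exception taxonomy shared across the package.

Three failure kinds are kept apart so callers (and the CLI) can react
differently: malformed input files (:class:`FormatError`), values that violate
a documented domain invariant (:class:`ValidationError`), and calls that break
an operation's contract, e.g. scoring an unvalidated diary
(:class:`ContractError`).
"""


class Par24Error(Exception):
    """Base class for all package-specific errors."""


class FormatError(Par24Error):
    """An input file does not conform to the documented CSV dialect."""


class ValidationError(Par24Error):
    """A value violates a domain invariant (e.g. non-positive MET)."""


class ContractError(Par24Error):
    """An operation was called outside its precondition."""


class PipelineError(Par24Error):
    """An end-to-end study run cannot proceed (e.g. zero matched participants)."""
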
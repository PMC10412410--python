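"""Exception hierarchy.

Errors are split by the contract they violate so callers (and the CLI) can
map them to distinct exit codes: bad on-disk data vs. inconsistent inputs
vs. bad parameters vs. mathematically undefined requests.
"""


class RareclustError(Exception):
    """Base class for all package errors."""


class FormatError(RareclustError):
    """A file is missing or not in the expected on-disk format."""


class IntegrityError(RareclustError):
    """Components of a dataset disagree (dimension or identifier mismatch)."""


class ValidationError(RareclustError):
    """An in-memory object violates its invariants."""


class ParameterError(RareclustError):
    """A parameter is outside its admissible range."""


class DomainError(RareclustError):
    """The requested quantity is mathematically undefined for this input."""
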
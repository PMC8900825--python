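"""Exception hierarchy.

Every error raised by fragflow derives from :class:`FragflowError`, so
callers (and the CLI) can catch one type. Subclasses carry structured
context where the workflow needs it (e.g. the offending schema key).
"""

from __future__ import annotations


class FragflowError(Exception):
    """Base class for all fragflow errors."""


class AddressError(FragflowError, ValueError):
    """Malformed or out-of-range plate/well address."""


class LibraryError(FragflowError):
    """Problems ingesting or querying a fragment library."""


class FragmentNotFoundError(LibraryError, KeyError):
    """Unknown fragment identifier."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class DocumentValidationError(FragflowError):
    """A document failed collection-schema validation.

    Attributes
    ----------
    key : str
        The required key that is missing or has the wrong type.
    """

    def __init__(self, message: str, key: str):
        super().__init__(message)
        self.key = key


class StateError(FragflowError):
    """Campaign stage transition not permitted."""


class TransferError(FragflowError):
    """Invalid acoustic-transfer request (volume, duplicate destination, ...)."""


class CapacityError(FragflowError):
    """More items than the destination plate can hold."""


class ReconciliationError(FragflowError):
    """Harvest results and puck scans cannot be paired up."""
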
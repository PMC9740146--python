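"""Exception hierarchy for eegauth.

Everything derives from :class:`EEGAuthError` so callers can catch the
package's errors in one clause; the subclasses separate malformed files
(:class:`FormatError`), invalid in-memory data (:class:`ValidationError`),
bad user-supplied parameters (:class:`ParameterError`) and broken caller
contracts such as mismatched feature columns (:class:`ContractError`).
"""


class EEGAuthError(Exception):
    """Base class for all eegauth errors."""


class FormatError(EEGAuthError, ValueError):
    """A file on disk does not conform to the expected layout/schema."""


class ValidationError(EEGAuthError, ValueError):
    """In-memory data violates an invariant (shape, finiteness, labels)."""


class ParameterError(EEGAuthError, ValueError):
    """A user-supplied parameter is out of its valid domain."""


class ContractError(EEGAuthError, ValueError):
    """A call violates an API contract (e.g. feature-column mismatch)."""
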
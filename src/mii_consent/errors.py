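"""Exception hierarchy shared by all modules.

Validation problems in *data under examination* (e.g. a record that breaks
the five-year insurance cap) are reported as data, not raised — see
:mod:`mii_consent.engine`.  Exceptions here signal inputs that cannot be
interpreted at all.
"""


class MiiConsentError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MiiConsentError):
    """A value violates a structural invariant (malformed OID, missing
    mandatory data element, mixed patients in one document, ...)."""


class FormatError(MiiConsentError):
    """A document cannot be parsed in the requested dialect."""


class NotFoundError(MiiConsentError):
    """A code, policy or value set is not registered.

    Carries the queried identifier so callers can report it.
    """

    def __init__(self, message: str, identifier: str | None = None):
        super().__init__(message)
        self.identifier = identifier


class ConflictError(MiiConsentError):
    """An allocation or import collides with already-registered content."""


class UnmappedLabelError(MiiConsentError):
    """A source status token is outside the published mapping table domain.

    Deliberately distinct from mapping to ``unknown``: ``unknown`` means
    absence of documentation, never vocabulary drift.
    """
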
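"""Exception hierarchy.

Every error raised by the library derives from :class:`XtalTrackError` so
callers (and the CLI) can catch one base class.  Validation failures carry a
human-readable message naming the offending field or entity.
"""


class XtalTrackError(Exception):
    """Base class for all xtaltrack errors."""


class ValidationError(XtalTrackError):
    """Input violates a documented precondition (bad value, bad format)."""


class ParseError(ValidationError):
    """Text input could not be parsed (screen file line, sample name)."""


class ConflictError(XtalTrackError):
    """Uniqueness violated: duplicate barcode, acronym, name or well."""


class PermissionDenied(XtalTrackError):
    """Caller lacks the role required for this operation."""


class NotFoundError(XtalTrackError):
    """Referenced entity does not exist."""


class OccupancyError(XtalTrackError):
    """Pin or slot already holds something."""


class CapacityError(XtalTrackError):
    """No free slot available in any scanned puck."""


class StateError(XtalTrackError):
    """Operation not allowed in the entity's current lifecycle state."""


class LockedError(StateError):
    """Container belongs to a sent shipment and cannot be mutated."""


class UnsupportedFormatError(XtalTrackError):
    """File format recognized but not implemented (e.g. MIMER screens)."""


class TransportError(XtalTrackError):
    """Synchrotron endpoint unreachable or returned an error."""
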
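"""Exception hierarchy for the screen-analysis pipeline.

Every stage raises a subclass of :class:`ImmunoscreenError` so callers
(and the CLI exit-code mapping) can distinguish validation problems
from runtime failures.
"""


class ImmunoscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(ImmunoscreenError):
    """Input violates a documented invariant."""


class PlateParseError(ValidationError):
    """A plate-map or signal file row could not be parsed."""


class DuplicationError(ValidationError):
    """Duplicate key, e.g. the same (plate_id, well) twice."""


class GridError(ValidationError):
    """Time grids are inconsistent or a requested time is off-grid."""


class MissingControlError(ImmunoscreenError):
    """Too few control wells of the requested kind."""


class UndefinedZError(ImmunoscreenError):
    """Z-factor undefined: the control group means coincide."""


class NoValidTimepointError(ImmunoscreenError):
    """No timepoint satisfies the QC gate."""


class PairingError(ImmunoscreenError):
    """A compound lacks its paired monoculture or co-culture well."""


class LayoutError(ValidationError):
    """Requested layout does not fit the plate format."""
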
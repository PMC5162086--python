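"""Exception hierarchy.

Everything raised on purpose by mitoarch derives from :class:`MitoarchError`,
so callers (and the CLI) can distinguish data problems from bugs.
"""


class MitoarchError(Exception):
    """Base class for all mitoarch errors."""


class FormatError(MitoarchError):
    """Unparseable or malformed input file / pattern."""


class UnknownGeneError(MitoarchError):
    """A gene name that cannot be mapped onto the canonical token set."""


class EmptyRecordError(MitoarchError):
    """An input yielded zero usable gene features."""


class BoundsError(MitoarchError):
    """A coordinate outside the genome."""


class AmbiguityError(MitoarchError):
    """A duplicated token without a disambiguating copy suffix."""


class EmptyOrderError(MitoarchError):
    """No features of the requested kinds."""


class AnchorError(MitoarchError):
    """Neither the anchor gene nor any fallback is present."""


class IncomparableError(MitoarchError):
    """Two gene orders share no genes."""


class NotFoundError(MitoarchError):
    """A requested object (e.g. largest NCR) does not exist."""


class UndefinedGCError(MitoarchError):
    """GC content of an empty or all-ambiguous sequence."""


class EventError(MitoarchError):
    """An invalid rearrangement event (non-contiguous target, bad keep-pattern...)."""


class SpecError(MitoarchError):
    """An inconsistent synthetic-genome specification."""
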
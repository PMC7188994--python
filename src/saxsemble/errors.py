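"""Exception hierarchy.

Every error the pipeline can raise derives from :class:`SaxsembleError`
so callers (and the CLI exit-code mapping) can distinguish configuration,
I/O and computation failures.
"""


class SaxsembleError(Exception):
    """Base class for all package errors."""


class StructureIOError(SaxsembleError, IOError):
    """Unreadable/unwritable structure file."""


class EmptyStructureError(SaxsembleError, ValueError):
    """A file or selection produced zero atoms where atoms are required."""


class EnsembleConsistencyError(SaxsembleError, ValueError):
    """Frames of an ensemble do not share identical atom identities/order."""


class SelectionError(SaxsembleError, ValueError):
    """A selector resolved to an empty or otherwise unusable atom set."""


class AmbiguityError(SaxsembleError, ValueError):
    """A named-atom lookup matched more than one atom."""


class DegenerateGeometryError(SaxsembleError, ValueError):
    """Geometry unsuitable for the requested operation (e.g. collinear points)."""


class RejectionCollapseError(SaxsembleError, ValueError):
    """Iterative outlier rejection left fewer than 3 atom pairs."""


class CurveFormatError(SaxsembleError, ValueError):
    """A scattering-curve file could not be parsed."""


class EmptyRangeError(SaxsembleError, ValueError):
    """A q-range trim retained no points."""


class MissingSigmaError(SaxsembleError, ValueError):
    """An operation requiring per-point uncertainties got a curve without them."""


class ConnectivityError(SaxsembleError, ValueError):
    """Elastic network is disconnected (extra zero modes)."""


class ConfigError(SaxsembleError, ValueError):
    """Invalid run configuration."""
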
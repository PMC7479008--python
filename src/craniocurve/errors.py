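"""Exception hierarchy.

Every failure mode of the pipeline maps to a distinct exception class so the
command-line layer can translate them into distinct exit codes.
"""


class CranioError(Exception):
    """Base class for all craniocurve errors."""

    exit_code = 1


class InputError(CranioError):
    """Unreadable or malformed input file."""

    exit_code = 2


class DegenerateLandmarks(CranioError):
    """The three plane-defining landmarks are collinear or coincident."""

    exit_code = 3


class EmptySlice(CranioError):
    """The cutting plane does not intersect the surface."""

    exit_code = 4


class OpenContour(CranioError):
    """The plane section produced only open polylines, no closed loop."""

    exit_code = 5


class DegenerateOutline(CranioError):
    """Outline polygon has (near-)zero enclosed area."""

    exit_code = 6


class StartNotFound(CranioError):
    """The perpendicular bisector of the ex-ex segment misses the outline."""

    exit_code = 7


class CenterOutside(CranioError):
    """The polar centre is outside the outline polygon."""

    exit_code = 8


class InvalidRadius(CranioError):
    """Non-positive radius encountered during normalization."""

    exit_code = 9


class FlatCurve(CranioError):
    """Polar curve has no usable extrema (max - min below tolerance)."""

    exit_code = 10


class PeakTooFlat(CranioError):
    """The forehead peak never drops 0.1 below its maximum on one side."""

    exit_code = 11


class UndefinedICC(CranioError):
    """Ratings table carries no variance; ICC is undefined."""

    exit_code = 12


class SingletonGroup(CranioError):
    """A group of size 1 cannot contribute range/variance statistics."""

    exit_code = 13


class DegenerateVariance(CranioError):
    """All groups have zero within-group variance."""

    exit_code = 14


class SpecError(CranioError):
    """Invalid phantom specification."""

    exit_code = 15
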
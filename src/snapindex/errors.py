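"""Exception hierarchy for snapindex.

All package-specific failures derive from :class:`SnapindexError` so callers
(and the CLI) can distinguish "no indexing solution" outcomes from genuine
input or resource errors.
"""


class SnapindexError(Exception):
    """Base class for all snapindex errors."""


class InvalidCellError(SnapindexError, ValueError):
    """Unit-cell parameters are geometrically impossible (metric not positive definite)."""


class DegeneratePeakError(SnapindexError, ValueError):
    """A peak coincides with the direct beam: zero momentum transfer, no ULS."""


class UndefinedBisectorError(SnapindexError, ValueError):
    """Candidate direction and ULS direction are antiparallel; the bisecting axis is undefined."""


class ResourceLimitError(SnapindexError, RuntimeError):
    """A requested enumeration would exceed the configured point-count limit."""


class NoCandidatesError(SnapindexError, RuntimeError):
    """No peak has any candidate reciprocal-lattice point; the rotogram would be empty."""


class NoSolutionError(SnapindexError, RuntimeError):
    """No orientation scored above the acceptance threshold for this pattern."""


class InsufficientPeaksError(SnapindexError, ValueError):
    """Fewer peaks supplied than the configured minimum."""


class InsufficientInliersError(SnapindexError, RuntimeError):
    """Fewer than three inlier peaks: refinement is under-determined."""


class PeakListParseError(SnapindexError, ValueError):
    """A peak-list file row could not be parsed; the message names the line."""


class EvaluationAlignmentError(SnapindexError, ValueError):
    """Solutions and ground truths could not be aligned by pattern id."""


class DegenerateSimulationError(SnapindexError, RuntimeError):
    """A simulation produced zero reflections (cell, band and detector are inconsistent)."""
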
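"""Exception hierarchy shared across phylogrid modules."""


class PhylogridError(Exception):
    """Base class for all phylogrid errors."""


class InvalidParameterError(PhylogridError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(PhylogridError, ValueError):
    """An input file or text stream could not be parsed."""


class ValidationError(PhylogridError, ValueError):
    """A parsed object violates a structural invariant."""


class NameMismatchError(PhylogridError, ValueError):
    """Taxon name sets of a matrix and a tree do not line up.

    Carries the offending names so callers can report them.
    """

    def __init__(self, message, missing_from_tree=(), missing_from_matrix=()):
        super().__init__(message)
        self.missing_from_tree = sorted(missing_from_tree)
        self.missing_from_matrix = sorted(missing_from_matrix)


class EmptyIntersectionError(NameMismatchError):
    """No taxon is shared between a matrix and a tree."""


class InfeasibleMarginsError(PhylogridError, ValueError):
    """Requested row/column sums admit no binary matrix (Gale-Ryser)."""


class DegenerateTreeError(PhylogridError, ValueError):
    """A tree operation is undefined (e.g. zero total branch length)."""


class AlignmentError(PhylogridError, ValueError):
    """Two surfaces or maps do not share the required cell set/geometry."""


class UnknownMetricError(PhylogridError, KeyError):
    """A metric name is absent from an ensemble or surface collection."""


class InvalidScenarioError(InvalidParameterError):
    """An endemism-injection scenario refers to cells outside the grid."""


class UndefinedCellError(PhylogridError, ValueError):
    """A ratio metric is undefined because the denominator is zero."""

    def __init__(self, message, cells=()):
        super().__init__(message)
        self.cells = list(cells)


class StageError(PhylogridError, RuntimeError):
    """A pipeline stage failed; carries the stage and group name."""

    def __init__(self, stage, group=None, cause=None):
        msg = f"stage '{stage}'" + (f" for group '{group}'" if group else "")
        super().__init__(f"{msg} failed: {cause}")
        self.stage = stage
        self.group = group
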
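"""Exception hierarchy for stemopt."""


class StemoptError(Exception):
    """Base class for all stemopt errors."""


class InvalidParameterError(StemoptError, ValueError):
    """A cross-section or design parameter violates its invariants."""


class ConstraintError(StemoptError, ValueError):
    """A design vector violates its box bounds or admissibility constraints."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class GeometryViolationError(StemoptError, ValueError):
    """Stem boundary lies on or outside the canal boundary."""


class AlignmentError(StemoptError, ValueError):
    """Two stress-sample fields do not share the same sampling grid."""


class DegenerateFieldError(StemoptError, ValueError):
    """A stress field is degenerate (e.g. zero mean intact stress)."""


class SingularSectionError(StemoptError, ValueError):
    """A beam cross section has zero or negative stiffness."""


class FatigueDomainError(StemoptError, ValueError):
    """Stress outside the domain of the S-N model."""


class InfiniteLifeViolationError(StemoptError, ValueError):
    """Mean stress at or above the ultimate strength in the Goodman correction."""


class CapacityError(StemoptError, ValueError):
    """Requested orthogonal array exceeds the supported size."""


class InsufficientVerticesError(StemoptError, ValueError):
    """Vertex store too small for a farthest-point selection."""


class InfeasibleError(StemoptError, RuntimeError):
    """No feasible design found within the evaluation budget."""


class ParseError(StemoptError, ValueError):
    """A stress-field CSV does not match the declared schema."""
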
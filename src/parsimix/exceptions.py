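"""Exception hierarchy for parsimix."""


class ParsimixError(Exception):
    """Base class for all parsimix errors."""


class InvalidDecompositionError(ParsimixError):
    """A (volume, shape, rotation) triple violates its defining contracts."""


class SingularCovarianceError(ParsimixError):
    """A covariance matrix is singular (or not positive definite)."""


class DegenerateScatterError(ParsimixError):
    """All weighted scatter values collapsed to zero.

    Signals a component supported on a degenerate (lower-dimensional) point
    set; callers typically abort the affected random start.
    """


class DegenerateStartError(ParsimixError):
    """A single random start of the ECM algorithm collapsed (e.g. an empty
    hard-assignment component) and was abandoned."""


class FitFailureError(ParsimixError):
    """Every random start of a fit degenerated; no solution is available."""


class GenerationError(ParsimixError):
    """The overlap-controlled mixture generator failed (e.g. the bisection
    on the mean-separation scale could not bracket the target overlap)."""
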
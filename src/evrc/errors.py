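"""Exception hierarchy for the evrc package.

All evrc-specific failures derive from :class:`EvrcError` so callers can
catch the whole family; most also derive from the matching builtin so that
generic handling (``except ValueError``) keeps working.
"""


class EvrcError(Exception):
    """Base class for all evrc errors."""


class FormatError(EvrcError, ValueError):
    """Input file does not conform to the expected text format."""


class ValidationError(EvrcError, ValueError):
    """Input data violates a structural invariant (shape, sign, range)."""


class ParameterError(EvrcError, ValueError):
    """A tunable parameter is outside its admissible range."""


class UnrecoverableInputError(EvrcError, ValueError):
    """No usable constraints remain in the input (e.g. every bin isolated)."""


class DegenerateStructureError(EvrcError, ValueError):
    """A structure contains coincident points, so 1/distance is undefined."""


class DegenerateAlignmentError(EvrcError, ValueError):
    """Too few / collinear points to determine the requested superposition."""


class UndefinedCorrelationError(EvrcError, ValueError):
    """A correlation is requested on a constant or empty vector."""


class DivergenceError(EvrcError, RuntimeError):
    """The iterative optimization is moving away from any solution."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
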
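"""Exception hierarchy shared across the package."""


class MotifNullError(Exception):
    """Base class for all motifnull errors."""


class DimensionError(MotifNullError, ValueError):
    """Sequences of unequal length, or invalid motif dimensions."""


class AlphabetError(MotifNullError, ValueError):
    """A character outside {A, C, G, T} (ambiguity codes and gaps included)."""


class EmptyInputError(MotifNullError, ValueError):
    """An input stream or collection that must be nonempty was empty."""


class ParameterError(MotifNullError, ValueError):
    """An out-of-range or inconsistent parameter value."""


class FeasibilityError(ParameterError):
    """A target (mean IC, IC band, mean GC) outside the attainable range.

    Carries the feasible interval so callers can report it.
    """

    def __init__(self, message: str, feasible: tuple | None = None):
        if feasible is not None:
            message = f"{message} (feasible range: [{feasible[0]:.6g}, {feasible[1]:.6g}])"
        super().__init__(message)
        self.feasible = feasible


class ProposalBudgetError(MotifNullError, RuntimeError):
    """Rejection sampling exceeded its proposal budget."""
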
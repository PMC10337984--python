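"""Exception hierarchy for memodyn."""


class MemodynError(Exception):
    """Base class for all memodyn-specific errors."""


class NonUniqueStationaryError(MemodynError):
    """The Markov chain's eigenvalue-1 eigenspace has dimension > 1.

    Raised for degenerate (reducible or periodic) strategy pairs, typically
    involving deterministic corner strategies, where the long-run outcome
    frequencies depend on the initial round.
    """


class DegenerateChainError(MemodynError):
    """Both the determinant and stationary-distribution payoff forms are 0/0."""


class CapExceededError(MemodynError):
    """Requested memory length exceeds the configured state-space cap."""


class OutOfRangeError(MemodynError, ValueError):
    """A parameter lies outside its admissible open interval."""


class NotOnBoundaryError(MemodynError, ValueError):
    """The point is not on a boundary face (exactly one extreme coordinate)."""
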
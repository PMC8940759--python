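"""Exception types raised by gpcpk."""


class GPCError(Exception):
    """Base class for gpcpk errors."""


class DomainError(GPCError, ValueError):
    """An argument is outside the mathematical domain of the operation."""


class PoleError(GPCError, ValueError):
    """A parameter sits at (or within tolerance of) a pole, e.g. integer
    Pareto shape alpha, for which csc(pi*alpha) and Gamma(-alpha) blow up."""


class ConvergenceError(GPCError, ArithmeticError):
    """A series failed to reach the stopping threshold within the term cap,
    or the required working precision exceeded the overflow guard."""
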
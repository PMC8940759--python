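"""Precision policy and evaluation diagnostics.

All distribution values are computed with mpmath at a working precision
derived from a :class:`PrecisionPolicy`.  The policy captures the target
number of significant digits of the *result*, guard digits for intermediate
arithmetic, the absolute stopping threshold for series summation, and a hard
cap on the number of summed terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import mpmath as mp

__all__ = ["PrecisionPolicy", "EvalResult", "matching_digits", "matching_decimal_places"]


@dataclass(frozen=True)
class PrecisionPolicy:
    """Controls working precision and series stopping.

    Parameters
    ----------
    target_digits:
        Significant decimal digits the result should carry (>= 15).
    guard_digits:
        Extra digits carried by intermediate arithmetic.
    stop_exponent:
        Summation stops once ``|term| < 10**stop_exponent`` (after the term
        magnitude sequence has peaked, for alternating series).  Defaults to
        ``-target_digits``.
    max_terms:
        Hard cap on summed terms; exceeding it raises
        :class:`ConvergenceError`.
    relative_stop:
        If True, the stopping threshold is scaled by the magnitude of the
        closed-form (non-series) part of the value, which is useful when the
        function value itself is far below ``10**stop_exponent``.
    """

    target_digits: int = 65
    guard_digits: int = 10
    stop_exponent: Optional[int] = None
    max_terms: int = 10**6
    relative_stop: bool = False

    def __post_init__(self) -> None:
        if self.target_digits < 15:
            raise ValueError("target_digits must be >= 15")
        if self.guard_digits < 0:
            raise ValueError("guard_digits must be >= 0")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.stop_exponent is None:
            object.__setattr__(self, "stop_exponent", -self.target_digits)

    @property
    def working_digits(self) -> int:
        """Baseline working precision: target plus guard digits."""
        return self.target_digits + self.guard_digits


@dataclass
class EvalResult:
    """An arbitrary-precision function value plus series diagnostics.

    ``value`` is an ``mpmath.mpf``; use :meth:`value_str` for a decimal-string
    rendering at the policy's target precision.  ``branch`` records which of
    the two series engines produced the value, ``n_terms`` how many summand
    terms were added, ``max_term_log10`` the rounded base-10 exponent of the
    largest-magnitude summand (None when the sum is empty), and
    ``working_digits`` the decimal precision of the summation arithmetic.
    """

    value: mp.mpf
    branch: str  # "short" | "long"
    n_terms: int
    max_term_log10: Optional[int]
    working_digits: int
    kind: str = field(default="pdf")

    def value_str(self, digits: int = 65) -> str:
        return mp.nstr(self.value, digits)

    def __float__(self) -> float:
        return float(self.value)


def matching_digits(x, y) -> int:
    """Number of leading significant decimal digits on which x and y agree.

    Returns a large sentinel (1000) for exact equality.  The count is
    ``floor(-log10(|x-y| / max(|x|,|y|)))``, i.e. agreement of the leading
    significant figures rather than decimal places after the point.
    """
    x = mp.mpf(x) if not isinstance(x, mp.mpf) else x
    y = mp.mpf(y) if not isinstance(y, mp.mpf) else y
    if x == y:
        return 1000
    scale = max(abs(x), abs(y))
    if scale == 0:
        return 1000
    rel = abs(x - y) / scale
    return int(mp.floor(-mp.log10(rel)))


def matching_decimal_places(x, y) -> int:
    """Number of decimal places (digits after the point) on which x and y
    agree: floor(-log10 |x - y|).  This is the natural metric under an
    absolute series-stopping threshold, where the truncation error is
    bounded in absolute terms rather than relative ones."""
    x = mp.mpf(x) if not isinstance(x, mp.mpf) else x
    y = mp.mpf(y) if not isinstance(y, mp.mpf) else y
    if x == y:
        return 1000
    return int(mp.floor(-mp.log10(abs(x - y))))
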
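"""Arbitrary-precision special-function building blocks.

The GPC series need the incomplete beta function with a *negative* second
parameter, confluent hypergeometric functions at large negative argument,
Pochhammer symbols, and the regularised upper incomplete gamma Q.  The
negative-parameter incomplete beta is evaluated by its power series

    B_z(A, B) = z^A * sum_k (1-B)_k z^k / (k! (A+k)),

which is valid for any real B (and any non-negative-integer A) and converges
for |z| < 1; when z > 1/2 the reflection identity

    B_z(A, B) = B(A, B) - B_{1-z}(B, A)

routes the evaluation through the complementary argument so the series ratio
never exceeds 1/2.  Confluent hypergeometric values 1F1(A, A-k; x) with
nonpositive-integer offset are computed through the Kummer transformation
e^x * 1F1(-k, A-k; -x), a terminating (k+1)-term polynomial that is safe for
arbitrarily large |x|.
"""

from __future__ import annotations

import mpmath as mp

from .errors import ConvergenceError, DomainError, PoleError
from .policy import PrecisionPolicy

__all__ = [
    "pochhammer",
    "beta_inc",
    "beta_inc_reflect",
    "beta_ibp_reduce",
    "hyp1f1",
    "hyp1f1_reg",
    "gamma_reg_Q",
    "kummer_terminating",
]

_DEFAULT = PrecisionPolicy()

#: reflection/direct switch point for the incomplete beta series argument
_SPLIT = mp.mpf("0.5")


def pochhammer(x, k: int):
    """Rising factorial (x)_k = x (x+1) ... (x+k-1); (x)_0 = 1."""
    if k < 0:
        raise DomainError("pochhammer requires k >= 0")
    return mp.rf(mp.mpf(x), k)


def _near_nonpositive_int(x, tol=1e-8) -> bool:
    x = float(x)
    return x <= tol and abs(x - round(x)) <= tol


def _beta_series(z, A, B, policy: PrecisionPolicy):
    """B_z(A,B) by the direct power series; caller sets working precision.

    Converges for |z| < 1; terms decay geometrically with ratio -> z.
    Requires A not a nonpositive integer (pole of the A+k denominators).
    """
    z = mp.mpf(z)
    A = mp.mpf(A)
    B = mp.mpf(B)
    if z == 0:
        return mp.mpf(0)
    eps = mp.mpf(10) ** (-(mp.mp.dps - 3))
    s = mp.mpf(0)
    poch = mp.mpf(1)  # (1-B)_k
    fact = mp.mpf(1)
    for k in range(policy.max_terms):
        if k > 0:
            poch *= 1 - B + (k - 1)
            fact *= k
        term = poch * z**k / (fact * (A + k))
        s += term
        if k > 2 and abs(term) < eps * (abs(s) + eps):
            return z**A * s
    raise ConvergenceError("incomplete beta series exceeded max_terms")


def _complete_beta(A, B):
    """B(A,B) = Gamma(A) Gamma(B) / Gamma(A+B), via the entire reciprocal
    gamma so nonpositive-integer A+B yields 0 rather than a pole."""
    return mp.gamma(A) * mp.gamma(B) * mp.rgamma(A + B)


def beta_inc(z, A, B, policy: PrecisionPolicy = _DEFAULT):
    """Incomplete beta B_z(A,B) = integral_0^z u^(A-1) (1-u)^(B-1) du.

    B may be negative (non-integer); A must not be a nonpositive integer.
    For z <= 1/2 the direct series is used; otherwise the reflection through
    B_{1-z}(B,A), keeping the series ratio <= 1/2.
    """
    if not 0 <= z <= 1:
        raise DomainError(f"beta_inc requires z in [0,1], got {z}")
    if _near_nonpositive_int(A):
        raise PoleError(f"beta_inc: first parameter A={A} is a nonpositive integer")
    with mp.workdps(policy.working_digits + 8):
        z = mp.mpf(z)
        A = mp.mpf(A)
        B = mp.mpf(B)
        if z == 0:
            return mp.mpf(0)
        if z == 1:
            if _near_nonpositive_int(B):
                raise PoleError(
                    f"beta_inc: complete beta with nonpositive-integer B={B} diverges"
                )
            return _complete_beta(A, B)
        if z <= _SPLIT:
            return _beta_series(z, A, B, policy)
        if _near_nonpositive_int(B):
            raise PoleError(
                f"beta_inc: reflection route needs non-nonpositive-integer B, got {B}"
            )
        return _complete_beta(A, B) - _beta_series(1 - z, B, A, policy)


def beta_inc_reflect(z, A, B, policy: PrecisionPolicy = _DEFAULT):
    """B_{1-z}(A,B) evaluated via the reflection identity
    B_{1-z}(A,B) = B(A,B) - B_z(B,A).

    This is the alternative route to ``beta_inc(1-z, A, B)`` and serves as a
    cross-check of the series evaluation.
    """
    if not 0 <= z <= 1:
        raise DomainError(f"beta_inc_reflect requires z in [0,1], got {z}")
    with mp.workdps(policy.working_digits + 8):
        z = mp.mpf(z)
        A = mp.mpf(A)
        B = mp.mpf(B)
        if z == 1:
            return mp.mpf(0)
        if _near_nonpositive_int(B):
            raise PoleError(f"beta_inc_reflect: B={B} is a nonpositive integer")
        comp = _complete_beta(A, B)
        if z == 0:
            return comp
        return comp - _beta_series(z, B, A, policy)


def beta_ibp_reduce(z, A, B, policy: PrecisionPolicy = _DEFAULT):
    """B_z(A+1,B) via the integration-by-parts identity
    B_z(A+1,B) = A/(A+B) * B_z(A,B) - z^A (1-z)^B / (A+B).

    Used as an independent self-test route for the series evaluation."""
    with mp.workdps(policy.working_digits + 8):
        A = mp.mpf(A)
        B = mp.mpf(B)
        z = mp.mpf(z)
        if abs(A + B) < mp.mpf(10) ** (-policy.target_digits):
            raise ZeroDivisionError("beta_ibp_reduce: A+B is (numerically) zero")
        base = beta_inc(z, A, B, policy)
        return A / (A + B) * base - z**A * (1 - z) ** B / (A + B)


def kummer_terminating(A, k: int, x, keep_exp: bool = True):
    """1F1(A, A-k; x) for nonnegative integer k via the Kummer transform
    e^x * 1F1(-k, A-k; -x), a terminating (k+1)-term polynomial.

    Caller sets working precision.  With ``keep_exp=False`` the e^x factor is
    omitted (callers that combine several terms can factor it out)."""
    A = mp.mpf(A)
    x = mp.mpf(x)
    s = mp.mpf(1)
    c = mp.mpf(1)
    for j in range(1, k + 1):
        # c_j = (-k)_j (-x)^j / ((A-k)_j j!)
        c *= (-k + j - 1) * (-x) / ((A - k + j - 1) * j)
        s += c
    return mp.e**x * s if keep_exp else s


def hyp1f1(A, B, x, policy: PrecisionPolicy = _DEFAULT):
    """Kummer confluent hypergeometric 1F1(A,B;x), cancellation-safe.

    When B - A is a nonpositive integer -k the terminating Kummer polynomial
    is used, which is exact in k+1 terms for any x.  Otherwise mpmath's
    evaluation is run with the working precision raised by ~|x|*log10(e)
    digits to absorb the alternating-series cancellation at large |x|.
    """
    if _near_nonpositive_int(B):
        raise PoleError(f"hyp1f1: B={B} is a nonpositive integer")
    diff = float(B) - float(A)
    extra = int(abs(float(x)) * 0.4342944819032518) + 8
    if diff <= 1e-12 and abs(diff - round(diff)) < 1e-12:
        k = int(round(-diff))
        with mp.workdps(policy.working_digits + 8):
            return kummer_terminating(A, k, x)
    with mp.workdps(policy.working_digits + extra):
        return mp.hyp1f1(mp.mpf(A), mp.mpf(B), mp.mpf(x))


def hyp1f1_reg(A, B, x, policy: PrecisionPolicy = _DEFAULT):
    """Regularised confluent hypergeometric 1F~1(A,B;x) = 1F1(A,B;x)/Gamma(B).

    Entire in B: for nonpositive-integer B = -m the limit
    sum_{n>=m+1} (A)_n x^n / (Gamma(B+n) n!) is evaluated directly.
    """
    with mp.workdps(policy.working_digits + 8):
        A = mp.mpf(A)
        B = mp.mpf(B)
        x = mp.mpf(x)
        if not _near_nonpositive_int(B):
            if x < 0:
                # Kummer: 1F~1(A,B;x) = e^x 1F~1(B-A,B;-x); positive-argument
                # series avoids cancellation at large |x|
                return mp.e**x * mp.hyp1f1(B - A, B, -x) * mp.rgamma(B)
            return mp.hyp1f1(A, B, x) * mp.rgamma(B)
        # limit form at the pole
        m = int(round(-float(B)))
        eps = mp.mpf(10) ** (-(mp.mp.dps - 3))
        if x < 0:
            A2 = B - A
            s = mp.mpf(0)
            for n in range(m + 1, m + policy.max_terms):
                term = mp.rf(A2, n) * (-x) ** n * mp.rgamma(B + n) / mp.factorial(n)
                s += term
                if n > m + 2 and abs(term) < eps * (abs(s) + eps):
                    return mp.e**x * s
            raise ConvergenceError("hyp1f1_reg series exceeded max_terms")
        s = mp.mpf(0)
        for n in range(m + 1, m + policy.max_terms):
            term = mp.rf(A, n) * x**n * mp.rgamma(B + n) / mp.factorial(n)
            s += term
            if n > m + 2 and abs(term) < eps * (abs(s) + eps):
                return s
        raise ConvergenceError("hyp1f1_reg series exceeded max_terms")


def gamma_reg_Q(a, x, policy: PrecisionPolicy = _DEFAULT):
    """Regularised upper incomplete gamma Q(a,x) = Gamma(a,x)/Gamma(a),
    the survival function of the gamma distribution."""
    if not (float(a) > 0 and float(x) >= 0):
        raise DomainError("gamma_reg_Q requires a > 0 and x >= 0")
    with mp.workdps(policy.working_digits + 8):
        return mp.gammainc(mp.mpf(a), mp.mpf(x), mp.inf, regularized=True)
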
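"""The two GPC evaluation branches: short-t and long-t series.

Short-t
-------
The primary series for the GPC density,

    f(t) = theta(t-beta) * (alpha b^a beta^alpha / Gamma(a)) t^(a-alpha-1)
           * sum_n (-b t)^n / n! * B_{1-beta/t}(a+n, -alpha),

alternates in sign and, for t well beyond beta, its terms grow to enormous
magnitude before converging — the final value can be a thousand decades
below the largest summand.  The engine therefore runs in two passes:

1. a machine-precision *scan* of the summand in log10-magnitude arithmetic,
   recording how many terms are needed (stop once the magnitude sequence has
   peaked and dropped below the stopping threshold) and the rounded base-10
   exponent of the largest term;
2. a full re-computation of exactly those terms at a working precision of
   ``max_term_log10 + target`` digits, so that the cancelled sum still
   carries the target precision.

The stored summand terms include the constant prefactor, so the scanned
magnitudes are the magnitudes of the actual contributions to the value.

Long-t
------
The rearranged series (reflection of the incomplete beta, exchange of the
two absolutely convergent summations, and closure of the inner sum into a
confluent hypergeometric) gives, for the density,

    f(t) = GD(t; a,b)
           - pi csc(pi alpha) (b^a beta^alpha / Gamma(alpha)) t^(a-alpha-1)
             * 1F~1(a, a-alpha; -b t)
           - (alpha b^a / Gamma(a)) t^(a-1)
             * sum_{k>=1} (beta/t)^k (1-a)_k / (k! (k-alpha))
               * 1F1(a, a-k; -b t),

with analogous forms for the CDF, the super-cumulative integral and the
derivative.  The summand magnitudes decrease monotonically (ratio about
beta/(k t)), so a single last-term test suffices to stop, and each
1F1(a, a-k; -b t) is a terminating Kummer polynomial — no cancellation, no
precision precalculation.
"""

from __future__ import annotations

import math
from typing import Tuple

import mpmath as mp
from scipy.special import gammaln, gammasgn

from .errors import ConvergenceError, DomainError
from .params import GPCParams, FUNCTION_KINDS
from .policy import EvalResult, PrecisionPolicy
from .special import kummer_terminating, gamma_reg_Q, hyp1f1_reg

__all__ = [
    "gd_pdf",
    "pd_pdf",
    "conv_quadrature_oracle",
    "scan_short_terms",
    "evaluate_short",
    "evaluate_long",
    "asymptote_pdf",
    "long_term_ratio",
]

_DEFAULT = PrecisionPolicy()
#: hard guard: a pass-2 working precision beyond this signals runaway input
_MAX_WORKING_DIGITS = 10**6


def _check_kind(kind: str) -> None:
    if kind not in FUNCTION_KINDS:
        raise DomainError(f"kind must be one of {FUNCTION_KINDS}, got {kind!r}")


# ----------------------------------------------------------------------
# component densities
# ----------------------------------------------------------------------

def gd_pdf(t, a, b, policy: PrecisionPolicy = _DEFAULT):
    """Gamma density e^(-b t) (b t)^a / (t Gamma(a)) for t > 0, else 0."""
    if not (a > 0 and b > 0):
        raise DomainError("gd_pdf requires a > 0 and b > 0")
    with mp.workdps(policy.working_digits):
        t = mp.mpf(t)
        if t <= 0:
            return mp.mpf(0)
        a = mp.mpf(a)
        b = mp.mpf(b)
        return mp.e ** (-b * t) * (b * t) ** a / (t * mp.gamma(a))


def pd_pdf(t, alpha, beta_h, policy: PrecisionPolicy = _DEFAULT):
    """Pareto type I density (alpha/t) (beta/t)^alpha for t > beta, else 0."""
    if not (alpha > 0 and beta_h > 0):
        raise DomainError("pd_pdf requires alpha > 0 and beta_h > 0")
    with mp.workdps(policy.working_digits):
        t = mp.mpf(t)
        beta_h = mp.mpf(beta_h)
        if t <= beta_h:
            return mp.mpf(0)
        alpha = mp.mpf(alpha)
        return (alpha / t) * (beta_h / t) ** alpha


def conv_quadrature_oracle(t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT):
    """Direct adaptive quadrature of the defining convolution integral
    int_beta^t GD(t - tau) PD(tau) d tau.

    Written as int_0^{t-beta} GD(x) PD(t-x) dx and substituted with
    y = x^a, which removes the x^(a-1) endpoint singularity of the gamma
    density exactly, so tanh-sinh quadrature converges at full precision.
    Slow but independent of both series engines; the validation oracle for
    the density."""
    with mp.workdps(max(policy.working_digits, 40) + 10):
        t = mp.mpf(t)
        be = mp.mpf(params.beta_h)
        if t <= be:
            return mp.mpf(0)
        a, b, al = mp.mpf(params.a), mp.mpf(params.b), mp.mpf(params.alpha)
        pref = b**a / (a * mp.gamma(a))

        def integrand(y):
            x = y ** (1 / a)
            tau = t - x
            return mp.e ** (-b * x) * (al / tau) * (be / tau) ** al

        return pref * mp.quad(integrand, [0, ((t - be) / 2) ** a, (t - be) ** a])


# ----------------------------------------------------------------------
# short-t machinery
# ----------------------------------------------------------------------

def _beta_neg_first_series_float(x: float, negB: float, A: float) -> float:
    """B_x(negB, A) / x^negB = sum_k x^k (1-A)_k / (k! (k+negB)) in doubles.

    Used by the pass-1 scan with x = beta/t small; converges while
    |x * (A+k)| < k roughly, which holds throughout the scan regime."""
    s = 0.0
    c = 1.0
    for k in range(100000):
        if k > 0:
            c *= x * (1.0 - A + (k - 1)) / k
        term = c / (k + negB)
        s += term
        if k > 3 and abs(term) <= 1e-18 * abs(s):
            return s
        if not math.isfinite(s):
            raise ConvergenceError("pass-1 beta series overflowed")
    raise ConvergenceError("pass-1 beta series did not converge")


def _log10_beta_z(z: float, A: float, alpha: float) -> Tuple[float, float]:
    """(log10|B_z(A,-alpha)|, sign) at machine precision.

    Direct series for z <= 1/2 (log-scaled by z^A which may underflow),
    reflection through B_{1-z}(-alpha, A) otherwise."""
    if z <= 0.5:
        s = 0.0
        c = 1.0
        for k in range(100000):
            if k > 0:
                c *= z * (alpha + k) / k  # (1+alpha)_k z^k / k! incremental
            term = c / (A + k)
            s += term
            if k > 3 and abs(term) <= 1e-18 * abs(s):
                break
        else:
            raise ConvergenceError("pass-1 scan series did not converge")
        return A * math.log10(z) + math.log10(abs(s)), math.copysign(1.0, s)
    x = 1.0 - z
    # complete beta Gamma(A) Gamma(-alpha) / Gamma(A - alpha)
    lg = gammaln(A) + gammaln(-alpha) - gammaln(A - alpha)
    sg = gammasgn(A) * gammasgn(-alpha) * gammasgn(A - alpha)
    comp = sg * math.exp(lg)
    tail = x ** (-alpha) * _beta_neg_first_series_float(x, -alpha, A)
    v = comp - tail
    if v == 0.0:
        return -1e308, 1.0
    return math.log10(abs(v)), math.copysign(1.0, v)


def _short_prefactor_log10(kind: str, t: float, p: GPCParams) -> float:
    """log10 of the constant prefactor multiplying the short-t sum."""
    power = {"pdf": -1.0, "cdf": 0.0, "supercdf": 1.0, "deriv": -2.0}[kind]
    return (
        math.log10(p.alpha)
        + p.a * math.log10(p.b)
        + p.alpha * math.log10(p.beta_h)
        - gammaln(p.a) / math.log(10)
        + (p.a - p.alpha + power) * math.log10(t)
    )


def _short_term_log10(kind: str, n: int, t: float, p: GPCParams, z: float) -> float:
    """log10 |summand_n| (prefactor included) at machine precision."""
    bt = p.b * t
    base = n * math.log10(bt) - gammaln(n + 1.0) / math.log(10)
    a = p.a
    if kind == "pdf":
        lb, _ = _log10_beta_z(z, a + n, p.alpha)
        extra = 0.0
    elif kind == "cdf":
        lb, _ = _log10_beta_z(z, 1.0 + a + n, p.alpha)
        extra = -math.log10(a + n)
    elif kind == "supercdf":
        lb, _ = _log10_beta_z(z, 2.0 + a + n, p.alpha)
        extra = -math.log10((a + n) * (1.0 + a + n))
    else:  # deriv
        A = a + n - 1.0
        if abs(A) < 1e-9:
            # (a+n-1) * B_z(a+n-1, -alpha) -> z^A as A -> 0
            lb, extra = A * math.log10(z), 0.0
        else:
            lb, _ = _log10_beta_z(z, A, p.alpha)
            extra = math.log10(abs(A))
    return _short_prefactor_log10(kind, t, p) + base + extra + lb


def scan_short_terms(
    kind: str, t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT
) -> Tuple[int, int]:
    """Pass-1 scan of the short-t summand in log-magnitude arithmetic.

    Returns ``(n_terms, max_term_log10)``: the number of terms up to and
    including the first term whose magnitude, *after* the sequence has
    peaked, falls below ``10**policy.stop_exponent``, and the rounded base-10
    exponent of the largest summand magnitude.
    """
    _check_kind(kind)
    t = float(t)
    if t <= params.beta_h:
        raise DomainError("scan_short_terms requires t > beta")
    z = 1.0 - params.beta_h / t
    stop = float(policy.stop_exponent)
    best = -math.inf
    n = 0
    while n < policy.max_terms:
        lt = _short_term_log10(kind, n, t, params, z)
        if lt > best:
            best = lt
        peaked = lt < best - 0.5 or n > params.b * t + 4
        if policy.relative_stop and peaked and lt < stop + best:
            return n + 1, round(best)
        if peaked and lt < stop:
            return n + 1, round(best)
        n += 1
    raise ConvergenceError(f"short-t scan exceeded max_terms={policy.max_terms}")


def _scaled_beta(z, A, B, policy: PrecisionPolicy):
    """A * B_z(A,B), exact and pole-free as A -> 0 (deriv kind, n=0 when a=1).

    For z <= 1/2:  z^A * [1 + sum_{k>=1} A (1-B)_k z^k / (k! (A+k))].
    For z > 1/2:   Gamma(A+1) Gamma(B) / Gamma(A+B) - A * B_{1-z}(B,A).
    """
    z = mp.mpf(z)
    A = mp.mpf(A)
    B = mp.mpf(B)
    eps = mp.mpf(10) ** (-(mp.mp.dps - 3))
    if z <= mp.mpf("0.5"):
        s = mp.mpf(1)
        poch = mp.mpf(1)
        fact = mp.mpf(1)
        for k in range(1, policy.max_terms):
            poch *= 1 - B + (k - 1)
            fact *= k
            term = A * poch * z**k / (fact * (A + k))
            s += term
            if k > 2 and abs(term) < eps * (abs(s) + eps):
                return z**A * s
        raise ConvergenceError("scaled beta series exceeded max_terms")
    x = 1 - z
    comp = mp.gamma(A + 1) * mp.gamma(B) * mp.rgamma(A + B)
    s = mp.mpf(0)
    poch = mp.mpf(1)
    fact = mp.mpf(1)
    for k in range(policy.max_terms):
        if k > 0:
            poch *= 1 - A + (k - 1)
            fact *= k
        term = poch * x**k / (fact * (B + k))
        s += term
        if k > 2 and abs(term) < eps * (abs(s) + eps):
            return comp - A * x**B * s
    raise ConvergenceError("scaled beta series exceeded max_terms")


def _short_summand_mp(kind: str, n: int, t, p: GPCParams, policy: PrecisionPolicy):
    """Summand_n of Eq-form short-t series at the current mp precision,
    WITHOUT the constant prefactor (applied once by the caller)."""
    a = mp.mpf(p.a)
    al = mp.mpf(p.alpha)
    bt = mp.mpf(p.b) * t
    z = 1 - mp.mpf(p.beta_h) / t
    c = (-bt) ** n / mp.factorial(n)
    if kind == "pdf":
        return c * _scaled_beta(z, a + n, -al, policy) / (a + n)
    if kind == "cdf":
        return c / (a + n) * _scaled_beta(z, 1 + a + n, -al, policy) / (1 + a + n)
    if kind == "supercdf":
        return (
            c
            / ((a + n) * (1 + a + n))
            * _scaled_beta(z, 2 + a + n, -al, policy)
            / (2 + a + n)
        )
    # deriv: (a+n-1) * B_z(a+n-1, -alpha), pole-free via the scaled form
    return c * _scaled_beta(z, a + n - 1, -al, policy)


def evaluate_short(
    kind: str, t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT
) -> EvalResult:
    """Two-pass short-t evaluation of the requested GPC function.

    Pass 1 (:func:`scan_short_terms`) sizes the problem at machine
    precision; pass 2 re-computes every summand at
    ``max(target + guard, max_term_log10 + target + guard)`` digits and sums,
    leaving at least about ``target - 2`` correct digits after cancellation.
    """
    _check_kind(kind)
    tf = float(t)
    if tf <= params.beta_h:
        return EvalResult(mp.mpf(0), "short", 0, None, policy.working_digits, kind)
    n_terms, max_log10 = scan_short_terms(kind, tf, params, policy)
    t_in = t
    working = max(policy.working_digits, max(0, max_log10) + policy.working_digits)
    if working > _MAX_WORKING_DIGITS:
        raise ConvergenceError(
            f"required working precision {working} digits exceeds the overflow guard"
        )
    with mp.workdps(working + 8):
        t = mp.mpf(t_in)  # preserve extra precision of an mpf input
        p2 = PrecisionPolicy(
            target_digits=max(15, working),
            guard_digits=0,
            stop_exponent=policy.stop_exponent,
            max_terms=policy.max_terms,
        )
        total = mp.mpf(0)
        for n in range(n_terms):
            total += _short_summand_mp(kind, n, t, params, p2)
        a, b, al, be = (mp.mpf(params.a), mp.mpf(params.b),
                        mp.mpf(params.alpha), mp.mpf(params.beta_h))
        power = {"pdf": -1, "cdf": 0, "supercdf": 1, "deriv": -2}[kind]
        pref = al * b**a * be**al * mp.rgamma(a) * t ** (a - al + power)
        value = pref * total
    return EvalResult(value, "short", n_terms, max_log10, working, kind)


# ----------------------------------------------------------------------
# long-t machinery
# ----------------------------------------------------------------------

def _long_closed_form(kind: str, t, p: GPCParams, policy: PrecisionPolicy):
    """Closed (non-series) part of the long-t form for each kind."""
    a, b, al, be = (mp.mpf(p.a), mp.mpf(p.b), mp.mpf(p.alpha), mp.mpf(p.beta_h))
    bt = b * t
    picsc = mp.pi * mp.csc(mp.pi * al)
    if kind == "pdf":
        gam = b**a * mp.rgamma(a) * mp.e ** (-bt) * t ** (a - 1)
        asym = (
            -picsc * b**a * be**al * mp.rgamma(al) * t ** (a - al - 1)
            * hyp1f1_reg(a, a - al, -bt, policy)
        )
        return gam + asym
    if kind == "cdf":
        return (
            1
            - gamma_reg_Q(a, bt, policy)
            - picsc * b**a * be**al * mp.rgamma(al) * t ** (a - al)
            * hyp1f1_reg(a, a - al + 1, -bt, policy)
        )
    if kind == "supercdf":
        return (
            t * mp.e ** (-bt) * bt**a * mp.rgamma(a + 1)
            - al * be / (al - 1) * (1 - gamma_reg_Q(a, bt, policy))
            + (t - a / b) * (1 - gamma_reg_Q(a + 1, bt, policy))
            - picsc * b**a * be**al * mp.rgamma(al) * t ** (a - al + 1)
            * hyp1f1_reg(a, a - al + 2, -bt, policy)
        )
    # deriv
    return b**a * t ** (a - 2) * (
        (a - bt - 1) * mp.rgamma(a) * mp.e ** (-bt)
        + mp.pi * al * mp.csc(mp.pi * al) * (be / t) ** al * mp.rgamma(al + 1)
        * (
            (al + 1) * hyp1f1_reg(a, a - al, -bt, policy)
            - a * hyp1f1_reg(a + 1, a - al, -bt, policy)
        )
    )


def _long_term(kind: str, k: int, t, p: GPCParams, poch):
    """k-th simplified summand of the long-t series (constant prefactor
    included), with ``poch`` the running Pochhammer product for this kind."""
    a, b, al, be = (mp.mpf(p.a), mp.mpf(p.b), mp.mpf(p.alpha), mp.mpf(p.beta_h))
    bt = b * t
    r = be / t
    if kind == "pdf":
        # poch = (1-a)_k
        return (
            -al * b**a * mp.rgamma(a) * t ** (a - 1)
            * r**k * poch / (mp.factorial(k) * (k - al))
            * kummer_terminating(a, k, -bt)
        )
    if kind == "cdf":
        # poch = (-a)_k ; 1F1(a, a-(k-1); -bt)
        return (
            -al * b**a * mp.rgamma(1 + a) * t**a
            * r**k * poch / (mp.factorial(k) * (k - al))
            * kummer_terminating(a, k - 1, -bt)
        )
    if kind == "supercdf":
        # poch = (-a)_k, k >= 2 ; 1F1(a, a-(k-2); -bt)
        return (
            -al * b**a * t ** (a + 1) * mp.rgamma(a + 1)
            * r**k * poch / (mp.factorial(k) * (k - al) * (a - k + 1))
            * kummer_terminating(a, k - 2, -bt)
        )
    # deriv: poch = (1-a)_k
    return (
        b**a * t ** (a - 2) * al * mp.rgamma(a)
        * poch * r**k / (mp.factorial(k) * (k - al))
        * (
            bt * kummer_terminating(a, k, -bt)
            - (a - k - 1) * kummer_terminating(a - 1, k, -bt)
        )
    )


def evaluate_long(
    kind: str, t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT
) -> EvalResult:
    """Long-t evaluation: closed-form part plus the k-indexed accelerated sum.

    Intended for t >= 4*beta (the dispatcher's floor), though valid for any
    t > beta.  Summation stops when the magnitude of the last simplified
    term drops below ``10**policy.stop_exponent`` (the terms decrease
    monotonically, ratio about beta/(k t), so the single-term test is safe).
    """
    _check_kind(kind)
    if float(t) <= params.beta_h:
        return EvalResult(mp.mpf(0), "long", 0, None, policy.working_digits, kind)
    working = policy.working_digits
    with mp.workdps(working + 10):
        t = mp.mpf(t)  # preserve extra precision of an mpf input
        closed = _long_closed_form(kind, t, params, policy)
        thresh = mp.mpf(10) ** policy.stop_exponent
        if policy.relative_stop:
            thresh *= abs(closed)
        a = mp.mpf(params.a)
        k0 = 2 if kind == "supercdf" else 1
        if kind in ("pdf", "deriv"):
            poch = mp.mpf(1)  # accumulates (1-a)_k
            step0 = 1 - a
        else:
            poch = mp.mpf(1)  # accumulates (-a)_k
            step0 = -a
        # advance the Pochhammer product to k0
        for j in range(k0):
            poch *= step0 + j
        total = mp.mpf(0)
        n_terms = 0
        max_log10 = None
        k = k0
        while True:
            term = _long_term(kind, k, t, params, poch)
            total += term
            n_terms += 1
            if max_log10 is None and term != 0:
                max_log10 = int(mp.floor(mp.log10(abs(term)) + mp.mpf("0.5")))
            if abs(term) < thresh:
                break
            k += 1
            poch *= step0 + (k - 1)
            if n_terms >= policy.max_terms:
                raise ConvergenceError(
                    f"long-t sum exceeded max_terms={policy.max_terms}"
                )
        value = closed + total
    return EvalResult(value, "long", n_terms, max_log10, working, kind)


def asymptote_pdf(t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT):
    """The t -> infinity asymptote term of the GPC density alone:
    -pi csc(pi alpha) (b^a beta^alpha / Gamma(alpha)) t^(a-alpha-1)
    * 1F~1(a, a-alpha; -b t)."""
    if float(t) <= params.beta_h:
        raise DomainError("asymptote_pdf requires t > beta")
    with mp.workdps(policy.working_digits + 10):
        t = mp.mpf(float(t))
        a, b, al, be = (mp.mpf(params.a), mp.mpf(params.b),
                        mp.mpf(params.alpha), mp.mpf(params.beta_h))
        return (
            -mp.pi * mp.csc(mp.pi * al) * b**a * be**al * mp.rgamma(al)
            * t ** (a - al - 1) * hyp1f1_reg(a, a - al, -b * t, policy)
        )


def long_term_ratio(k: int, t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT):
    """|T_{k+1} / T_k| of the simplified long-t density summand; expected to
    be about beta/(k t) and strictly decreasing in k."""
    if k < 1:
        raise DomainError("long_term_ratio requires k >= 1")
    with mp.workdps(policy.working_digits + 10):
        t = mp.mpf(float(t))
        a = mp.mpf(params.a)
        poch_k = mp.rf(1 - a, k)
        poch_k1 = mp.rf(1 - a, k + 1)
        tk = _long_term("pdf", k, t, params, poch_k)
        tk1 = _long_term("pdf", k + 1, t, params, poch_k1)
        return abs(tk1 / tk)
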
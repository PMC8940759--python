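"""Public evaluation surface: branch dispatch, half-life, peak, concentration.

The two series engines are complementary: the short-t series converges in a
handful of terms for t near beta but needs enormous intermediate precision
for t >> beta, while the long-t series converges in a handful of monotone
terms for t >> beta.  The dispatcher switches at t = 4*beta, where the
long-t term ratio beta/(k t) is at worst about 1/4 — the cut is not
critical, it only needs to avoid term ratios approaching 1 as t -> beta.
"""

from __future__ import annotations

from typing import Optional, Tuple

import mpmath as mp

from .engines import evaluate_long, evaluate_short
from .errors import DomainError
from .params import ConcentrationModel, GPCParams
from .policy import EvalResult, PrecisionPolicy

__all__ = ["evaluate", "half_life", "find_peak", "concentration", "LONG_T_FLOOR_FACTOR"]

_DEFAULT = PrecisionPolicy()

#: the long-t branch is used for t >= LONG_T_FLOOR_FACTOR * beta
LONG_T_FLOOR_FACTOR = 4.0


def evaluate(
    kind: str,
    t,
    params: GPCParams,
    policy: PrecisionPolicy = _DEFAULT,
    force_branch: Optional[str] = None,
) -> EvalResult:
    """Evaluate a GPC function (pdf/cdf/supercdf/deriv) at time t (hours).

    Branch selection: t <= beta returns an exact zero (step-function
    convention theta(x)=0 for x<=0); beta < t < 4*beta uses the short-t
    engine; t >= 4*beta the long-t engine.  ``force_branch`` ("short" or
    "long") overrides the dispatch, e.g. for cross-validation.
    """
    tf = float(t)
    if force_branch not in (None, "short", "long"):
        raise DomainError("force_branch must be None, 'short' or 'long'")
    if tf <= params.beta_h:
        return EvalResult(mp.mpf(0), "short", 0, None, policy.working_digits, kind)
    branch = force_branch or (
        "long" if tf >= LONG_T_FLOOR_FACTOR * params.beta_h else "short"
    )
    if branch == "short":
        return evaluate_short(kind, t, params, policy)
    return evaluate_long(kind, t, params, policy)


def half_life(t, params: GPCParams, policy: PrecisionPolicy = _DEFAULT):
    """Instantaneous disposition half-life -ln(2) f(t) / f'(t).

    For a pure exponential decay this is the familiar ln(2)/rate constant;
    for the GPC it grows with t in the power tail.  Positive where the
    density is falling; singular (raises) at the density peak where f'=0.
    """
    tf = float(t)
    if tf <= params.beta_h:
        raise DomainError("half_life requires t > beta")
    f = evaluate("pdf", tf, params, policy).value
    fp = evaluate("deriv", tf, params, policy).value
    if fp == 0:
        raise ZeroDivisionError("half_life is singular at the density peak (f' = 0)")
    return -mp.log(2) * f / fp


def find_peak(
    params: GPCParams, policy: PrecisionPolicy = _DEFAULT, rel_tol: float = 1e-20
) -> Tuple[mp.mpf, mp.mpf]:
    """Locate the mode of the GPC density by bisection on the sign of f'.

    Brackets (beta*(1+1e-6), a/b + 10/b]; the density rises steeply from 0
    at t=beta and decays beyond the mode, so f' changes sign exactly once in
    the bracket.  Returns (t_peak, f(t_peak)).
    """
    with mp.workdps(max(policy.working_digits, 25) + 10):
        lo = mp.mpf(params.beta_h) * (1 + mp.mpf("1e-6"))
        hi = mp.mpf(params.a) / params.b + mp.mpf(10) / params.b
        dlo = evaluate("deriv", lo, params, policy).value
        dhi = evaluate("deriv", hi, params, policy).value
        if not (dlo > 0 and dhi < 0):
            raise DomainError(
                "find_peak: no derivative sign change in the bracket "
                f"({float(lo)}, {float(hi)})"
            )
        while (hi - lo) / hi > rel_tol:
            mid = (lo + hi) / 2
            if evaluate("deriv", mid, params, policy).value > 0:
                lo = mid
            else:
                hi = mid
        t_peak = (lo + hi) / 2
        return t_peak, evaluate("pdf", t_peak, params, policy).value


def concentration(t, model: ConcentrationModel, policy: PrecisionPolicy = _DEFAULT):
    """Single-dose concentration C(t) = AUC * pdf(t), mg/L."""
    with mp.workdps(policy.working_digits + 5):
        return mp.mpf(model.auc) * evaluate("pdf", t, model.params, policy).value
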
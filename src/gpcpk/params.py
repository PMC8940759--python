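"""Domain types: distribution parameters, concentration models, regimens.

The gamma-Pareto type I convolution (GPC) is the distribution of the sum of
a gamma variate (shape ``a``, rate ``b`` per hour) and a Pareto type I
variate (shape ``alpha``, location/scale ``beta_h`` hours).  In the
pharmacokinetic reading, ``beta_h`` is the circulation delay between an
intravenous bolus and the sampling site, and the Pareto power tail models
the slow, fractal-like washout from tissue.

All internal time arithmetic is in hours; ``beta`` is commonly reported in
seconds and can be supplied that way via :meth:`GPCParams.from_seconds_beta`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, PoleError

__all__ = [
    "GPCParams",
    "ConcentrationModel",
    "DoseRegimen",
    "ConcentrationSeries",
    "FUNCTION_KINDS",
    "dog1_params",
    "dog1_model",
]

#: The four GPC function kinds: density, CDF, super-cumulative (integral of
#: the CDF), and the density derivative.
FUNCTION_KINDS = ("pdf", "cdf", "supercdf", "deriv")

#: alpha closer than this to a nonnegative integer is rejected (csc(pi*alpha)
#: pole in the long-t asymptote; the negative-parameter beta series requires
#: non-integer alpha).
ALPHA_INTEGER_TOL = 1e-8


@dataclass(frozen=True)
class GPCParams:
    """Parameters of the gamma-Pareto type I convolution.

    a:      gamma shape, dimensionless, > 0
    b:      gamma rate, 1/h, > 0
    alpha:  Pareto shape, dimensionless, > 0, non-integer
    beta_h: Pareto delay/scale, hours, > 0
    """

    a: float
    b: float
    alpha: float
    beta_h: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.alpha > 0 and self.beta_h > 0):
            raise DomainError("GPCParams requires a, b, alpha, beta_h all > 0")
        if abs(self.alpha - round(self.alpha)) <= ALPHA_INTEGER_TOL:
            raise PoleError(
                f"alpha={self.alpha} is within {ALPHA_INTEGER_TOL} of an integer; "
                "the GPC series and its csc(pi*alpha) asymptote require "
                "non-integer alpha"
            )

    @classmethod
    def from_seconds_beta(cls, a: float, b: float, alpha: float, beta_s: float) -> "GPCParams":
        """Construct with the Pareto delay given in seconds."""
        return cls(a=a, b=b, alpha=alpha, beta_h=beta_s / 3600.0)

    @property
    def beta_s(self) -> float:
        return self.beta_h * 3600.0


@dataclass(frozen=True)
class ConcentrationModel:
    """AUC-scaled GPC concentration model: C(t) = auc * pdf(t).

    auc:  area under the concentration curve, mg*h/L
    dose: administered dose, mg/kg (optional); clearance CL = dose/auc
    """

    params: GPCParams
    auc: float
    dose: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.auc > 0:
            raise DomainError("auc must be > 0")
        if self.dose is not None and not self.dose > 0:
            raise DomainError("dose must be > 0 when given")

    @property
    def cl(self) -> Optional[float]:
        """Clearance in L/(h*kg), dose/auc."""
        if self.dose is None:
            return None
        return self.dose / self.auc

    @property
    def cl_ml_min_kg(self) -> Optional[float]:
        """Clearance in mL/(min*kg), the unit usual in PK reports."""
        cl = self.cl
        return None if cl is None else cl * 1000.0 / 60.0


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated equal intravenous bolus doses at a fixed interval."""

    interval_h: float
    n_doses: int
    dose_mg_per_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.interval_h > 0:
            raise DomainError("interval_h must be > 0")
        if self.n_doses < 1:
            raise DomainError("n_doses must be >= 1")

    @property
    def dose_times(self) -> np.ndarray:
        """Dose instants 0, tau, ..., (n-1)*tau in hours."""
        return self.interval_h * np.arange(self.n_doses, dtype=float)


@dataclass
class ConcentrationSeries:
    """Observed or simulated concentration-time data for one subject."""

    times: np.ndarray  # hours, strictly increasing, > 0
    concs: np.ndarray  # mg/L, > 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concs = np.asarray(self.concs, dtype=float)
        if self.times.shape != self.concs.shape or self.times.ndim != 1:
            raise DomainError("times and concs must be 1-D arrays of equal length")
        if not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(self.times > 0):
            raise DomainError("times must be > 0")
        if not np.all(self.concs > 0):
            raise DomainError(
                "all concentrations must be > 0 (the relative loss divides by them)"
            )

    def __len__(self) -> int:
        return len(self.times)


def dog1_params() -> GPCParams:
    """Reference GPC parameter set: metformin disposition in a healthy dog
    after an intravenous bolus (a=0.3493, b=0.7318/h, alpha=0.2644,
    beta=25 s).  Used throughout the examples and tests."""
    return GPCParams.from_seconds_beta(a=0.3493, b=0.7318, alpha=0.2644, beta_s=25.0)


def dog1_model() -> ConcentrationModel:
    """Reference concentration model for the same subject: AUC=31.16 mg*h/L
    from an 18.248 mg/kg bolus (clearance 9.76 mL/(min*kg))."""
    return ConcentrationModel(params=dog1_params(), auc=31.16, dose=18.248)
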
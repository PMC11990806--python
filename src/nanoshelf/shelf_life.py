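"""Van't Hoff shelf-life extrapolation and Arrhenius validation.

The empirical Van't Hoff (Q10) rule says reaction rates rise A-fold per
10 degC, with A typically 2-4.  If a quality indicator crosses its acceptance
limit after C_exp at stress temperature t_exp, the shelf life at storage
temperature t is

    C(t) = A**((t_exp - t) / 10) * C_exp

The exponent uses the Celsius temperature *difference*, which is scale-free.
When a storage-temperature observation of the same crossing is available,
the coefficient is refined by solving the relation for A ("selection
method"): the package uses bisection on the strictly monotone map
A -> C(A), cross-checked against the closed form
A = exp(ln(observed/C_exp) * 10 / (t_exp - t_obs)).

The extrapolation is validated through the Arrhenius picture: the two-point
activation energy

    E_A = R * T1*T2/(T1 - T2) * ln(k1/k2)      (temperatures in kelvin)

should be comparable to the energy a Q10 coefficient A implies at the mean
temperature, E_A = R * T**2 * ln(A) / 10.  Both numbers are always reported;
consistency is a relative-difference verdict, not an assertion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from pydantic import BaseModel, Field

from nanoshelf.data_model_io import DAYS_PER_MONTH, MINUTES_PER_DAY
from nanoshelf.staging import LinearFit

__all__ = [
    "VantHoffModel",
    "ArrheniusPoint",
    "ValidityVerdict",
    "predict_time",
    "predict_time_days",
    "refine_coefficient",
    "closed_form_coefficient",
    "shelf_life_table",
    "activation_energy",
    "q10_equivalent",
    "vant_hoff_validity",
    "rate_constant_from_stage",
    "R_GAS",
]

R_GAS = 8.314  # J/(mol K)
KELVIN_OFFSET = 273.15


class BracketingError(ValueError):
    """Bisection bounds do not bracket the requested coefficient."""


class VantHoffModel(BaseModel):
    """Reference crossing duration at a reference temperature plus the
    temperature coefficient A (rate fold-change per 10 degC)."""

    A: float = Field(gt=1)
    T_ref_C: float
    t_ref_min: float = Field(gt=0)


class ArrheniusPoint(BaseModel):
    """Rate constant at one absolute temperature."""

    T_K: float = Field(gt=0)
    k: float = Field(gt=0)

    @classmethod
    def from_celsius(cls, T_C: float, k: float) -> "ArrheniusPoint":
        return cls(T_K=T_C + KELVIN_OFFSET, k=k)


def predict_time(model: VantHoffModel, T_target_C: float) -> float:
    """Predicted crossing time (minutes) at T_target:
    t_ref * A**((T_ref - T_target)/10)."""
    return model.t_ref_min * model.A ** ((model.T_ref_C - T_target_C) / 10.0)


def predict_time_days(model: VantHoffModel, T_target_C: float) -> float:
    return predict_time(model, T_target_C) / MINUTES_PER_DAY


def closed_form_coefficient(
    t_ref_min: float, T_ref_C: float, observed_min: float, T_obs_C: float
) -> float:
    """Exact solution of the Van't Hoff relation for A."""
    if T_ref_C == T_obs_C:
        raise ValueError("reference and observed temperatures must differ")
    return math.exp(math.log(observed_min / t_ref_min) * 10.0 / (T_ref_C - T_obs_C))


def refine_coefficient(
    t_ref_min: float,
    T_ref_C: float,
    observed_min: float,
    T_obs_C: float,
    bounds: tuple[float, float] = (1.5, 6.0),
    tol: float = 1e-6,
) -> float:
    """Solve t_ref * A**((T_ref - T_obs)/10) = observed for A by bisection.

    The map A -> predicted time is strictly monotone for T_obs != T_ref, so
    bisection converges; iteration stops when the predicted time matches the
    observation to relative tolerance ``tol``.  Raises BracketingError when
    the bounds do not straddle the solution.
    """
    if t_ref_min <= 0 or observed_min <= 0:
        raise ValueError("durations must be positive")
    a_lo, a_hi = bounds
    if not 0 < a_lo < a_hi:
        raise ValueError("bounds must satisfy 0 < A_lo < A_hi")
    exponent = (T_ref_C - T_obs_C) / 10.0
    if exponent == 0:
        raise ValueError("reference and observed temperatures must differ")

    def f(a: float) -> float:
        return t_ref_min * a**exponent - observed_min

    f_lo, f_hi = f(a_lo), f(a_hi)
    if f_lo == 0:
        return a_lo
    if f_hi == 0:
        return a_hi
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"bounds ({a_lo}, {a_hi}) do not bracket the coefficient"
        )
    for _ in range(200):
        a_mid = 0.5 * (a_lo + a_hi)
        f_mid = f(a_mid)
        if abs(f_mid) <= tol * observed_min:
            return a_mid
        if f_lo * f_mid < 0:
            a_hi, f_hi = a_mid, f_mid
        else:
            a_lo, f_lo = a_mid, f_mid
    return 0.5 * (a_lo + a_hi)


def shelf_life_table(
    model: VantHoffModel, temperatures_C: list[float]
) -> pd.DataFrame:
    """Predicted durations at each temperature, in minutes, days and months
    (1 month = 30.44 days)."""
    rows = []
    for T in temperatures_C:
        minutes = predict_time(model, T)
        rows.append(
            {
                "temperature_C": T,
                "minutes": minutes,
                "days": minutes / MINUTES_PER_DAY,
                "months": minutes / MINUTES_PER_DAY / DAYS_PER_MONTH,
            }
        )
    return pd.DataFrame(rows, columns=["temperature_C", "minutes", "days", "months"])


def activation_energy(
    p1: ArrheniusPoint, p2: ArrheniusPoint, R: float = R_GAS
) -> float:
    """Two-point Arrhenius activation energy in J/mol:
    E_A = R * T1*T2/(T1 - T2) * ln(k1/k2).

    Symmetric under swapping the points; raises on equal temperatures.
    """
    if p1.T_K == p2.T_K:
        raise ValueError("activation energy needs two distinct temperatures")
    return R * (p1.T_K * p2.T_K / (p1.T_K - p2.T_K)) * math.log(p1.k / p2.k)


def q10_equivalent(E_A: float, T_K: float, R: float = R_GAS) -> float:
    """Temperature coefficient implied by an activation energy at T:
    A = exp(10 * E_A / (R * T^2))."""
    if T_K <= 0:
        raise ValueError("temperature must be positive kelvin")
    return math.exp(10.0 * E_A / (R * T_K**2))


@dataclass(frozen=True)
class ValidityVerdict:
    verdict: str  # "consistent" | "inconsistent"
    E_A_arrhenius: float  # J/mol, from the rate-constant pair
    E_A_vant_hoff: float  # J/mol, implied by A at the mean temperature
    relative_difference: float


def vant_hoff_validity(
    A: float,
    p1: ArrheniusPoint,
    p2: ArrheniusPoint,
    rtol: float = 0.5,
    R: float = R_GAS,
) -> ValidityVerdict:
    """Compare the activation energy from the rate-constant pair with the one
    implied by the Q10 coefficient A at the mean kelvin temperature
    (E_A = R * T_mid^2 * ln(A) / 10).  Both values are always reported; the
    verdict is 'consistent' iff their relative difference is <= rtol."""
    e_arr = activation_energy(p1, p2, R=R)
    t_mid = 0.5 * (p1.T_K + p2.T_K)
    e_vh = R * t_mid**2 * math.log(A) / 10.0
    denom = max(abs(e_arr), abs(e_vh))
    rel = 0.0 if denom == 0 else abs(e_arr - e_vh) / denom
    verdict = "consistent" if rel <= rtol else "inconsistent"
    return ValidityVerdict(verdict, e_arr, e_vh, rel)


def rate_constant_from_stage(fit: LinearFit, initial: float) -> float:
    """Fractional change per minute of a stage: |slope| / initial value.

    This is the first-order rate a linear stage implies at its start, and the
    convention used to feed stage fits into the Arrhenius comparison."""
    if initial == 0:
        raise ValueError("initial value must be nonzero")
    return abs(fit.slope) / abs(initial)
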
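"""Stern-Volmer analysis of albumin fluorescence quenching by nanoparticles.

The model is F0/F = 1 + k*[Q]: relative fluorescence intensity (RFI) rises
linearly with quencher concentration with a fixed intercept of 1.  The
quenching constant k (in 1/uM, since Q is expressed in uM Fe3+) is fitted by
least squares through that fixed intercept; C50 = 1/k is the quencher
concentration that halves the fluorescence.  Comparing k at two temperatures
classifies the mechanism: a temperature-independent slope indicates static
(ground-state complex) quenching, a slope that rises significantly with
temperature indicates dynamic (collisional) quenching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from nanoshelf.data_model_io import Protein, QuenchSeries

__all__ = [
    "QuenchFit",
    "MechanismCall",
    "relative_fluorescence",
    "fit_quenching_constant",
    "c50",
    "classify_mechanism",
]

INTERCEPT_WARN_TOL = 0.05


@dataclass(frozen=True)
class QuenchFit:
    """Stern-Volmer fit with the intercept constrained to 1.

    ``free_intercept`` and ``free_slope`` come from an unconstrained
    diagnostic fit; ``intercept_warning`` is set when the free intercept
    strays more than 5 % from 1, which flags curvature or baseline problems.
    """

    k: float  # quenching constant, 1/uM
    k_se: float
    n_points: int
    r_squared: float
    protein: Protein
    temperature_C: float
    pH: float
    free_intercept: float = float("nan")
    free_slope: float = float("nan")
    intercept_warning: bool = False

    @property
    def dof(self) -> int:
        return self.n_points - 1


class DegenerateDesignError(ValueError):
    """All quencher concentrations identical: slope is unidentifiable."""


class UndefinedC50Error(ValueError):
    """k <= 0: fluorescence never falls to half its baseline."""


def relative_fluorescence(series: QuenchSeries) -> pd.DataFrame:
    """Table of (q_uM, rfi) with rfi = F0/F; rfi at q = 0 is exactly 1."""
    f0 = series.f0
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    rows = []
    for p in series.points:
        if p.fluorescence <= 0:
            raise ValueError(f"non-positive fluorescence at q = {p.q_uM}")
        rfi = 1.0 if p.q_uM == 0 else f0 / p.fluorescence
        rows.append({"q_uM": p.q_uM, "rfi": rfi})
    return pd.DataFrame(rows)


def fit_quenching_constant(series: QuenchSeries) -> QuenchFit:
    """Fit k in F0/F = 1 + k q by least squares through the fixed intercept.

    The estimator is k = sum(q*(rfi-1)) / sum(q^2) over the q > 0 points.

    The standard error propagates the fluorescence error model rather than
    treating residuals as iid: intensities carry multiplicative noise, so
    rfi = F0/F inherits a *shared* error from the q = 0 baseline (variance
    proportional to rfi^2, correlated across the ladder and partly collinear
    with the slope) on top of an independent per-point error, also
    proportional to rfi.  Writing the error vector as
    e = eps0*u - diag(u)*eps with u the rfi profile, the slope error is
    q'e/q'q, giving Var(k) = sigma^2 * ((q'u)^2 + sum(q^2 u^2)) / (q'q)^2;
    sigma^2 is estimated from the residual sum of squares divided by its
    expectation coefficient ||(I-P)u||^2 + tr(D(I-P)D) under the same model
    (P the projection onto q).  R^2 is the fraction of sum((rfi-1)^2)
    explained.  A free-intercept ordinary least squares fit is run alongside
    as a linearity diagnostic.
    """
    table = relative_fluorescence(series)
    pos = table[table.q_uM > 0]
    if len(pos) < 3:
        raise ValueError("need at least 3 points with q > 0")
    q = pos.q_uM.to_numpy()
    y = pos.rfi.to_numpy() - 1.0
    if np.ptp(q) == 0:
        raise DegenerateDesignError("all q values identical")

    sqq = float(np.sum(q * q))
    k = float(np.sum(q * y) / sqq)
    resid = y - k * q
    u = 1.0 + k * q  # fitted rfi profile
    proj_u = q * float(np.sum(q * u)) / sqq
    u_perp2 = float(np.sum((u - proj_u) ** 2))
    tr_term = float(np.sum(u * u) - np.sum((q * u) ** 2) / sqq)
    denom = u_perp2 + tr_term
    sigma2 = float(np.sum(resid**2)) / denom if denom > 0 else 0.0
    var_k = sigma2 * (float(np.sum(q * u)) ** 2 + float(np.sum(q * q * u * u))) / sqq**2
    k_se = math.sqrt(var_k)
    ss_tot = float(np.sum(y**2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot

    ols = stats.linregress(q, pos.rfi.to_numpy())
    warn = abs(ols.intercept - 1.0) > INTERCEPT_WARN_TOL

    return QuenchFit(
        k=k,
        k_se=k_se,
        n_points=len(table),
        r_squared=r_squared,
        protein=series.protein,
        temperature_C=series.temperature_C,
        pH=series.pH,
        free_intercept=float(ols.intercept),
        free_slope=float(ols.slope),
        intercept_warning=bool(warn),
    )


def c50(fit: QuenchFit) -> float:
    """Quencher concentration (uM) at which F = F0/2, i.e. 1/k."""
    if fit.k <= 0:
        raise UndefinedC50Error("C50 undefined for k <= 0")
    return 1.0 / fit.k


@dataclass(frozen=True)
class MechanismCall:
    mechanism: str  # "static" or "dynamic"
    statistic: float
    p_value: float
    alpha: float
    note: str = ""


def classify_mechanism(
    fit_low_T: QuenchFit, fit_high_T: QuenchFit, alpha: float = 0.05
) -> MechanismCall:
    """Static vs dynamic quenching from two fits at different temperatures.

    Welch-style two-sided test on the slope difference using k +- k_se.  A
    non-significant difference, or a significant *decrease* with temperature,
    is called static (dynamic quenching requires the constant to grow with
    temperature); a significant increase is called dynamic.  When both
    standard errors are zero the comparison is exact.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fit_low_T.protein != fit_high_T.protein or fit_low_T.pH != fit_high_T.pH:
        raise ValueError("fits must share protein and pH")
    lo, hi = fit_low_T, fit_high_T
    if lo.temperature_C > hi.temperature_C:
        lo, hi = hi, lo

    diff = hi.k - lo.k
    var = lo.k_se**2 + hi.k_se**2
    if var == 0:
        if diff == 0:
            return MechanismCall("static", 0.0, 1.0, alpha, "exact comparison")
        mech = "dynamic" if diff > 0 else "static"
        note = "exact comparison" + (
            "; k decreases with temperature" if diff < 0 else ""
        )
        return MechanismCall(mech, math.copysign(math.inf, diff), 0.0, alpha, note)

    t_stat = diff / math.sqrt(var)
    # Welch-Satterthwaite degrees of freedom from the two fits
    df = var**2 / (
        lo.k_se**4 / max(lo.dof, 1) + hi.k_se**4 / max(hi.dof, 1)
    )
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    if p >= alpha:
        return MechanismCall("static", t_stat, p, alpha)
    if diff > 0:
        return MechanismCall("dynamic", t_stat, p, alpha)
    return MechanismCall(
        "static", t_stat, p, alpha, "significant decrease with temperature"
    )
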
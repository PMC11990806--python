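"""Turbidity-coefficient computations and TEM cluster-area summaries.

Light passing a colloidal suspension is attenuated as I = I0 * exp(-tau*l),
so the turbidity coefficient is tau = ln(I0/I)/l.  Turbidity factors as
tau = n * C with n the particle number density and C the per-particle
scattering cross-section, here taken as C = Q*pi*d**2 with Q the scattering
efficiency (a ``convention`` switch selects the geometric-cross-section form
Q*pi*d**2/4 instead).

Cluster morphometry reduces TEM cluster-area sets to median and quartiles
(linear interpolation between order statistics) and fold changes of medians
between conditions — e.g. aggregation induced by a protein corona.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from nanoshelf.data_model_io import ClusterAreaSet

__all__ = [
    "TurbiditySummary",
    "AreaSummary",
    "turbidity_coefficient",
    "scattering_cross_section",
    "particle_count",
    "relative_turbidity_change",
    "summarize_areas",
    "fold_change",
]


@dataclass(frozen=True)
class TurbiditySummary:
    tau: float
    relative_change_percent: float
    wavelength_nm: float
    window: tuple[float, float]


@dataclass(frozen=True)
class AreaSummary:
    median_nm2: float
    q25_nm2: float
    q75_nm2: float
    n: int


def turbidity_coefficient(transmitted_fraction: float, path_length: float) -> float:
    """tau = ln(1/(I/I0)) / l from the transmitted fraction."""
    if not 0 < transmitted_fraction <= 1:
        raise ValueError("transmitted_fraction must be in (0, 1]")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    return math.log(1.0 / transmitted_fraction) / path_length


def scattering_cross_section(
    d_nm: float, Q: float, convention: str = "replication"
) -> float:
    """Per-particle scattering cross-section from diameter and efficiency Q.

    ``convention='replication'`` uses C = Q*pi*d**2; ``'geometric'`` uses the
    textbook geometric cross-section C = Q*pi*d**2/4.
    """
    if d_nm <= 0:
        raise ValueError("diameter must be positive")
    if Q < 0:
        raise ValueError("Q must be >= 0")
    c = Q * math.pi * d_nm**2
    if convention == "replication":
        return c
    if convention == "geometric":
        return c / 4.0
    raise ValueError(f"unknown convention {convention!r}")


def particle_count(tau: float, C: float) -> float:
    """Number density n = tau / C (in tau's implied units)."""
    if C <= 0:
        raise ValueError("cross-section C must be positive")
    return tau / C


def relative_turbidity_change(index_start: float, index_end: float) -> float:
    """Percent drop of an instrument turbidity index over a window:
    100 * (start - end) / start.  Operates on the raw optical-density index
    without unit conversion."""
    if index_start <= 0:
        raise ValueError("index_start must be positive")
    return 100.0 * (index_start - index_end) / index_start


def summarize_areas(areas: ClusterAreaSet) -> AreaSummary:
    """Median and quartiles of a cluster-area set (linear-interpolation
    quantile convention); permutation-invariant."""
    a = np.asarray(areas.areas_nm2, dtype=float)
    q25, med, q75 = np.percentile(a, [25, 50, 75], method="linear")
    return AreaSummary(
        median_nm2=float(med), q25_nm2=float(q25), q75_nm2=float(q75), n=len(a)
    )


def fold_change(median_b_nm2: float, median_a_nm2: float) -> float:
    """Ratio of medians (condition b over condition a)."""
    if median_a_nm2 <= 0:
        raise ValueError("reference median must be positive")
    return median_b_nm2 / median_a_nm2
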
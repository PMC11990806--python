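"""Seeded generators for kinetic, quenching, turbidity and cluster-area data.

The generators reproduce the statistical structure the downstream analysis
assumes, so every stage of the pipeline can be exercised without instrument
exports:

* two-stage piecewise-linear aging kinetics (a decrease-only stage followed
  by an increase-only stage, or vice versa), optionally paired across two
  temperatures with the time axis stretched by the Van't Hoff factor
  ``A**((T_ref - T_target)/10)``;
* linear Stern-Volmer quenching ladders, ``F(q) = F0 / (1 + k q)``;
* exponentially attenuated light transmission with a slow turbidity drift;
* lognormal TEM cluster-area distributions.

Noise conventions: additive Gaussian for kinetic channels, multiplicative
Gaussian for fluorescence intensities (positive, scale-proportional).
Concentration and size channels are clipped at zero; PDI is clipped to
[0, 1].  Identical seeds give bit-identical output.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, model_validator

from nanoshelf.data_model_io import (
    Channel,
    ClusterAreaSet,
    Condition,
    KineticSample,
    KineticSeries,
    Protein,
    QuenchPoint,
    QuenchSeries,
    TurbidityRecord,
)

__all__ = [
    "TwoStageSpec",
    "PairedSpec",
    "gen_two_stage_series",
    "gen_paired_series",
    "gen_quench_series",
    "gen_cluster_areas",
    "gen_turbidity_series",
    "two_stage_mean",
    "stretch_factor",
]


class TwoStageSpec(BaseModel):
    """Piecewise-linear mean with one breakpoint and Gaussian noise.

    The noiseless mean at time t is
    ``initial_value + slope1 * min(t, bp) + slope2 * max(0, t - bp)``.
    """

    initial_value: float
    slope1: float
    breakpoint_min: float = Field(gt=0)
    slope2: float
    noise_sd: float = Field(ge=0, default=0.0)
    timepoints_min: list[float]
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TwoStageSpec":
        if not self.timepoints_min:
            raise ValueError("timepoints_min must not be empty")
        if any(
            b <= a for a, b in zip(self.timepoints_min, self.timepoints_min[1:])
        ):
            raise ValueError("timepoints must be strictly increasing")
        lo, hi = self.timepoints_min[0], self.timepoints_min[-1]
        if not lo < self.breakpoint_min < hi:
            raise ValueError("breakpoint must lie strictly inside the time range")
        if self.slope1 * self.slope2 > 0:
            raise ValueError(
                "stages must be unidirectional: slopes of opposite sign or zero"
            )
        return self


class PairedSpec(BaseModel):
    """A reference two-stage series plus its Van't Hoff-scaled counterpart."""

    base: TwoStageSpec
    A: float = Field(gt=1)
    T_ref_C: float
    T_target_C: float

    @model_validator(mode="after")
    def _check(self) -> "PairedSpec":
        if self.T_ref_C == self.T_target_C:
            raise ValueError("T_ref_C and T_target_C must differ")
        return self


def stretch_factor(A: float, T_ref_C: float, T_target_C: float) -> float:
    """Time-axis stretch A**((T_ref - T_target)/10) between two temperatures."""
    return A ** ((T_ref_C - T_target_C) / 10.0)


def two_stage_mean(spec: TwoStageSpec, t: np.ndarray) -> np.ndarray:
    """Noiseless piecewise-linear mean of the two-stage model."""
    t = np.asarray(t, dtype=float)
    bp = spec.breakpoint_min
    return (
        spec.initial_value
        + spec.slope1 * np.minimum(t, bp)
        + spec.slope2 * np.maximum(0.0, t - bp)
    )


def _clip_for_channel(values: np.ndarray, channel: Channel) -> np.ndarray:
    if channel is Channel.pdi:
        return np.clip(values, 0.0, 1.0)
    return np.maximum(values, 0.0)


def gen_two_stage_series(
    spec: TwoStageSpec, condition: Condition, channel: Channel
) -> KineticSeries:
    """Generate one kinetic series from a two-stage spec.

    Additive Gaussian noise of sd ``spec.noise_sd`` is drawn from
    ``numpy.random.default_rng(spec.seed)``; values are clipped at zero for
    nonnegative channels (and to [0, 1] for PDI).
    """
    t = np.asarray(spec.timepoints_min, dtype=float)
    mean = two_stage_mean(spec, t)
    rng = np.random.default_rng(spec.seed)
    values = mean + rng.normal(0.0, spec.noise_sd, size=t.shape)
    values = _clip_for_channel(values, channel)
    samples = [
        KineticSample(**{"time_min": ti, channel.value: vi})
        for ti, vi in zip(t, values)
    ]
    return KineticSeries(condition=condition, samples=samples)


def gen_paired_series(
    spec: PairedSpec,
    condition_ref: Condition,
    condition_target: Condition,
    channel: Channel = Channel.fe_supernatant,
) -> tuple[KineticSeries, KineticSeries]:
    """Generate matched series at T_ref and T_target.

    The target series is the base series with its time axis stretched by
    ``A**((T_ref - T_target)/10)``: timepoints and breakpoint scale by the
    factor, slopes divide by it, so noiseless threshold-crossing times scale
    by exactly the stretch factor.  The target draws noise from seed+1 so the
    two series are independent.
    """
    s = stretch_factor(spec.A, spec.T_ref_C, spec.T_target_C)
    base = spec.base
    target_spec = base.model_copy(
        update={
            "slope1": base.slope1 / s,
            "slope2": base.slope2 / s,
            "breakpoint_min": base.breakpoint_min * s,
            "timepoints_min": [t * s for t in base.timepoints_min],
            "seed": base.seed + 1,
        }
    )
    ref = gen_two_stage_series(base, condition_ref, channel)
    target = gen_two_stage_series(target_spec, condition_target, channel)
    return ref, target


def gen_quench_series(
    k: float,
    F0: float,
    q_grid: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    protein: Protein = Protein.HSA,
    temperature_C: float = 25.0,
    pH: float = 7.4,
) -> QuenchSeries:
    """Generate a Stern-Volmer ladder: F(q) = F0/(1 + k q) with
    multiplicative Gaussian noise of relative sd ``noise_sd``.

    The q = 0 baseline must be part of the grid (it defines F0).
    """
    if k < 0:
        raise ValueError("quenching constant k must be >= 0")
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    q = np.asarray(q_grid, dtype=float)
    if not (q == 0).any():
        raise ValueError("q_grid must contain 0 (the F0 baseline)")
    rng = np.random.default_rng(seed)
    f = F0 / (1.0 + k * q)
    f = f * (1.0 + rng.normal(0.0, noise_sd, size=q.shape))
    f = np.maximum(f, np.finfo(float).tiny)
    points = [QuenchPoint(q_uM=qi, fluorescence=fi) for qi, fi in zip(q, f)]
    return QuenchSeries(
        protein=protein, temperature_C=temperature_C, pH=pH, points=points
    )


def gen_cluster_areas(
    n: int, median_nm2: float, sigma_log: float, seed: int = 0, label: str = "synthetic"
) -> ClusterAreaSet:
    """Lognormal cluster-area sample with the given median (nm^2).

    For a lognormal, the median equals exp(mu), so areas are
    ``median * exp(sigma_log * Z)`` with Z standard normal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if median_nm2 <= 0:
        raise ValueError("median_nm2 must be positive")
    if sigma_log < 0:
        raise ValueError("sigma_log must be >= 0")
    rng = np.random.default_rng(seed)
    areas = median_nm2 * np.exp(sigma_log * rng.standard_normal(n))
    return ClusterAreaSet(label=label, areas_nm2=areas.tolist())


def gen_turbidity_series(
    tau: float,
    path_length: float,
    timepoints_min: list[float],
    drift_per_min: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength_nm: float = 450.0,
) -> list[TurbidityRecord]:
    """Transmitted-light kinetics: I/I0 = exp(-(tau + drift*t) * l) + noise.

    Additive Gaussian noise on the transmitted fraction, clipped to (0, 1].
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if path_length <= 0:
        raise ValueError("path_length must be positive")
    t = np.asarray(timepoints_min, dtype=float)
    rng = np.random.default_rng(seed)
    frac = np.exp(-(tau + drift_per_min * t) * path_length)
    frac = frac + rng.normal(0.0, noise_sd, size=t.shape)
    frac = np.clip(frac, np.finfo(float).tiny, 1.0)
    return [
        TurbidityRecord(
            time_min=ti,
            wavelength_nm=wavelength_nm,
            transmitted_fraction=fi,
            path_length=path_length,
        )
        for ti, fi in zip(t, frac)
    ]
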
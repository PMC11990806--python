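"""Domain types and CSV readers/writers for the analysis pipeline.

All times are kept internally in minutes (storage days are converted on read,
1 day = 1440 min) so that stress-test and storage kinetics share one axis.
Measurement channels may be missing per row — iron is only measured on
supernatants after centrifugation — so :class:`KineticSample` allows any
subset of channels as long as at least one is present.

Structural validity (types, enums, orderings) is enforced at construction by
pydantic; *scientific* invariants (PDI range, pH range, minimum sample
counts) are checked by :func:`validate_series`, which reports findings
instead of raising, so that suspect instrument exports can still be loaded
and inspected.
"""

from __future__ import annotations

import enum
import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

MINUTES_PER_DAY = 1440.0
DAYS_PER_MONTH = 30.44

KINETICS_COLUMNS = [
    "time",
    "time_unit",
    "temperature_C",
    "protein",
    "protein_mg_per_ml",
    "pH",
    "fe_supernatant_ug_per_ml",
    "z_avg_nm",
    "pdi",
]
QUENCH_COLUMNS = ["protein", "temperature_C", "pH", "q_uM", "fluorescence"]
AREAS_COLUMNS = ["label", "area_nm2"]
TURBIDITY_COLUMNS = [
    "time_min",
    "wavelength_nm",
    "transmitted_fraction",
    "path_length",
    "turbidity_index",
]


class FormatError(ValueError):
    """A file does not have the expected tabular layout."""


class ValidationError(ValueError):
    """Data parsed fine but violates a scientific invariant."""


class Protein(str, enum.Enum):
    none = "none"
    BSA = "BSA"
    HSA = "HSA"


class Channel(str, enum.Enum):
    fe_supernatant = "fe_supernatant_ug_per_ml"
    z_avg = "z_avg_nm"
    pdi = "pdi"


class Condition(BaseModel):
    """Experimental context: temperature, protein load, pH and total iron."""

    model_config = ConfigDict(frozen=True)

    temperature_C: float
    protein: Protein = Protein.none
    protein_mg_per_ml: float = 0.0
    pH: float = 7.4
    fe_total_ug_per_ml: float = 50.0

    def label(self) -> str:
        return (
            f"T={self.temperature_C:g}C/{self.protein.value}"
            f"@{self.protein_mg_per_ml:g}mg_mL/pH={self.pH:g}"
        )


class KineticSample(BaseModel):
    """One time point; any subset of channels, but at least one present."""

    time_min: float = Field(ge=0)
    fe_supernatant_ug_per_ml: float | None = None
    z_avg_nm: float | None = None
    pdi: float | None = None

    @model_validator(mode="after")
    def _at_least_one_channel(self) -> "KineticSample":
        if all(
            getattr(self, ch.value) is None for ch in Channel
        ):
            raise ValueError("kinetic sample has no measurement channel")
        return self

    def channel(self, channel: Channel) -> float | None:
        return getattr(self, channel.value)


class KineticSeries(BaseModel):
    condition: Condition
    samples: list[KineticSample]

    @model_validator(mode="after")
    def _times_increasing(self) -> "KineticSeries":
        times = [s.time_min for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        return self

    def times(self, channel: Channel | None = None) -> list[float]:
        if channel is None:
            return [s.time_min for s in self.samples]
        return [s.time_min for s in self.samples if s.channel(channel) is not None]

    def values(self, channel: Channel) -> list[float]:
        return [
            v for s in self.samples if (v := s.channel(channel)) is not None
        ]


class QuenchPoint(BaseModel):
    q_uM: float = Field(ge=0)
    fluorescence: float = Field(gt=0)


class QuenchSeries(BaseModel):
    """Fluorescence vs quencher ladder at fixed protein/temperature/pH.

    Exactly one point must sit at q = 0: it defines the baseline F0.
    """

    protein: Protein
    temperature_C: float
    pH: float
    points: list[QuenchPoint]

    @model_validator(mode="after")
    def _ladder(self) -> "QuenchSeries":
        qs = [p.q_uM for p in self.points]
        if sum(q == 0 for q in qs) != 1:
            raise ValueError("no F0 baseline: exactly one q_uM = 0 point required")
        if any(b <= a for a, b in zip(qs, qs[1:])):
            raise ValueError("q values must be strictly increasing")
        return self

    @property
    def f0(self) -> float:
        return next(p.fluorescence for p in self.points if p.q_uM == 0)


class ClusterAreaSet(BaseModel):
    label: str
    areas_nm2: list[float]

    @model_validator(mode="after")
    def _positive(self) -> "ClusterAreaSet":
        if len(self.areas_nm2) < 1:
            raise ValueError("at least one cluster area required")
        if any(a <= 0 for a in self.areas_nm2):
            raise ValueError("cluster areas must be positive")
        return self


class TurbidityRecord(BaseModel):
    time_min: float
    wavelength_nm: float
    transmitted_fraction: float = Field(gt=0, le=1)
    path_length: float = Field(gt=0)
    turbidity_index: float | None = Field(default=None, ge=0)


# ---------------------------------------------------------------------------
# validation findings


class Finding(BaseModel):
    """One violated invariant, pointing at the offending sample index."""

    invariant: str
    sample_index: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" at {self.sample_index}" if self.sample_index is not None else ""
        return f"{self.invariant}{loc}"


def validate_series(series: KineticSeries) -> list[Finding]:
    """Check scientific invariants; return findings (empty list = valid)."""
    findings: list[Finding] = []
    cond = series.condition
    if not -20 <= cond.temperature_C <= 120:
        findings.append(Finding(invariant="temperature_C out of [-20,120]"))
    if not 0 <= cond.pH <= 14:
        findings.append(Finding(invariant="pH out of [0,14]"))
    if cond.protein_mg_per_ml < 0:
        findings.append(Finding(invariant="protein_mg_per_ml negative"))
    if cond.protein is Protein.none and cond.protein_mg_per_ml != 0:
        findings.append(Finding(invariant="protein=none but protein_mg_per_ml != 0"))
    if cond.fe_total_ug_per_ml <= 0:
        findings.append(Finding(invariant="fe_total_ug_per_ml not positive"))
    if len(series.samples) < 2:
        findings.append(Finding(invariant="fewer than 2 samples"))
    for i, s in enumerate(series.samples):
        if s.pdi is not None and not 0 <= s.pdi <= 1:
            findings.append(Finding(invariant="pdi out of [0,1]", sample_index=i))
        if s.z_avg_nm is not None and s.z_avg_nm <= 0:
            findings.append(Finding(invariant="z_avg_nm not positive", sample_index=i))
        if s.fe_supernatant_ug_per_ml is not None and s.fe_supernatant_ug_per_ml < 0:
            findings.append(
                Finding(invariant="fe_supernatant negative", sample_index=i)
            )
    return findings


# ---------------------------------------------------------------------------
# CSV I/O

_CONDITION_COLS = ["temperature_C", "protein", "protein_mg_per_ml", "pH"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_kinetics_csv(
    path: str | Path, time_unit: str = "min"
) -> list[KineticSeries]:
    """Read kinetic series from CSV, grouped by experimental condition.

    ``time_unit`` ("min" or "day") is the default when the file carries no
    ``time_unit`` column; a per-row column takes precedence.  Day times are
    converted to minutes.  Rows sharing a condition and an optional
    ``replicate`` column are averaged per time point on load.
    """
    path = Path(path)
    if time_unit not in ("min", "day"):
        raise ValueError(f"time_unit must be 'min' or 'day', got {time_unit!r}")
    df = pd.read_csv(path, float_precision='round_trip')
    _require_columns(df, ["time", "temperature_C", "protein", "pH"], path)
    channels = [c.value for c in Channel if c.value in df.columns]
    if not channels:
        raise FormatError(f"{path}: no measurement channel column present")

    if "time_unit" not in df.columns:
        df = df.assign(time_unit=time_unit)
    df["time_unit"] = df["time_unit"].fillna(time_unit)
    bad_units = set(df["time_unit"].unique()) - {"min", "day"}
    if bad_units:
        raise FormatError(f"{path}: unknown time_unit value(s) {sorted(bad_units)}")
    df["time_min"] = df["time"].where(
        df["time_unit"] == "min", df["time"] * MINUTES_PER_DAY
    )
    if "protein_mg_per_ml" not in df.columns:
        df = df.assign(protein_mg_per_ml=0.0)
    if "fe_total_ug_per_ml" not in df.columns:
        df = df.assign(fe_total_ug_per_ml=50.0)

    if "replicate" in df.columns:
        group_cols = _CONDITION_COLS + ["fe_total_ug_per_ml", "time_min"]
        df = df.groupby(group_cols, as_index=False, sort=False)[channels].mean()

    series: list[KineticSeries] = []
    for key, grp in df.groupby(
        _CONDITION_COLS + ["fe_total_ug_per_ml"], sort=False
    ):
        temperature, protein, prot_mg, ph, fe_total = key
        grp = grp.sort_values("time_min")
        if grp["time_min"].duplicated().any():
            raise ValidationError(
                f"{path}: duplicate time points within condition "
                f"(T={temperature}, protein={protein}, pH={ph})"
            )
        cond = Condition(
            temperature_C=temperature,
            protein=Protein(protein),
            protein_mg_per_ml=prot_mg,
            pH=ph,
            fe_total_ug_per_ml=fe_total,
        )
        samples = []
        for _, row in grp.iterrows():
            fields = {"time_min": row["time_min"]}
            for ch in channels:
                v = row[ch]
                fields[ch] = None if pd.isna(v) else float(v)
            samples.append(KineticSample(**fields))
        series.append(KineticSeries(condition=cond, samples=samples))
    return series


def write_kinetics_csv(series: Iterable[KineticSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        c = s.condition
        for sample in s.samples:
            rows.append(
                {
                    "time": sample.time_min,
                    "time_unit": "min",
                    "temperature_C": c.temperature_C,
                    "protein": c.protein.value,
                    "protein_mg_per_ml": c.protein_mg_per_ml,
                    "pH": c.pH,
                    "fe_total_ug_per_ml": c.fe_total_ug_per_ml,
                    "fe_supernatant_ug_per_ml": sample.fe_supernatant_ug_per_ml,
                    "z_avg_nm": sample.z_avg_nm,
                    "pdi": sample.pdi,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format='%.17g')


def read_quench_csv(path: str | Path) -> list[QuenchSeries]:
    """Read fluorescence-quenching ladders, one series per (protein, T, pH)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision='round_trip')
    _require_columns(df, QUENCH_COLUMNS, path)
    series = []
    for (protein, temperature, ph), grp in df.groupby(
        ["protein", "temperature_C", "pH"], sort=False
    ):
        grp = grp.sort_values("q_uM")
        if not (grp["q_uM"] == 0).any():
            raise ValidationError(
                f"{path}: no F0 baseline (q_uM = 0 row) for "
                f"{protein}/{temperature}C/pH{ph}"
            )
        points = [
            QuenchPoint(q_uM=row.q_uM, fluorescence=row.fluorescence)
            for row in grp.itertuples()
        ]
        series.append(
            QuenchSeries(
                protein=Protein(protein),
                temperature_C=temperature,
                pH=ph,
                points=points,
            )
        )
    return series


def write_quench_csv(series: Iterable[QuenchSeries], path: str | Path) -> None:
    rows = [
        {
            "protein": s.protein.value,
            "temperature_C": s.temperature_C,
            "pH": s.pH,
            "q_uM": p.q_uM,
            "fluorescence": p.fluorescence,
        }
        for s in series
        for p in s.points
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format='%.17g')


def read_areas_csv(path: str | Path) -> list[ClusterAreaSet]:
    path = Path(path)
    df = pd.read_csv(path, float_precision='round_trip')
    _require_columns(df, AREAS_COLUMNS, path)
    return [
        ClusterAreaSet(label=str(label), areas_nm2=grp["area_nm2"].tolist())
        for label, grp in df.groupby("label", sort=False)
    ]


def write_areas_csv(sets: Iterable[ClusterAreaSet], path: str | Path) -> None:
    rows = [
        {"label": s.label, "area_nm2": a} for s in sets for a in s.areas_nm2
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format='%.17g')


def read_turbidity_csv(path: str | Path) -> list[TurbidityRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision='round_trip')
    _require_columns(
        df, ["time_min", "wavelength_nm", "transmitted_fraction", "path_length"], path
    )
    records = []
    for row in df.itertuples():
        idx = getattr(row, "turbidity_index", None)
        if idx is not None and isinstance(idx, float) and math.isnan(idx):
            idx = None
        records.append(
            TurbidityRecord(
                time_min=row.time_min,
                wavelength_nm=row.wavelength_nm,
                transmitted_fraction=row.transmitted_fraction,
                path_length=row.path_length,
                turbidity_index=idx,
            )
        )
    return records


def write_turbidity_csv(records: Iterable[TurbidityRecord], path: str | Path) -> None:
    pd.DataFrame([r.model_dump() for r in records]).to_csv(path, index=False, float_format='%.17g')
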
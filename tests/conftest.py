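import numpy as np
import pytest

from nanoshelf.data_model_io import (
    Channel,
    Condition,
    KineticSample,
    KineticSeries,
    Protein,
)

# the instrument's quencher ladder, uM Fe3+
Q_LADDER = [0, 0.028, 0.056, 0.084, 0.112, 0.14, 0.168, 0.196, 0.224, 0.252]


@pytest.fixture
def condition_70C() -> Condition:
    return Condition(
        temperature_C=70, protein=Protein.HSA, protein_mg_per_ml=0.5, pH=7.4
    )


@pytest.fixture
def condition_8C() -> Condition:
    return Condition(
        temperature_C=8, protein=Protein.HSA, protein_mg_per_ml=0.5, pH=7.4
    )


@pytest.fixture
def iron_series(condition_70C) -> KineticSeries:
    """Noiseless linear iron decline: 12 ug/mL falling 0.0771 ug/mL/min."""
    times = [0.0, 30.0, 60.0, 120.0]
    return KineticSeries(
        condition=condition_70C,
        samples=[
            KineticSample(
                time_min=t, fe_supernatant_ug_per_ml=12.0 - 0.0771 * t
            )
            for t in times
        ],
    )


def make_series(times, values, channel=Channel.fe_supernatant, condition=None):
    condition = condition or Condition(temperature_C=70)
    return KineticSeries(
        condition=condition,
        samples=[
            KineticSample(**{"time_min": float(t), channel.value: float(v)})
            for t, v in zip(times, values)
        ],
    )
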
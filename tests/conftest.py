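import numpy as np
import pandas as pd
import pytest

from organclocks import (
    ClockConfig,
    CohortData,
    SimulationConfig,
    SurvivalSpec,
    TraitSpec,
    simulate_inputs,
)


def two_organ_config(seed: int = 0, n: int = 400, **kw) -> SimulationConfig:
    """A reduced two-organ study: brain + kidney, 20 probes each."""
    defaults = dict(
        n_subjects=n,
        organs=("brain", "kidney"),
        probes_per_organ=20,
        n_nonspecific=20,
        traits=(
            TraitSpec(name="cdr", kind="offset_linear", organ="brain", effect=1.0),
            TraitSpec(
                name="probe_trait", kind="probe_linear", organ="brain",
                effect=0.5, n_driver_probes=5,
            ),
            TraitSpec(name="hypertension", kind="disease", organ="kidney", beta=0.5),
        ),
        survival=SurvivalSpec(organ="kidney", theta=0.4),
        seed=seed,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_inputs():
    """Expression + panel + cohort + truth for a small two-organ study."""
    return simulate_inputs(two_organ_config(seed=7, n=400))


@pytest.fixture(scope="session")
def fast_clock_config():
    return ClockConfig(n_bootstraps=20, n_lambdas=25, seed=11)


@pytest.fixture()
def planted_cohort():
    """Noise-free cohort where one probe encodes age exactly.

    probe p0 = (age - 60) / 10 on the log10 scale; p1 and p2 are inert
    noise. A clock trained here must recover age almost perfectly.
    """
    rng = np.random.default_rng(42)
    n = 300
    age = rng.uniform(30, 100, n)
    proteins = pd.DataFrame(
        {
            "p0": (age - 60.0) / 10.0,
            "p1": rng.normal(0, 1, n),
            "p2": rng.normal(0, 1, n),
        }
    )
    meta = pd.DataFrame(
        {"age": age, "sex": rng.integers(0, 2, n).astype(float), "cohort": "x"}
    )
    return CohortData(proteins, meta)
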
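import numpy as np
import pandas as pd
import pytest

from opsccrna.io_core import CountsMatrix, SurvivalTable
from opsccrna.synthetic import SimulationConfig


@pytest.fixture
def toy_survival() -> SurvivalTable:
    """Four subjects, events at 1, 2, 3, 4 months, no censoring."""
    return SurvivalTable(
        pd.DataFrame(
            {"time_months": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]},
            index=pd.Index(["a", "b", "c", "d"], name="sample_id"),
        )
    )


@pytest.fixture
def small_counts() -> CountsMatrix:
    """Deterministic 4-gene x 6-sample matrix with two groups."""
    rng = np.random.default_rng(0)
    counts = rng.integers(10, 1000, size=(4, 6))
    meta = pd.DataFrame(
        {"group": ["A", "A", "A", "B", "B", "B"]},
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    return CountsMatrix(
        gene_ids=[f"g{i}" for i in range(4)],
        sample_ids=list(meta.index),
        counts=np.asarray(counts),
        gene_lengths_bp=np.array([1000, 2000, 500, 1500]),
        metadata=meta,
    )


def random_survival_table(rng: np.random.Generator, n: int, censor_frac: float = 0.3) -> SurvivalTable:
    t = rng.exponential(20.0, n) + 0.01
    e = (rng.random(n) > censor_frac).astype(int)
    return SurvivalTable(
        pd.DataFrame(
            {"time_months": t, "event": e},
            index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
        )
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig()
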
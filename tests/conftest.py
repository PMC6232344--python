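import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import herbnet as hn
from herbnet import datasets

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def candidates():
    """The packaged 32-compound candidate table."""
    return datasets.load_potential_compounds()


@pytest.fixture(scope="session")
def full_catalog(candidates):
    """Candidates plus the two animal-ingredient compounds."""
    animal = datasets.load_animal_compounds()
    return hn.CompoundTable(
        pd.concat([candidates.df, animal.df], ignore_index=True), provenance="fixture"
    )


@pytest.fixture(scope="session")
def taurine_block():
    return datasets.load_factorial_block("taurine")


@pytest.fixture(scope="session")
def ginsenoside_block():
    return datasets.load_factorial_block("ginsenoside")


def replicates_matching(design, cells, rows_per_cell=None):
    """Construct raw replicates reproducing each cell's (n, mean, sd) exactly."""
    rows = []
    for cell in cells:
        n = cell.n
        base = np.arange(n, dtype=float)
        base -= base.mean()
        base /= base.std(ddof=1)
        vals = cell.mean + cell.sd * base
        for v in vals:
            rows.append({**dict(zip(design.factors, cell.levels)), "response": v})
    return pd.DataFrame(rows)
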
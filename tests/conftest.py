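import numpy as np
import pandas as pd
import pytest

from soilrisk import pmf
from soilrisk.core_io import METALS, ReferenceTable, SampleTable
from soilrisk.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def reference() -> ReferenceTable:
    return ReferenceTable.default()


@pytest.fixture(scope="session")
def default_spec() -> GeneratorSpec:
    """The default synthetic survey: 252 points × 3 layers, 4 sources."""
    return GeneratorSpec(seed=7, noise_cv=0.05)


@pytest.fixture(scope="session")
def survey(default_spec):
    """Generated default survey with its ground-truth matrices."""
    return generate(default_spec)


@pytest.fixture(scope="session")
def pmf_base(survey, reference):
    """A 4-factor PMF fit of the default survey's surface layer
    (shared across tests; fitting is the expensive step)."""
    table, truth = survey
    X = table.concentrations("surface")
    U = pmf.build_uncertainty(X, reference)
    model = pmf.fit(X, U, p=4, n_starts=20, seed=1)
    return X, U, model, truth


def make_table(n: int = 5, seed: int = 0) -> SampleTable:
    """Small random but valid sample table for I/O tests."""
    rng = np.random.default_rng(seed)
    data = pd.DataFrame(
        {
            "sample_id": [f"P{i}" for i in range(n)],
            "x": rng.uniform(0, 100, n),
            "y": rng.uniform(0, 100, n),
            "depth_layer": rng.choice(["surface", "subsurface", "saturated"], n),
            "pH": rng.uniform(5, 9, n),
        }
    )
    for m in METALS:
        data[m] = rng.uniform(0.01, 50, n)
    return SampleTable(data=data)


@pytest.fixture
def small_table() -> SampleTable:
    return make_table()
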
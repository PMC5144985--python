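import numpy as np
import pandas as pd
import pytest

import ionqtl as iq


@pytest.fixture(scope="session")
def small_map() -> iq.GeneticMap:
    return iq.make_map(2, 21, 100.0)


@pytest.fixture(scope="session")
def geno300(small_map) -> pd.DataFrame:
    return iq.simulate_ril_genotypes(small_map, 300, seed=42)


@pytest.fixture()
def toy_cross(small_map, geno300) -> iq.Cross:
    """A 300-line cross with one additive QTL (effect 1 SD) on chr 1 at 50 cM."""
    rng = np.random.default_rng(7)
    q = small_map.nearest_marker(1, 50.0)
    y = geno300.to_numpy()[:, q] + rng.normal(0.0, 1.0, 300)
    traits = pd.DataFrame({"t": y}, index=geno300.index)
    return iq.Cross(small_map, geno300, traits, env_id="E1")


@pytest.fixture()
def seed_scenario() -> iq.SimScenario:
    return iq.SimScenario(
        n_lines=40,
        n_chr=2,
        markers_per_chr=10,
        chr_length_cm=100.0,
        environments=(
            iq.EnvironmentSpec("E1", 30, 4),
            iq.EnvironmentSpec("E2", 20, 1),
        ),
        traits=("Mo", "Cd"),
        residual_sd=1.0,
        measurement_sd=0.01,
        outlier_rate=0.0,
        rng_seed=11,
    )
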
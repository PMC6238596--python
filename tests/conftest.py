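import numpy as np
import pandas as pd
import pytest

from phosphodiff.synthetic import SimulationConfig, simulate_all


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-scale simulated study for unit tests."""
    base = dict(
        seed=11,
        n_proteins=300,
        n_phosphoproteins=150,
        n_decoy_reference_sites=200,
        map_n_species=10,
        map_n_reactions=6,
        map_n_phosphosites=5,
        map_n_pmids=3,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """One small simulated study on disk, shared across tests."""
    outdir = tmp_path_factory.mktemp("study")
    config = small_config()
    paths = simulate_all(config, outdir)
    return config, paths


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def quant_frame(values, prefix=("control", "acute", "chronic"), reps=None):
    """Build a quant matrix from a 2-D array with generated sample labels."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if reps is None:
        reps = n // len(prefix)
    cols = [f"{c}_{r + 1}" for c in prefix for r in range(reps)][:n]
    return pd.DataFrame(values, columns=cols,
                        index=[f"a{i}" for i in range(values.shape[0])])
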
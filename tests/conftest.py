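import numpy as np
import pandas as pd
import pytest

from vitismet import SimulationConfig, generate_peak_experiment, preprocess_chain
from vitismet.peaks import RESISTANT, SUSCEPTIBLE


SMALL_CONFIG = SimulationConfig(
    n_genotypes_resistant=4,
    n_genotypes_susceptible=3,
    n_features=300,
    n_discriminatory=40,
    missing_rate=0.1,
    seed=7,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A reduced two-group experiment (12 vs 9 samples, 300 features)."""
    lists, meta, truth = generate_peak_experiment(SMALL_CONFIG)
    return SMALL_CONFIG, lists, meta, truth


@pytest.fixture(scope="session")
def small_stages(small_experiment):
    config, lists, meta, _ = small_experiment
    return preprocess_chain(lists, meta, standard_mz=config.internal_standard_mz)


@pytest.fixture(scope="session")
def study_shaped_experiment():
    """Full study-sized experiment: 21 vs 12 samples, 2000 features, 190 planted."""
    config = SimulationConfig(seed=11)
    lists, meta, truth = generate_peak_experiment(config)
    stages = preprocess_chain(lists, meta, standard_mz=config.internal_standard_mz)
    return config, meta, truth, stages


def two_group_meta(n_res: int, n_sus: int) -> pd.DataFrame:
    """Minimal metadata with one genotype per sample (no replicate structure)."""
    rows = [(f"r{i}", f"gr{i}", 1, RESISTANT) for i in range(n_res)]
    rows += [(f"s{i}", f"gs{i}", 1, SUSCEPTIBLE) for i in range(n_sus)]
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "replicate", "group"])
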
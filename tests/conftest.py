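import numpy as np
import pandas as pd
import pytest

from polyeld.containers import CountTable
from polyeld.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def null_dataset():
    """All-additive, all-equal simulation: nothing should be called."""
    config = SimulationConfig(
        n_genes=1000, mean_expression=100, effect_fold=4,
        class_mix={"additive_equal": 1.0}, seed=11,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def planted_dataset():
    """Equal mixture of the strong-effect classes, all genes paired."""
    classes = ["additive_equal", "eld_A_up", "eld_A_down", "eld_C_up",
               "eld_C_down", "transgressive_up", "transgressive_down",
               "novel_bias"]
    config = SimulationConfig(
        n_genes=800, frac_paired=1.0, mean_expression=500, effect_fold=8,
        class_mix={k: 1 / len(classes) for k in classes}, seed=5,
    )
    return generate_dataset(config)


@pytest.fixture()
def tiny_counts():
    """Hand-sized table: 3 genes, 2 samples, 2 replicates, declared libs."""
    long = pd.DataFrame(
        {
            "gene_id": ["g1", "g1", "g1", "g1", "g2", "g2", "g2", "g2",
                        "g3", "g3", "g3", "g3"],
            "sample": ["X", "X", "Y", "Y"] * 3,
            "replicate": [1, 2, 1, 2] * 3,
            "count": [10, 12, 50, 48, 5, 7, 5, 7, 0, 0, 0, 0],
        }
    )
    libs = {("X", 1): 10_000, ("X", 2): 10_000,
            ("Y", 1): 10_000, ("Y", 2): 10_000}
    return CountTable.from_long(long, library_sizes=libs)
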
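import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     database=None, deadline=None)
hypothesis_settings.load_profile("deterministic")

from gliotad.core import SampleSheet, SignalMatrix
from gliotad.simulate import SimulationConfig, generate_genome, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_tads=20, genes_per_tad=5, n_enhancers=60,
        chrom_length=20_000_000, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    genes, tads, truth = generate_genome(small_config)
    return generate_cohort(genes, tads, truth, small_config)


@pytest.fixture
def two_group_sheet():
    ids = [f"PA{i}" for i in range(5)] + [f"GBM{i}" for i in range(5)]
    return SampleSheet(ids, ["PA"] * 5 + ["GBM"] * 5)


def make_matrix(values, feature_ids, sample_ids, kind="expression"):
    return SignalMatrix(
        pd.DataFrame(np.asarray(values, dtype=float),
                     index=feature_ids, columns=sample_ids),
        kind,
    )
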
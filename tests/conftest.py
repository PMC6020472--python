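import numpy as np
import pandas as pd
import pytest

from splicestress.expr_io import ExpressionDataset
from splicestress.synthetic_data import SimulationConfig


@pytest.fixture
def small_dataset() -> ExpressionDataset:
    """3 genes x 4 samples (2 control, 2 treated), log2 scale."""
    data = pd.DataFrame(
        [[1.0, 2.0, 5.0, 6.0],
         [4.0, 4.5, 1.0, 1.5],
         [3.0, 3.0, 3.0, 3.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = {"s1": "control", "s2": "control", "s3": "treated", "s4": "treated"}
    return ExpressionDataset(dataset_id="toy", data=data, group_of=groups)


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    """Small, fast simulation settings for smoke-level pipeline tests."""
    return SimulationConfig(
        seed=7,
        genes_total=200,
        pathway_sets={"spliceosome": 20},
        planted_effect={"spliceosome": -3.0},
        noise_sd=0.4,
        n_samples_splicing=6,
        background_events_per_sample=10,
        genes_per_cluster=20,
        transcript_stop_counts=(0, 1, 2, 3),
        n_planted_pairs=2,
        n_null_genes_per_set=3,
    )
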
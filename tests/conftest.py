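import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import factorde as fd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    """Balanced 48-sample design: 2 tissues x 2 treatments x 4 times x 3 reps."""
    return fd.generate_design(replicates=3, batches=2, seed=7)


@pytest.fixture(scope="session")
def small_dataset(design):
    """300 signal + 20 control + 30 flat probes with planted classes."""
    cfg = fd.SimulationConfig(
        n_probes=300, n_control_probes=20, n_flat_probes=30, seed=1
    )
    matrix, truth = fd.simulate_expression(design, cfg)
    annotation = fd.make_probe_annotation(truth, seed=2)
    return matrix, truth, annotation


@pytest.fixture(scope="session")
def filtered_dataset(design, small_dataset):
    matrix, truth, annotation = small_dataset
    filtered = fd.filter_probes(matrix, annotation, min_sd=0.1, min_mean=0.0)
    return filtered, truth, annotation


def random_matrix(design, n_probes, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(8.0, 1.0, size=(n_probes, len(design)))
    return pd.DataFrame(
        values,
        index=pd.Index([f"p{i:04d}" for i in range(n_probes)], name="probe_id"),
        columns=design["sample_id"],
    )
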
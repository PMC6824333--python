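import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from toxsig.data_model import ExpressionDataset
from toxsig.synthetic_data import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config():
    """Fast desk-scale study conditions for unit-level pipeline tests."""
    return SimulationConfig(
        n_genes=150,
        n_samples=(60, 60, 60),
        module_sizes=(15,) * 6,
        n_informative_modules=2,
        n_dose_genes=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's default study conditions (600 genes, 10 modules of 60,
    120 samples per dataset)."""
    return generate_bundle(SimulationConfig(seed=1234))


@pytest.fixture()
def toy_dataset():
    """Tiny complete expression matrix for arithmetic-level checks."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 3.0, 1.0, 5.0],
            "s2": [2.0, 4.0, 2.0, 1.5, 4.0],
            "s3": [3.0, 6.0, 1.0, 2.5, 6.0],
            "s4": [4.0, 8.0, 0.0, 2.0, 5.0],
        },
        index=["G1", "G2", "G3", "G4", "G5"],
    )
    return ExpressionDataset("toy", values)


def make_labels(dataset, flags):
    from toxsig.data_model import DYSREGULATED, NON_DYSREGULATED

    return pd.Series(
        np.where(np.asarray(flags, dtype=bool), DYSREGULATED, NON_DYSREGULATED),
        index=dataset.samples,
        name="label",
    )
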
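import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from srmtx.config import SyntheticConfig
from srmtx import synthetic

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale study conditions: 120 subjects, 20 regions, 300 genes."""
    return SyntheticConfig(
        n_subjects=120,
        n_regions_per_hemisphere=10,
        n_genes=300,
        n_srm_regions=3,
        annotation_size=40,
        ppi_module_size=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> synthetic.SyntheticDataset:
    return synthetic.generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset() -> synthetic.SyntheticDataset:
    """The default study conditions (248 subjects, 68 regions, 2000 genes)."""
    return synthetic.generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_trait_frame(values: np.ndarray) -> pd.DataFrame:
    """Trait table in the shape compute_srm expects, with exact scores."""
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(len(values))],
            "combined_score": values**2,
            "transformed_score": values,
        }
    )
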
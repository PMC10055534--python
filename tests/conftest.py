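import numpy as np
import pandas as pd
import pytest

from mirscreen import ScreenSimConfig, simulate_screen
from mirscreen.normalize import normalize_screen
from mirscreen.screen_qc import filter_low_count_wells


@pytest.fixture(scope="session")
def small_config():
    """One sequencing batch, 60 miRNAs — fast but structurally complete."""
    return ScreenSimConfig(
        seed=123,
        n_batches=2,
        n_mirnas=60,
        coreg_pair=("miR-050", "miR-051"),
    )


@pytest.fixture(scope="session")
def small_screen(small_config):
    dataset, truth = simulate_screen(small_config)
    return dataset, truth


@pytest.fixture(scope="session")
def small_normalized(small_screen):
    dataset, _ = small_screen
    dataset, _ = filter_low_count_wells(dataset)
    return normalize_screen(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_counts():
    """3 miRNAs x 2 wells, trivially checkable by hand."""
    return pd.DataFrame(
        {"P01:A01": [2, 3, 5], "P01:A02": [10, 0, 90]},
        index=pd.Index(["miR-001", "miR-002", "miR-003"], name="mirna_id"),
    )
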
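import numpy as np
import pytest

from fdgm.landmark_io import LandmarkConfiguration, LandmarkDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


def make_dataset(coords_list, view="other", labels=None, prefix="s"):
    """Build a LandmarkDataset from a list of (N, 2) arrays."""
    labels = labels or [""] * len(coords_list)
    configs = [
        LandmarkConfiguration(
            specimen_id=f"{prefix}{i + 1}",
            coords=np.asarray(c, float),
            species_label=labels[i],
            view=view,
        )
        for i, c in enumerate(coords_list)
    ]
    return LandmarkDataset(configurations=configs, view=view)


@pytest.fixture
def random_dataset(rng):
    """12 random non-degenerate configurations of 7 landmarks."""
    return make_dataset([rng.normal(size=(7, 2)) for _ in range(12)])
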
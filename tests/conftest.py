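import numpy as np
import pandas as pd
import pytest

from svocortex.atlas import load_atlas
from svocortex.ring import build_ring
from svocortex.simulate import AnatomySpec, PopulationSpec, simulate_dataset


@pytest.fixture(scope="session")
def ring():
    return build_ring()


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def small_study(ring, atlas):
    """Synthetic study with a strong embedded effect at the left olfactory
    sulcus (parcel 22), small enough to analyse quickly."""
    return simulate_dataset(
        PopulationSpec(n_subjects=60, noise_fraction=0.1),
        AnatomySpec(effect_map={("left", 22): 0.006}),
        ring,
        atlas,
        seed=1234,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_choice_table(rng, n_subjects, n_pairs=24):
    rows = []
    for i in range(n_subjects):
        for k in range(n_pairs):
            rows.append((f"P{i:03d}", k, int(rng.integers(0, 2))))
    return pd.DataFrame(rows, columns=["participant_id", "pair_index", "chosen"])
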
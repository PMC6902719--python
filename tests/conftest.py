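import numpy as np
import pandas as pd
import pytest

import lipidiga as L


@pytest.fixture(scope="session")
def panel():
    return L.load_default_panel()


@pytest.fixture(scope="session")
def scheme(panel):
    return L.default_group_scheme(panel)


@pytest.fixture
def pre_post_comparison():
    return L.PairwiseComparison(
        arm="EPA",
        tissue="epidermis",
        condition_a={"phase": "pre", "uvr_time": "unirradiated"},
        condition_b={"phase": "post", "uvr_time": "unirradiated"},
    )


def epidermis_config(seed, n=12, **kwargs):
    """Single-tissue, single-timepoint study config used across tests."""
    defaults = dict(
        n_subjects_per_arm={"EPA": n},
        tissues=("epidermis",),
        uvr_timepoints=("unirradiated",),
        seed=seed,
    )
    defaults.update(kwargs)
    return L.StudyConfig(**defaults)


@pytest.fixture
def tiny_matrix():
    """Hand-sized 4-sample x 3-species matrix with one missing cell."""
    design = pd.DataFrame(
        {
            "subject": ["s1", "s2", "s1", "s2"],
            "arm": ["EPA"] * 4,
            "phase": ["pre", "pre", "post", "post"],
            "tissue": ["epidermis"] * 4,
            "uvr_time": ["unirradiated"] * 4,
        },
        index=["a1", "a2", "b1", "b2"],
    )
    values = pd.DataFrame(
        {
            "PGE2": [10.0, 12.0, 11.0, 13.0],
            "12-HETE": [100.0, np.nan, 90.0, 110.0],
            "12-HEPE": [5.0, 6.0, 10.0, 12.0],
        },
        index=design.index,
    )
    lod = pd.Series({"PGE2": 0.5, "12-HETE": 2.0, "12-HEPE": 0.5})
    return L.ConcentrationMatrix(design=design, values=values, lod=lod, unit="pg/mg-protein")
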
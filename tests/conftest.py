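import numpy as np
import pandas as pd
import pytest

from dietmg.food_tree import build_food_tree, diet_profiles
from dietmg.synthetic_data import gen_diaries, gen_food_db, gen_msp_metagenome


@pytest.fixture(scope="session")
def food_db():
    return gen_food_db(n_items=80, n_nutrients=8, seed=101)


@pytest.fixture(scope="session")
def diaries_truth(food_db):
    return gen_diaries(food_db, n_subjects=25, gradient_sd=1.0, seed=102)


@pytest.fixture(scope="session")
def tree(food_db):
    return build_food_tree(food_db, seed=103)


@pytest.fixture(scope="session")
def profiles(diaries_truth, tree):
    diaries, _ = diaries_truth
    return diet_profiles(diaries, tree)


@pytest.fixture(scope="session")
def msp_data():
    """One MSP with two planted accessory blocks over 40 samples."""
    return gen_msp_metagenome(40, 1, [[12, 12]], seed=104)


@pytest.fixture()
def hand_tree():
    """Tiny 3-leaf food tree with unit branch lengths for brute-force checks.

    Topology: root -> (animal-based -> (L3 -> (L4 -> (L5a -> a, b; L5b -> c)))).
    """
    db = pd.DataFrame(
        {
            "level2": ["animal-based", "animal-based", "plant-based"],
            "level3": ["animal-based:meat", "animal-based:meat", "plant-based:fruit"],
            "level4": ["m:c1", "m:c1", "f:c1"],
            "protein_g": [20.0, 21.0, 1.0],
            "fat_g": [10.0, 11.0, 0.5],
            "carb_g": [0.0, 0.5, 12.0],
            "fiber_g": [0.0, 0.0, 2.0],
            "energy_kcal": [170.0, 180.0, 60.0],
            "is_drink": [False, False, False],
            "fruit_veg_pct": [0.0, 0.0, 100.0],
        },
        index=["a", "b", "c"],
    )
    return build_food_tree(db, dmm_k_range=[1], seed=0)
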
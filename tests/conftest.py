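import numpy as np
import pandas as pd
import pytest

from meddiet.food_composition import FoodItem


@pytest.fixture
def toy_items() -> dict[str, FoodItem]:
    """A minimal composition table: two cereals, one red meat, olive oil, butter."""
    items = [
        FoodItem("WHT", "wheat", "cereals", 340.0, 0.4, 0.3, False),
        FoodItem("RIC", "rice", "cereals", 130.0, 0.1, 0.1, False),
        FoodItem("BEE", "beef", "red_meat", 250.0, 6.0, 6.5, False),
        FoodItem("OIL", "olive oil", "none", 884.0, 14.0, 73.0, True),
        FoodItem("BUT", "butter", "none", 717.0, 51.4, 21.0, False),
    ]
    return {it.item_id: it for it in items}


@pytest.fixture
def toy_intake(toy_items) -> pd.DataFrame:
    """Three subjects over the toy items (g/day)."""
    return pd.DataFrame(
        {
            "WHT": [100.0, 0.0, 200.0],
            "RIC": [50.0, 0.0, 0.0],
            "BEE": [80.0, 0.0, 40.0],
            "OIL": [10.0, 0.0, 30.0],
            "BUT": [5.0, 0.0, 0.0],
        },
        index=pd.Index(["A", "B", "C"], name="subject_id"),
    )


def make_pair_sets(diffs: np.ndarray):
    """Build 1:1 MatchedSets with the given within-pair difference matrix.

    The control row is all zeros, so the case row equals the difference.
    """
    from meddiet.matched_analysis import MatchedSet

    diffs = np.asarray(diffs, dtype=float)
    if diffs.ndim == 1:  # a vector of scalar pair differences
        diffs = diffs[:, None]
    sets = []
    for i, d in enumerate(diffs):
        X = np.vstack([d, np.zeros_like(d)])
        sets.append(MatchedSet(set_id=f"p{i}", X=X, subject_ids=(f"c{i}", f"k{i}")))
    return sets
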
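import numpy as np
import pandas as pd
import pytest

from shortform.scale_model import ItemSpec, ScaleSpec


@pytest.fixture
def toy_spec() -> ScaleSpec:
    """Two subscales, four items, one reverse-keyed, 1..6 scale."""
    return ScaleSpec(
        items=[
            ItemSpec("a1", "A"),
            ItemSpec("a2", "A"),
            ItemSpec("a3", "A", reverse_keyed=True),
            ItemSpec("b1", "B"),
        ],
        response_min=1,
        response_max=6,
    )


@pytest.fixture
def toy_responses() -> pd.DataFrame:
    """5 x 4 matrix with missing cells; scores are hand-computed in tests."""
    return pd.DataFrame(
        {
            "a1": [2, 1, 5, np.nan, 6],
            "a2": [4, 1, np.nan, np.nan, 6],
            "a3": [6, 1, 2, 4, 1],
            "b1": [1, 6, 3, np.nan, 2],
        },
        index=[f"r{i}" for i in range(1, 6)],
    )


def make_random_instance(seed: int, n_items_range=(8, 14), n_respondents: int = 150):
    """Small random scale + complete Likert data for GA/oracle tests.

    Items load on their subscale's factor with loadings in [0.2, 0.85],
    so instances mix clearly useful and near-useless items.
    """
    rng = np.random.default_rng(seed)
    L = int(rng.integers(*n_items_range, endpoint=True))
    n_sub = int(rng.integers(2, 4))
    sub_of = np.sort(rng.integers(0, n_sub, size=L))
    # guarantee every subscale has >= 2 items
    for s in range(n_sub):
        if (sub_of == s).sum() < 2:
            return make_random_instance(seed + 1000, n_items_range, n_respondents)
    items = [ItemSpec(f"i{j}", f"s{sub_of[j]}") for j in range(L)]
    spec = ScaleSpec(items=items, response_min=1, response_max=6)

    loadings = rng.uniform(0.2, 0.85, size=L)
    F = rng.standard_normal((n_respondents, n_sub))
    latent = loadings * F[:, sub_of] + np.sqrt(1 - loadings**2) * rng.standard_normal(
        (n_respondents, L)
    )
    cuts = np.quantile(latent, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
    responses = pd.DataFrame(
        1 + np.searchsorted(cuts, latent.ravel()).reshape(latent.shape),
        columns=spec.item_ids,
    )
    return spec, responses
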
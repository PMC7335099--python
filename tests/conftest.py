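import numpy as np
import pandas as pd
import pytest

from forestdiv.community import CommunityAbundance, TraitTable
from forestdiv.simulate import generate_phylogeny, generate_traits


@pytest.fixture(scope="session")
def tree12():
    """Small pure-birth tree used for exhaustive metric sweeps."""
    return generate_phylogeny(12, seed=42)


@pytest.fixture(scope="session")
def tree100():
    return generate_phylogeny(100, seed=7)


@pytest.fixture(scope="session")
def numeric_traits(tree12):
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        rng.normal(size=(12, 3)),
        index=tree12.tip_labels,
        columns=["wd", "sla", "la"],
    )
    return TraitTable(df, {c: "numeric" for c in df.columns})


def make_community(species, weights, plot_id="plot", date=2000.0):
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return CommunityAbundance(plot_id, date, dict(zip(species, w)), 1.0)


@pytest.fixture
def community_factory():
    return make_community
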
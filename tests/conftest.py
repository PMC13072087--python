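import numpy as np
import pandas as pd
import pytest

from nichebreadth.phylo import parse_newick
from nichebreadth.synthetic import ClimateFieldParams, simulate_occurrences, simulate_yule_tree


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); — root-to-tip distance 2 everywhere."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def yule50():
    return simulate_yule_tree(50, seed=101)


@pytest.fixture(scope="session")
def small_occurrences():
    """Modest synthetic occurrence table: 30 species, 5-80 localities each."""
    params = ClimateFieldParams(
        n_species=30, locality_range=(5, 80), seed=202
    )
    records, truth = simulate_occurrences(params)
    return records, truth


def random_species_records(rng: np.random.Generator, n_loc: int) -> pd.DataFrame:
    """One species' worth of unconstrained-but-valid climate records."""
    m = rng.normal(20, 5, n_loc)
    a = rng.uniform(0.5, 12, n_loc)
    bio12 = rng.uniform(50, 2500, n_loc)
    w = rng.uniform(0.35, 0.6, n_loc)
    d = rng.uniform(0, np.minimum(w, 1 - w))
    return pd.DataFrame(
        {
            "species": "sp",
            "lon": rng.uniform(-20, 50, n_loc),
            "lat": rng.uniform(-40, 40, n_loc),
            "region": "Africa",
            "bio1": np.clip(m + rng.normal(0, 1, n_loc), m - a, m + a),
            "bio5": m + a,
            "bio6": m - a,
            "bio12": bio12,
            "bio16": w * bio12,
            "bio17": d * bio12,
        }
    )
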
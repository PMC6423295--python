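import numpy as np
import pandas as pd
import pytest

from pollinet.census_io import CENSUS_COLUMNS, NO_VISIT, SurveyDataset


def make_records(rows):
    """Rows of (census_id, year, period, census_type, plant, individual,
    pollinator, count, duration); pollinator may be NO_VISIT."""
    return pd.DataFrame(rows, columns=CENSUS_COLUMNS)


def make_dataset(rows, apis_name="Apis mellifera"):
    return SurveyDataset.from_records(make_records(rows), apis_name=apis_name)


@pytest.fixture
def toy_dataset():
    """2 plants, 2 wild pollinators, two periods, incl. a zero-visit census."""
    rows = [
        ("c1", 2008, "pre", "focal5min", "PlantA", "A1", "Bee", 2, 5.0),
        ("c1", 2008, "pre", "focal5min", "PlantA", "A1", "Fly", 1, 5.0),
        ("c2", 2008, "pre", "focal5min", "PlantA", "A1", "Bee", 0, 5.0),
        ("c2", 2008, "pre", "focal5min", "PlantA", "A1", NO_VISIT, 0, 5.0),
        ("c3", 2008, "pre", "focal5min", "PlantB", "B1", "Fly", 3, 5.0),
        ("c4", 2008, "apis", "focal5min", "PlantA", "A1", "Bee", 1, 5.0),
        ("c5", 2008, "apis", "focal5min", "PlantB", "B1", NO_VISIT, 0, 5.0),
        ("c6", 2008, "apis", "focal5min", "PlantB", "B2", "Apis mellifera", 4, 5.0),
    ]
    return make_dataset(rows)


def random_dataset(seed, n_plants=3, n_polls=4, n_censuses=50):
    """Randomized valid dataset for round-trip / property tests."""
    rng = np.random.default_rng(seed)
    plants = [f"P{i}" for i in range(n_plants)]
    polls = [f"A{j}" for j in range(n_polls)]
    rows = []
    for k in range(n_censuses):
        plant = plants[rng.integers(n_plants)]
        period = ("pre", "apis")[rng.integers(2)]
        ctype = ("focal5min", "spot")[rng.integers(2)]
        cid = f"c{k}"
        ind = f"{plant}-i{rng.integers(2)}"
        dur = 5.0 if ctype == "focal5min" else 1.5
        counts = rng.poisson(0.6, size=n_polls)
        if counts.sum() == 0:
            rows.append((cid, 2008, period, ctype, plant, ind, NO_VISIT, 0, dur))
        else:
            for j in np.nonzero(counts)[0]:
                rows.append((cid, 2008, period, ctype, plant, ind, polls[j],
                             int(counts[j]), dur))
    return make_dataset(rows)
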
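import collections

import pytest

from thermaldev import (
    read_mean_lifetable,
    table1_fixture_path,
    weighted_mean_observations,
)

#: printed best-fit Brière parameters (n, Tb, TL, m) per species-sex group
PUBLISHED_BRIERE = {
    ("C_cunea", "female"): (5.74e-5, 12.57, 33.0, 2.4),
    ("C_cunea", "male"): (6.0e-5, 11.1, 33.0, 3.0),
    ("P_omnivorus", "female"): (1.1e-5, 11.6, 36.0, 0.9),
    ("P_omnivorus", "male"): (1.0e-5, 10.1, 36.0, 0.92),
}


@pytest.fixture(scope="session")
def fixture_records():
    """Expanded per-individual records from the packaged mean-dev-time table."""
    result = read_mean_lifetable(table1_fixture_path())
    assert not result.errors
    return result.records


@pytest.fixture(scope="session")
def fixture_groups(fixture_records):
    """Records grouped by (species, sex)."""
    groups = collections.defaultdict(list)
    for rec in fixture_records:
        groups[(rec.species, rec.sex)].append(rec)
    return dict(groups)


@pytest.fixture(scope="session")
def fixture_mean_obs(fixture_groups):
    """Cell-mean rate observations (weight = cell n) per species-sex group."""
    return {key: weighted_mean_observations(recs) for key, recs in fixture_groups.items()}
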
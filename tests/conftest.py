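import pandas as pd
import pytest

from streamarch.config import RunConfig
from streamarch.synthetic import SyntheticConfig, simulate_bundle

#: fixed_k matching the planted group counts of the default generator
PLANTED_K = {"tier1": 2, "East": 3, "West": 2}


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 1): 200 sites, 2 cycles each."""
    return simulate_bundle(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    from streamarch.hierarchy import run_pipeline

    return run_pipeline(bundle, RunConfig(seed=1, fixed_k=dict(PLANTED_K)))


@pytest.fixture()
def tiny_table():
    """Three-survey table with all Tier-I features present."""
    from streamarch.datamodel import SampleTable, feature_set

    fset = feature_set("TIER1")
    rows = []
    for i, (site, cyc) in enumerate([("S1", "C1"), ("S1", "C2"), ("S2", "C1")]):
        rows.append({"site_id": site, "cycle_id": cyc, **{n: float(i + j) for j, n in enumerate(fset.names)}})
    return SampleTable(pd.DataFrame(rows))


def archetype_ari(frame, truth):
    """ARI between assigned archetypes and ground truth for assigned sites."""
    from sklearn.metrics import adjusted_rand_score

    merged = (
        frame[frame["status"] == "assigned"]
        .set_index("site_id")
        .join(truth.sites.set_index("site_id"), rsuffix="_true")
    )
    return (
        adjusted_rand_score(merged["region_true"], merged["region"]),
        adjusted_rand_score(merged["archetype_true"], merged["archetype"]),
    )
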
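import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle module

from livelihood_landscapes import (
    CategorySet,
    CommunityMetadata,
    HouseholdRecord,
    SyntheticConfig,
    generate_community,
)


@pytest.fixture(scope="session")
def four_categories() -> CategorySet:
    return CategorySet(("fishing", "farming", "informal", "tourism"))


@pytest.fixture
def toy_households() -> list[HouseholdRecord]:
    """Three households with hand-enumerable counters and links:

    H1=(A,B,C), H2=(A,C), H3=(B) over A=fishing, B=farming, C=informal
    -> A primary=2; B primary=1, secondary=1; C secondary=2;
       counts A->B=1, A->C=2, B->C=1.
    """
    return [
        HouseholdRecord("h1", "s1", ("fishing", "farming", "informal")),
        HouseholdRecord("h2", "s1", ("fishing", "informal")),
        HouseholdRecord("h3", "s1", ("farming",)),
    ]


@pytest.fixture
def toy_metadata() -> list[CommunityMetadata]:
    return [
        CommunityMetadata("s1", "kenya", "peri_urban", 0.8, 120.0, 3),
        CommunityMetadata("s2", "kenya", "rural", -1.1, 40.0, 2),
    ]


@pytest.fixture(scope="session")
def synthetic_site() -> list[HouseholdRecord]:
    return generate_community(SyntheticConfig(n_households=200, seed=11), "synth")
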
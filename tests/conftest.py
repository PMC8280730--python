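"""Shared fixtures: cached benchmark pairs (building one involves several
minimizations, so each label is constructed once per session)."""

import pytest

from dummycure import fixtures as fx


@pytest.fixture(scope="session")
def fixture_cache():
    cache = {}

    def get(label: str) -> fx.FixturePair:
        if label not in cache:
            cache[label] = fx.build_fixture(label)
        return cache[label]

    return get


@pytest.fixture(scope="session")
def curated_cache(fixture_cache):
    """(label, endpoint) -> (hybrid, partition, junctions, plan)."""
    cache = {}

    def get(label: str, endpoint: str):
        key = (label, endpoint)
        if key not in cache:
            cache[key] = fx.curate_fixture(fixture_cache(label), endpoint)
        return cache[key]

    return get
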
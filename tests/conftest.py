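from __future__ import annotations

import random

import pytest

from rtdx.kb_store import KnowledgeBase
from rtdx.scenarios import build_scenario


@pytest.fixture(scope="session")
def scenario1():
    return build_scenario(1)


@pytest.fixture(scope="session")
def scenario2():
    return build_scenario(2)


@pytest.fixture(scope="session")
def scenario3():
    return build_scenario(3)


@pytest.fixture(scope="session")
def scenario4():
    return build_scenario(4)


@pytest.fixture(scope="session")
def scenario5():
    return build_scenario(5)


@pytest.fixture(scope="session")
def scenario5_copy():
    return build_scenario(5, variant="copy")


@pytest.fixture(scope="session")
def scenario6():
    return build_scenario(6)


def shuffled_rebuild(kb: KnowledgeBase, seed: int) -> KnowledgeBase:
    """Re-insert the KB's contents in a random (but declaration-valid) order."""
    rng = random.Random(seed)
    out = KnowledgeBase()
    out.metadata.update(kb.metadata)
    groups = [
        list(kb.temporal_regions.values()),
        list(kb.universals.values()),
        list(kb.particulars.values()),
        list(kb.configurations.values()),
        list(kb.representations.values())
        + list(kb.ices.values())
        + list(kb.processes.values())
        + list(kb.clinical_pictures.values())
        + list(kb.knowledge_aggregates.values()),
        list(kb.temporal_constraints)
        + list(kb.instantiations)
        + list(kb.relations)
        + list(kb.negatives),
    ]
    for group in groups:
        rng.shuffle(group)
        for item in group:
            out.add(item)
    return out
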
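"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive every statistic by direct scanning of
prescription sets, without touching the implementation's counting paths.
"""

from __future__ import annotations

from itertools import combinations

import pytest

from herbmine import PrescriptionRecord, SurveyCorpus, placeholder_registry
from herbmine.datasets import frequent_materials_registry, toy_corpus


def make_corpus(sets: list[set[str]]) -> SurveyCorpus:
    """Corpus from bare material-id sets, with a placeholder registry."""
    ids = sorted(set().union(*sets)) if sets else []
    prescriptions = [
        PrescriptionRecord(
            prescription_id=f"P{i}", pharmacy_id=f"S{i}", materials=frozenset(s)
        )
        for i, s in enumerate(sets, start=1)
    ]
    return SurveyCorpus(registry=placeholder_registry(ids), prescriptions=prescriptions)


# ---------------------------------------------------------------- oracles

def naive_fc(sets: list[set[str]]) -> dict[str, int]:
    """Citation counts by direct set-membership scanning."""
    out: dict[str, int] = {}
    for mid in sorted(set().union(*sets)):
        out[mid] = sum(1 for s in sets if mid in s)
    return out


def naive_pair_support(sets: list[set[str]]) -> dict[tuple[str, str], int]:
    """Support of every unordered pair, by exhaustive enumeration of all
    size-2 subsets of the material universe and direct subset scans."""
    universe = sorted(set().union(*sets))
    out: dict[tuple[str, str], int] = {}
    for a, b in combinations(universe, 2):
        s = sum(1 for p in sets if a in p and b in p)
        if s > 0:
            out[(a, b)] = s
    return out


def naive_confidence_one(sets: list[set[str]], a: str, b: str) -> bool:
    """True iff no prescription contains ``a`` without ``b`` (and ``a``
    occurs at all): the soundness condition for a confidence-1 rule."""
    if not any(a in s for s in sets):
        return False
    return all(b in s for s in sets if a in s)


# --------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def registry19():
    return frequent_materials_registry()


@pytest.fixture(scope="session")
def toy():
    return toy_corpus()


@pytest.fixture()
def tiny_corpus():
    """The hand-enumerable {A,B},{A,B},{A,C} corpus."""
    return make_corpus([{"A", "B"}, {"A", "B"}, {"A", "C"}])
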
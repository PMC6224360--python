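"""Shared fixtures and an independent enumeration oracle for the mixture."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Dict

import pytest

from tetragam import LocusCounts
from tetragam.datasets import flhorag1_counts, retained_loci
from tetragam.model import (
    GameteClass,
    PairingScenario,
    SegregationParams,
    TetraploidGenotype,
)


@pytest.fixture(scope="session")
def study_records():
    return flhorag1_counts()


@pytest.fixture(scope="session")
def retained_records():
    return retained_loci()


def locus_counts(record) -> LocusCounts:
    return LocusCounts(record.name, dict(record.counts))


def enumeration_oracle(
    genotype: TetraploidGenotype,
    scenario: PairingScenario,
    params: SegregationParams,
) -> Dict[GameteClass, float]:
    """Brute-force reference: enumerate every (mode, copy-choice) outcome.

    Walks the meiotic outcome tree explicitly — disomic draws (one copy per
    scenario pair), random bivalent pair draws, and doubled single copies —
    accumulating each outcome's probability into its allele-multiset class.
    Independent of the linear-coefficient construction used by the package.
    """
    tau = Fraction(params.tau).limit_denominator(10**6)
    beta = Fraction(params.beta).limit_denominator(10**6)
    acc: Dict[GameteClass, Fraction] = {}

    def add(a: str, b: str, p: Fraction) -> None:
        key = tuple(sorted((a, b)))
        acc[key] = acc.get(key, Fraction(0)) + p

    (i, j), (k, l) = scenario.pairs
    for x in (i, j):
        for y in (k, l):
            add(
                genotype.copies[x].allele,
                genotype.copies[y].allele,
                (1 - tau) * Fraction(1, 4),
            )
    for x, y in combinations(range(4), 2):
        add(
            genotype.copies[x].allele,
            genotype.copies[y].allele,
            tau * (1 - beta) * Fraction(1, 6),
        )
    for copy in genotype.copies:
        add(copy.allele, copy.allele, tau * beta * Fraction(1, 4))
    return {cls: float(p) for cls, p in acc.items() if p > 0}
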
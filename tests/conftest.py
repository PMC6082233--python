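"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import settings

from karyomorph import ChromosomeMeasurement, MetaphasePlate
from karyomorph.karyotype import pairing_dissimilarity

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_chrom(
    short: float,
    long: float,
    sat: float = 0.0,
    sat_arm: str | None = None,
    pop: str = "P",
    plate: str = "p1",
    cid: int = 1,
) -> ChromosomeMeasurement:
    if sat_arm is None:
        sat_arm = "short" if sat > 0 else "none"
    return ChromosomeMeasurement(pop, plate, cid, short, long, sat, sat_arm)


def make_plate(arm_pairs, pop: str = "P", plate: str = "p1") -> MetaphasePlate:
    """Plate from (short, long[, sat]) tuples, one per chromosome."""
    chroms = tuple(
        make_chrom(*args, pop=pop, plate=plate, cid=i + 1)
        for i, args in enumerate(arm_pairs)
    )
    return MetaphasePlate(pop, plate, chroms)


def random_plate(rng: np.random.Generator, n: int = 8, pop: str = "R",
                 plate: str = "p1") -> MetaphasePlate:
    """Random even-count plate for matching-oracle tests."""
    chroms = []
    for i in range(n):
        s = rng.uniform(0.5, 5.0)
        l = s * rng.uniform(1.0, 8.0)
        chroms.append(make_chrom(s, l, pop=pop, plate=plate, cid=i + 1))
    return MetaphasePlate(pop, plate, tuple(chroms))


def brute_force_matching_cost(plate: MetaphasePlate, weight: float = 0.5) -> float:
    """Exhaustive-search optimum over all perfect matchings (oracle)."""
    chroms = plate.chromosomes

    def best(indices: tuple[int, ...]) -> float:
        if not indices:
            return 0.0
        first, rest = indices[0], indices[1:]
        return min(
            pairing_dissimilarity(chroms[first], chroms[j], weight)
            + best(tuple(k for k in rest if k != j))
            for j in rest
        )

    return best(tuple(range(len(chroms))))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def duplicated_plate(rng) -> MetaphasePlate:
    """16-chromosome plate made of 8 exactly duplicated pairs, shuffled."""
    pairs = []
    for i in range(8):
        s = rng.uniform(0.5, 4.0)
        l = s * rng.uniform(1.0, 6.0)
        pairs.append((s, l))
    args = [p for p in pairs for _ in range(2)]
    order = rng.permutation(len(args))
    return make_plate([args[i] for i in order])
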
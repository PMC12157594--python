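"""Shared fixtures: tiny references, reads and a cached simulated bundle.

Everything is generated programmatically and seeded; the heavier "biased"
bundle is session-scoped so end-to-end tests share one simulation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pancall import AlignedSequence, Reference, simulate_biased_scenario

BASES = "ACGT"


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_reference():
    r = np.random.default_rng(11)
    return Reference({"chrT": random_sequence(r, 2000), "chrU": random_sequence(r, 1500)})


def make_read(
    name: str,
    contig: str,
    start: int,
    bases: str,
    cigar=None,
    quals=None,
    mapq: int = 60,
    strand: str = "+",
    origin: str = "read",
) -> AlignedSequence:
    if cigar is None:
        cigar = (("M", len(bases)),)
    if quals is None and origin == "read":
        quals = tuple([30] * len(bases))
    return AlignedSequence(
        name=name,
        contig=contig,
        start=start,
        cigar=tuple(cigar),
        bases=bases,
        base_qualities=quals,
        mapping_quality=mapq if origin == "read" else None,
        strand=strand if origin == "read" else None,
        origin=origin,
    )


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small full-scenario bundle shared by integration-level tests."""
    return simulate_biased_scenario(seed=11, preset="tiny")
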
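"""Shared fixtures and independent brute-force oracles.

The per-base oracles here deliberately avoid the sweep-line code path so
that every equality check is a genuine dual-route comparison.
"""

from __future__ import annotations

import random
from collections import defaultdict

import pytest

from svcluster.ssv_io import GenomicInterval, SSVRecord

# Three overlapping same-type placements whose endpoint union is the five
# ordered positions 100,200,300,400,500 (1-based), i.e. 99/199/300/400/500
# in half-open coordinates.
WORKED_TRIO = [
    ("ssv1", GenomicInterval("1", 99, 300)),
    ("ssv2", GenomicInterval("1", 199, 400)),
    ("ssv3", GenomicInterval("1", 199, 500)),
]


def make_pair(
    ssv_id: str,
    start0: int,
    end0: int,
    *,
    chrom: str = "1",
    study_id: str = "nstd1",
    variant_type: str = "deletion",
) -> tuple[SSVRecord, GenomicInterval]:
    rec = SSVRecord(
        ssv_id=ssv_id,
        study_id=study_id,
        variant_type=variant_type,
        chrom=chrom,
        start=start0 + 1,
        stop=end0,
    )
    return rec, GenomicInterval(chrom, start0, end0)


@pytest.fixture
def worked_pairs() -> list[tuple[SSVRecord, GenomicInterval]]:
    """The worked three-SSV example as (record, interval) pairs."""
    return [
        make_pair("ssv1", 99, 300),
        make_pair("ssv2", 199, 400),
        make_pair("ssv3", 199, 500),
    ]


def brute_profile(items: list[tuple[str, GenomicInterval]]) -> dict[int, tuple[str, ...]]:
    """Per-base member multiset by literal counting (single chromosome)."""
    prof: dict[int, list[str]] = defaultdict(list)
    for member_id, iv in items:
        for pos in range(iv.start, iv.end):
            prof[pos].append(member_id)
    return {pos: tuple(sorted(mids)) for pos, mids in prof.items()}


def profile_of_segments(
    segments: list[tuple[GenomicInterval, tuple[str, ...]]]
) -> dict[int, tuple[str, ...]]:
    """Expand partition output back to a per-base profile."""
    prof: dict[int, tuple[str, ...]] = {}
    for iv, members in segments:
        for pos in range(iv.start, iv.end):
            assert pos not in prof, "segments overlap"
            prof[pos] = members
    return prof


def random_interval_instance(
    rng: random.Random, max_intervals: int = 30, max_coord: int = 1000
) -> list[tuple[str, GenomicInterval]]:
    """One random small single-chromosome instance (may repeat coordinates)."""
    n = rng.randint(0, max_intervals)
    items = []
    for i in range(n):
        start = rng.randrange(0, max_coord - 1)
        end = rng.randrange(start + 1, max_coord)
        items.append((f"m{i}", GenomicInterval("1", start, end)))
    return items
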
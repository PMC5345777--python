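"""Filtering, rare/common classification, and user-interval comparison."""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from svcluster.cluster import ClusterSet, SVCluster
from svcluster.ssv_io import GenomicInterval, chrom_sort_key

logger = logging.getLogger(__name__)

RARE = "rare"
COMMON = "common"
DEFAULT_RARE_THRESHOLD = 2  # count <= 2 rare, count > 2 common


@dataclass(frozen=True)
class FilterCriteria:
    """Conjunction of optional cluster predicates; absent criteria match all.

    Sizes are in base pairs, end - start in half-open coordinates.
    """

    types: Optional[frozenset[str]] = None
    chroms: Optional[frozenset[str]] = None
    min_size: Optional[int] = None
    max_size: Optional[int] = None
    min_count: Optional[int] = None
    max_count: Optional[int] = None

    def __post_init__(self) -> None:
        for lo, hi, name in (
            (self.min_size, self.max_size, "size"),
            (self.min_count, self.max_count, "count"),
        ):
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"min_{name} > max_{name}")

    def matches(self, c: SVCluster) -> bool:
        if self.types is not None and c.variant_type not in self.types:
            return False
        if self.chroms is not None and c.chrom not in self.chroms:
            return False
        if self.min_size is not None and c.size < self.min_size:
            return False
        if self.max_size is not None and c.size > self.max_size:
            return False
        if self.min_count is not None and c.count < self.min_count:
            return False
        if self.max_count is not None and c.count > self.max_count:
            return False
        return True


@dataclass(frozen=True)
class OverlapHit:
    """One (user interval x SVC) intersection with extent and count."""

    query_id: str
    query: GenomicInterval
    svc_id: Optional[str]
    overlap: GenomicInterval
    svc_count: int
    jaccard: float


def filter_clusters(cs: ClusterSet, crit: FilterCriteria) -> ClusterSet:
    """Keep exactly the clusters matching ALL supplied criteria.

    Order and original SVC ids are preserved (no renumbering); empty
    criteria act as the identity.
    """
    kept = [c for c in cs.clusters if crit.matches(c)]
    return ClusterSet(grouping_mode=cs.grouping_mode, assembly=cs.assembly, clusters=kept)


def classify_frequency(c: SVCluster, threshold: int = DEFAULT_RARE_THRESHOLD) -> str:
    """Label a cluster rare (count <= threshold) or common (count > threshold)."""
    return RARE if c.count <= threshold else COMMON


def overlap_query(
    cs: ClusterSet,
    queries: Iterable[tuple[str, GenomicInterval]],
    *,
    min_jaccard: float = 0.0,
) -> list[OverlapHit]:
    """Report every (query, SVC) pair overlapping by >= 1 base.

    Hits are ordered by query input order then genome position.  Queries on
    chromosomes absent from the set yield no hits and a warning.
    """
    by_chrom: dict[str, list[SVCluster]] = defaultdict(list)
    for c in cs.clusters:
        by_chrom[c.chrom].append(c)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda c: (c.interval.start, c.interval.end))
    starts = {chrom: [c.interval.start for c in cands] for chrom, cands in by_chrom.items()}

    hits: list[OverlapHit] = []
    for query_id, q in queries:
        cands = by_chrom.get(q.chrom)
        if cands is None:
            logger.warning("query %s: chromosome %s absent from cluster set", query_id, q.chrom)
            continue
        # Candidates must start before the query ends; scan those and test ends.
        hi = bisect_right(starts[q.chrom], q.end - 1)
        found = []
        for c in cands[:hi]:
            inter = q.intersection(c.interval)
            if inter is None:
                continue
            union = len(q) + len(c.interval) - len(inter)
            jac = len(inter) / union
            if jac < min_jaccard:
                continue
            found.append(
                OverlapHit(
                    query_id=query_id,
                    query=q,
                    svc_id=c.svc_id,
                    overlap=inter,
                    svc_count=c.count,
                    jaccard=jac,
                )
            )
        found.sort(key=lambda h: (h.overlap.start, h.overlap.end))
        hits.extend(found)
    return hits


def read_bed_queries(path: Union[str, Path]) -> list[tuple[str, GenomicInterval]]:
    """Read BED3+name query intervals (0-based half-open).

    Rows without a name column get synthetic ids ``q<n>``.
    """
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"q{n}"
            out.append((name, GenomicInterval(chrom, start, end)))
    return out


OVERLAP_REPORT_COLUMNS = (
    "query_id",
    "query_chrom",
    "query_start0",
    "query_end0",
    "svc_id",
    "overlap_start0",
    "overlap_end0",
    "svc_count",
    "jaccard",
)


def write_overlap_report(hits: Iterable[OverlapHit], path: Union[str, Path]) -> None:
    """Write overlap hits as a TSV report."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(OVERLAP_REPORT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id,
                        h.query.chrom,
                        str(h.query.start),
                        str(h.query.end),
                        h.svc_id or ".",
                        str(h.overlap.start),
                        str(h.overlap.end),
                        str(h.svc_count),
                        f"{h.jaccard:.6g}",
                    )
                )
                + "\n"
            )
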
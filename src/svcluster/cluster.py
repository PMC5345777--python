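"""Core segmentation: partition interval streams into disjoint counted regions.

Each (grouping key, chromosome) stream of resolved placements is cut at
every interval endpoint; between consecutive breakpoints a region is
emitted whenever at least one placement covers it, carrying the multiset
of covering members as its concordance count.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from collections.abc import Iterable
from dataclasses import dataclass, field, replace
from typing import Optional

from svcluster.ssv_io import GenomicInterval, SSVRecord, chrom_sort_key

COMBINED_BY_TYPE = "combined_by_type"
STUDY_BY_TYPE = "study_by_type"
GROUPING_MODES = (COMBINED_BY_TYPE, STUDY_BY_TYPE)


@dataclass(frozen=True)
class SVCluster:
    """One disjoint cluster region with its concordance count.

    ``count`` is the number of SSV placements containing every base of the
    region; duplicate submissions each count.  ``members``/``studies`` are
    retained only when requested (memory trade-off at millions of inputs).
    """

    interval: GenomicInterval
    count: int
    variant_type: str
    svc_id: Optional[str] = None
    study_id: Optional[str] = None
    members: Optional[tuple[str, ...]] = None
    studies: Optional[frozenset[str]] = None
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("cluster count must be >= 1")
        if self.members is not None and len(self.members) != self.count:
            raise ValueError("count must equal number of retained members")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def size(self) -> int:
        return len(self.interval)

    def attribute_dict(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass
class ClusterSet:
    """Ordered, per-group-disjoint collection of SVClusters."""

    grouping_mode: str = COMBINED_BY_TYPE
    assembly: str = ""
    clusters: list[SVCluster] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.grouping_mode not in GROUPING_MODES:
            raise ValueError(f"unknown grouping mode {self.grouping_mode!r}")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def group_key(self, c: SVCluster) -> tuple:
        if self.grouping_mode == STUDY_BY_TYPE:
            return (c.variant_type, c.study_id)
        return (c.variant_type,)

    def validate(self) -> None:
        """Check ordering/disjointness within every (group, chromosome)."""
        by_group: dict[tuple, SVCluster] = {}
        for c in self.clusters:
            key = self.group_key(c) + (c.chrom,)
            prev = by_group.get(key)
            if prev is not None:
                if c.interval.start < prev.interval.end:
                    raise ValueError(f"clusters overlap or are unsorted in group {key}")
                if (
                    c.interval.start == prev.interval.end
                    and prev.members is not None
                    and c.members == prev.members
                ):
                    raise ValueError(f"adjacent clusters share a member set in group {key}")
            by_group[key] = c


def partition(
    intervals: Iterable[tuple[str, GenomicInterval]],
) -> list[tuple[GenomicInterval, tuple[str, ...]]]:
    """Cut one chromosome's intervals into disjoint counted segments.

    Single left-to-right sweep over the sorted endpoints maintaining the
    active member multiset; a segment is emitted between consecutive
    breakpoints whenever the multiset is non-empty.  Output segments are
    disjoint, sorted, tile the union of the inputs exactly, and adjacent
    segments always differ in member set (every breakpoint is an endpoint).

    Half-open semantics: an interval ending at p and another starting at p
    do not overlap.
    """
    items = list(intervals)
    if not items:
        return []
    chroms = {iv.chrom for _, iv in items}
    if len(chroms) > 1:
        raise ValueError(f"partition requires a single chromosome, got {sorted(chroms)}")
    chrom = chroms.pop()

    starts: dict[int, list[str]] = defaultdict(list)
    ends: dict[int, list[str]] = defaultdict(list)
    for member_id, iv in items:
        starts[iv.start].append(member_id)
        ends[iv.end].append(member_id)

    points = sorted(set(starts) | set(ends))
    active: Counter[str] = Counter()
    segments: list[tuple[GenomicInterval, tuple[str, ...]]] = []
    for left, right in zip(points, points[1:]):
        for mid in ends.get(left, ()):
            active[mid] -= 1
            if active[mid] == 0:
                del active[mid]
        for mid in starts.get(left, ()):
            active[mid] += 1
        if active:
            members = tuple(sorted(active.elements()))
            segments.append((GenomicInterval(chrom, left, right), members))
    return segments


def cluster_records(
    stream: Iterable[tuple[SSVRecord, GenomicInterval]],
    grouping_mode: str = COMBINED_BY_TYPE,
    *,
    assembly: str = "",
    retain_members: bool = True,
    member_limit: Optional[int] = 1_000_000,
) -> ClusterSet:
    """Apply :func:`partition` independently per grouping key and chromosome.

    ``combined_by_type`` groups by variant type pooling all studies;
    ``study_by_type`` groups by (study, variant type).  Member/study sets
    are dropped above *member_limit* input records to bound memory.
    """
    if grouping_mode not in GROUPING_MODES:
        raise ValueError(f"unknown grouping mode {grouping_mode!r}")

    groups: dict[tuple, dict[str, list[tuple[str, GenomicInterval]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    # Study lookup by ssv_id; an ssv_id submitted by several studies maps to
    # all of them (exact under study_by_type grouping, union otherwise).
    studies_by_ssv: dict[str, set[str]] = defaultdict(set)
    n = 0
    for rec, iv in stream:
        key = (
            (rec.variant_type, rec.study_id)
            if grouping_mode == STUDY_BY_TYPE
            else (rec.variant_type,)
        )
        groups[key][iv.chrom].append((rec.ssv_id, iv))
        studies_by_ssv[rec.ssv_id].add(rec.study_id)
        n += 1
    if member_limit is not None and n > member_limit:
        retain_members = False

    clusters: list[SVCluster] = []
    for key in sorted(groups):
        by_chrom = groups[key]
        variant_type = key[0]
        study_id = key[1] if grouping_mode == STUDY_BY_TYPE else None
        for chrom in sorted(by_chrom, key=chrom_sort_key):
            for iv, members in partition(by_chrom[chrom]):
                if retain_members:
                    studies = frozenset(s for m in members for s in studies_by_ssv[m])
                    clusters.append(
                        SVCluster(
                            interval=iv,
                            count=len(members),
                            variant_type=variant_type,
                            study_id=study_id,
                            members=members,
                            studies=studies,
                        )
                    )
                else:
                    clusters.append(
                        SVCluster(
                            interval=iv,
                            count=len(members),
                            variant_type=variant_type,
                            study_id=study_id,
                        )
                    )
    return ClusterSet(grouping_mode=grouping_mode, assembly=assembly, clusters=clusters)


def assign_ids(cs: ClusterSet) -> ClusterSet:
    """Assign IDs "SVC1", "SVC2", ... in iteration order; idempotent."""
    clusters = [replace(c, svc_id=f"SVC{i}") for i, c in enumerate(cs.clusters, start=1)]
    return ClusterSet(grouping_mode=cs.grouping_mode, assembly=cs.assembly, clusters=clusters)
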
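"""Attach co-located features (genes, clinical variants, SNPs) to clusters.

Feature inputs are flat BED4 / GFF3 files with a user-supplied kind label;
annotation is pure metadata addition and never changes interval or count.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import gffutils

from svcluster.cluster import ClusterSet, SVCluster
from svcluster.ssv_io import GenomicInterval


@dataclass(frozen=True)
class FeatureRecord:
    chrom: str
    interval: GenomicInterval
    name: str
    kind: str  # source label, e.g. "gene", "clinvar", "snp"


def read_bed_features(path: Union[str, Path], kind: str) -> list[FeatureRecord]:
    """Read BED4 features (0-based half-open, name in column 4)."""
    out: list[FeatureRecord] = []
    with open(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] else f"{kind}{n}"
            out.append(FeatureRecord(chrom, GenomicInterval(chrom, start, end), name, kind))
    return out


def read_gff3_features(path: Union[str, Path], kind: str) -> list[FeatureRecord]:
    """Read GFF3 features; the name comes from the Name or ID attribute."""
    out: list[FeatureRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line)
            name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.featuretype])[0]
            out.append(
                FeatureRecord(
                    feat.seqid,
                    GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                    name,
                    kind,
                )
            )
    return out


def annotate_clusters(
    cs: ClusterSet,
    features: Iterable[FeatureRecord],
    *,
    containment_only: bool = False,
) -> ClusterSet:
    """Attach, per feature kind, the sorted unique names of co-located features.

    Co-location is any-overlap (>= 1 base) by default, or full containment
    of the feature inside the cluster with *containment_only*.  Names land
    in cluster attributes as ``<kind>=<comma-list>``; clusters without
    overlaps are unchanged and duplicate names collapse.
    """
    by_chrom: dict[str, list[FeatureRecord]] = defaultdict(list)
    for f in features:
        by_chrom[f.chrom].append(f)

    out: list[SVCluster] = []
    for c in cs.clusters:
        names_by_kind: dict[str, set[str]] = defaultdict(set)
        for f in by_chrom.get(c.chrom, ()):
            if containment_only:
                hit = c.interval.contains(f.interval)
            else:
                hit = c.interval.overlaps(f.interval)
            if hit:
                names_by_kind[f.kind].add(f.name)
        if not names_by_kind:
            out.append(c)
            continue
        attrs = dict(c.attributes)
        for kind in sorted(names_by_kind):
            attrs[kind] = ",".join(sorted(names_by_kind[kind]))
        out.append(replace(c, attributes=tuple(sorted(attrs.items()))))
    return ClusterSet(grouping_mode=cs.grouping_mode, assembly=cs.assembly, clusters=out)
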
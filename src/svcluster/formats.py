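"""Readers/writers for SVC GVF and browser track exports (bedGraph, WIG, BED).

GVF output is GFF3-syntax with 1-based inclusive coordinates; bedGraph is
0-based half-open; WIG uses variableStep-with-span stanzas with 1-based
starts.  All writers are deterministic: identical input produces
byte-identical output.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

from svcluster.cluster import COMBINED_BY_TYPE, STUDY_BY_TYPE, ClusterSet, SVCluster
from svcluster.ssv_io import ErrorLog, GenomicInterval

logger = logging.getLogger(__name__)

GVF_VERSION = "1.10"
GVF_SOURCE = "dbVar_SVC"

#: Attribute keys owned by this dialect; anything else is foreign and preserved.
_RESERVED_ATTRS = ("ID", "variant_count", "variant_type", "study", "studies", "members")


def write_gvf(
    cs: ClusterSet,
    path: Union[str, Path],
    *,
    gvf_version: str = GVF_VERSION,
    so_aliases: Optional[dict[str, str]] = None,
) -> None:
    """Write a ClusterSet as a 9-column GVF file.

    Columns: seqid, source, type (the variant-type token, optionally mapped
    through *so_aliases*), start (1-based), end, score ".", strand ".",
    phase ".", attributes.  Requires assigned IDs.
    """
    lines = [f"##gvf-version {gvf_version}"]
    if cs.assembly:
        lines.append(f"##genome-build {cs.assembly}")
    lines.append(f"##svc-grouping {cs.grouping_mode}")
    for c in cs.clusters:
        if c.svc_id is None:
            raise ValueError("write_gvf requires assigned SVC ids (run assign_ids first)")
        type_token = so_aliases.get(c.variant_type, c.variant_type) if so_aliases else c.variant_type
        attrs = [
            f"ID={c.svc_id}",
            f"variant_count={c.count}",
            f"variant_type={c.variant_type}",
        ]
        if c.study_id is not None:
            attrs.append(f"study={c.study_id}")
        if c.studies is not None:
            attrs.append("studies=" + ",".join(sorted(c.studies)))
        if c.members is not None:
            attrs.append("members=" + ",".join(c.members))
        for k, v in c.attributes:
            attrs.append(f"{k}={v}")
        lines.append(
            "\t".join(
                (
                    c.chrom,
                    GVF_SOURCE,
                    type_token,
                    str(c.interval.start + 1),
                    str(c.interval.end),
                    ".",
                    ".",
                    ".",
                    ";".join(attrs),
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gvf(path: Union[str, Path], *, errlog: Optional[ErrorLog] = None) -> ClusterSet:
    """Parse a GVF file written by :func:`write_gvf`; inverse on its own output.

    Malformed feature lines are rejected per-line into *errlog*; a missing
    gvf-version pragma is a warning, not fatal.  Foreign attributes are
    preserved in cluster ``attributes``.
    """
    errlog = errlog if errlog is not None else ErrorLog()
    source = str(path)
    assembly = ""
    grouping = COMBINED_BY_TYPE
    clusters: list[SVCluster] = []
    saw_version = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("##"):
                if line.startswith("##gvf-version"):
                    saw_version = True
                elif line.startswith("##genome-build"):
                    assembly = line.split(None, 1)[1].strip() if " " in line else ""
                elif line.startswith("##svc-grouping"):
                    token = line.split(None, 1)[1].strip()
                    if token in (COMBINED_BY_TYPE, STUDY_BY_TYPE):
                        grouping = token
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                errlog.reject(source, lineno, f"expected 9 columns, got {len(cols)}", line)
                continue
            seqid, _src, type_col, start_s, end_s, _score, _strand, _phase, attr_col = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                errlog.reject(source, lineno, "non-numeric coordinates", line)
                continue
            attrs: dict[str, str] = {}
            for pair in attr_col.split(";"):
                if not pair:
                    continue
                k, _, v = pair.partition("=")
                attrs[k] = v
            if "variant_count" not in attrs:
                errlog.reject(source, lineno, "variant_count attribute absent", line)
                continue
            try:
                count = int(attrs["variant_count"])
                interval = GenomicInterval(seqid, start1 - 1, end1)
            except ValueError as exc:
                errlog.reject(source, lineno, str(exc), line)
                continue
            members = tuple(attrs["members"].split(",")) if attrs.get("members") else None
            studies = frozenset(attrs["studies"].split(",")) if attrs.get("studies") else None
            foreign = tuple((k, v) for k, v in attrs.items() if k not in _RESERVED_ATTRS)
            try:
                clusters.append(
                    SVCluster(
                        interval=interval,
                        count=count,
                        variant_type=attrs.get("variant_type", type_col),
                        svc_id=attrs.get("ID"),
                        study_id=attrs.get("study"),
                        members=members,
                        studies=studies,
                        attributes=foreign,
                    )
                )
            except ValueError as exc:
                errlog.reject(source, lineno, str(exc), line)
    if not saw_version:
        logger.warning("%s: missing ##gvf-version pragma", source)
    return ClusterSet(grouping_mode=grouping, assembly=assembly, clusters=clusters)


def _require_single_group(cs: ClusterSet, what: str) -> None:
    groups = {(c.variant_type, c.study_id) for c in cs.clusters}
    if len(groups) > 1:
        raise ValueError(
            f"{what} holds one value dimension; export each of the {len(groups)} "
            "(variant type, study) groups to its own track"
        )


def write_bedgraph(
    cs: ClusterSet, path: Union[str, Path], track_name: str = "SVC_count"
) -> None:
    """Write counts as a bedGraph track (0-based half-open).

    Requires a single (variant type, study) group; disjoint equal-count
    regions stay separate lines (no merging across gaps).
    """
    _require_single_group(cs, "a bedGraph track")
    lines = [f"track type=bedGraph name={track_name}"]
    for c in cs.clusters:
        lines.append(f"{c.chrom}\t{c.interval.start}\t{c.interval.end}\t{c.count}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_wig(cs: ClusterSet, path: Union[str, Path], track_name: str = "SVC_count") -> None:
    """Write counts as a variableStep-with-span WIG track (1-based starts).

    A new stanza is opened whenever the chromosome or the region span
    changes, so arbitrary region lengths round-trip exactly.
    """
    _require_single_group(cs, "a WIG track")
    lines = [f"track type=wiggle_0 name={track_name}"]
    current: Optional[tuple[str, int]] = None
    for c in cs.clusters:
        span = len(c.interval)
        if current != (c.chrom, span):
            lines.append(f"variableStep chrom={c.chrom} span={span}")
            current = (c.chrom, span)
        lines.append(f"{c.interval.start + 1}\t{c.count}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed3(cs: ClusterSet, path: Union[str, Path]) -> None:
    """Plain 3-column BED of the cluster regions (counts dropped)."""
    lines = [f"{c.chrom}\t{c.interval.start}\t{c.interval.end}" for c in cs.clusters]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path: Union[str, Path]) -> list[tuple[str, int, int, int]]:
    """Parse a bedGraph track back to (chrom, start0, end0, value) rows."""
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, v = line.split("\t")
            rows.append((chrom, int(s), int(e), int(v)))
    return rows


def read_wig(path: Union[str, Path]) -> list[tuple[str, int, int, int]]:
    """Parse a variableStep WIG track back to (chrom, start0, end0, value) rows."""
    rows: list[tuple[str, int, int, int]] = []
    chrom, span = None, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("variableStep"):
                fields = dict(tok.split("=") for tok in line.split()[1:])
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                continue
            if chrom is None:
                raise ValueError("WIG data line before any variableStep declaration")
            pos_s, val_s = line.split("\t")
            start0 = int(pos_s) - 1
            rows.append((chrom, start0, start0 + span, int(val_s)))
    return rows


def step_function(rows: list[tuple[str, int, int, int]]) -> dict[tuple[str, int], int]:
    """Expand track rows into a per-base {(chrom, pos): value} profile."""
    profile: dict[tuple[str, int], int] = {}
    for chrom, start, end, value in rows:
        for pos in range(start, end):
            profile[(chrom, pos)] = value
    return profile
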
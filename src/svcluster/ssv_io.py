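"""Parsing, coordinate resolution and merging of per-study SSV files.

Input files are tab-delimited, one submitted structural variant (SSV) per
row, with possibly-fuzzy placements expressed as outer/start/inner
coordinate tiers (1-based inclusive).  All internal computation uses
0-based half-open intervals; conversion happens only at I/O boundaries.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Iterable, Iterator
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import yaml

logger = logging.getLogger(__name__)

# Fields a ColumnMap must cover for every input dialect.
MANDATORY_FIELDS = ("ssv_id", "study_id", "variant_type", "chrom")
COORD_FIELDS = ("outer_start", "start", "inner_start", "inner_stop", "stop", "outer_stop")
OPTIONAL_FIELDS = COORD_FIELDS + ("assembly",)

START_TIERS = ("outer_start", "start", "inner_start")
STOP_TIERS = ("inner_stop", "stop", "outer_stop")

#: Sentinel strings treated as "no value" in coordinate columns.
_MISSING = {"", ".", "-", "na", "nan", "null", "none"}

_CHROM_RANK = {str(i): i for i in range(1, 23)}
_CHROM_RANK.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


class ConfigurationError(ValueError):
    """Raised when a ColumnMap or run configuration is unusable."""


@dataclass(frozen=True)
class GenomicInterval:
    """A resolved, strand-less placement; 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.chrom}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(self.chrom, max(self.start, other.start), min(self.end, other.end))

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class SSVRecord:
    """One submitted structural variant with a possibly-fuzzy placement.

    Coordinate fields are 1-based inclusive genomic positions; any tier may
    be absent as long as at least one start tier and one stop tier remain.
    """

    ssv_id: str
    study_id: str
    variant_type: str
    chrom: str
    outer_start: Optional[int] = None
    start: Optional[int] = None
    inner_start: Optional[int] = None
    inner_stop: Optional[int] = None
    stop: Optional[int] = None
    outer_stop: Optional[int] = None
    assembly: str = ""

    def validate(self) -> None:
        """Raise ValueError if the record breaks the placement invariants."""
        starts = [getattr(self, f) for f in START_TIERS if getattr(self, f) is not None]
        stops = [getattr(self, f) for f in STOP_TIERS if getattr(self, f) is not None]
        if not starts or not stops:
            raise ValueError("record needs at least one start tier and one stop tier")
        ordered_starts = [getattr(self, f) for f in START_TIERS if getattr(self, f) is not None]
        if ordered_starts != sorted(ordered_starts):
            raise ValueError("start tiers out of order (need outer_start <= start <= inner_start)")
        ordered_stops = [getattr(self, f) for f in STOP_TIERS if getattr(self, f) is not None]
        if ordered_stops != sorted(ordered_stops):
            raise ValueError("stop tiers out of order (need inner_stop <= stop <= outer_stop)")
        # Both resolution policies must yield a non-empty interval.
        if max(starts) > min(stops):
            raise ValueError("innermost placement is empty (resolved start > stop)")


@dataclass(frozen=True)
class RowRejection:
    """One rejected input row, with its provenance and a reason."""

    source: str
    line_number: int
    reason: str
    raw: str = ""


class ErrorLog:
    """Collects per-row rejections instead of silently dropping them."""

    def __init__(self) -> None:
        self.rejections: list[RowRejection] = []

    def reject(self, source: str, line_number: int, reason: str, raw: str = "") -> None:
        self.rejections.append(RowRejection(source, line_number, reason, raw))
        logger.warning("rejected %s line %d: %s", source, line_number, reason)

    def __len__(self) -> int:
        return len(self.rejections)


@dataclass
class ColumnMap:
    """Maps SSVRecord fields to column names (or 0-based indices) of a TSV dialect."""

    columns: dict[str, Union[str, int]]
    has_header: bool = True
    comment: str = "#"

    def __post_init__(self) -> None:
        for f in MANDATORY_FIELDS:
            if f not in self.columns:
                raise ConfigurationError(f"ColumnMap missing mandatory field {f!r}")
        known = set(MANDATORY_FIELDS) | set(OPTIONAL_FIELDS)
        unknown = set(self.columns) - known
        if unknown:
            raise ConfigurationError(f"ColumnMap has unknown fields: {sorted(unknown)}")

    @classmethod
    def default(cls) -> "ColumnMap":
        """Dialect written by the synthetic-data generator and re-serializer."""
        fields = MANDATORY_FIELDS + OPTIONAL_FIELDS
        return cls(columns={f: f for f in fields})

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ColumnMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError(f"column map {path}: expected a mapping")
        columns = doc.get("columns", doc)
        meta = {k: doc[k] for k in ("has_header", "comment") if k in doc}
        if "columns" not in doc:
            columns = {k: v for k, v in columns.items() if k not in ("has_header", "comment")}
        return cls(columns=dict(columns), **meta)

    def indices_for(self, header: Optional[list[str]]) -> dict[str, int]:
        """Resolve the mapping to concrete column indices for one file."""
        out: dict[str, int] = {}
        for fld, col in self.columns.items():
            if isinstance(col, int):
                out[fld] = col
            else:
                if header is None:
                    raise ConfigurationError(
                        f"column {col!r} for field {fld!r} needs a header but file has none"
                    )
                try:
                    out[fld] = header.index(col)
                except ValueError:
                    if fld in MANDATORY_FIELDS:
                        raise ConfigurationError(f"mandatory column {col!r} absent from header")
                    continue  # optional fields may be missing from a dialect
        return out


def normalize_variant_type(token: str, aliases: Optional[dict[str, str]] = None) -> str:
    """Case-fold and whitespace-collapse a variant-type token, then apply aliases."""
    norm = re.sub(r"\s+", " ", token.strip()).casefold()
    if aliases:
        norm = aliases.get(norm, norm)
    return norm


def chrom_sort_key(chrom: str, aliases: Optional[dict[str, str]] = None) -> tuple:
    """Natural ordering 1..22, X, Y, MT for recognized names; else lexicographic.

    RefSeq NC_ accessions can be folded in via an alias table mapping
    accession -> plain chromosome name.
    """
    name = aliases.get(chrom, chrom) if aliases else chrom
    base = name[3:] if name[:3].lower() == "chr" else name
    rank = _CHROM_RANK.get(base.upper())
    if rank is not None:
        return (0, rank, "")
    return (1, 0, name)


def _parse_coord(value: str) -> Optional[int]:
    v = value.strip()
    if v.lower() in _MISSING:
        return None
    return int(v)


def _iter_rows(fh: TextIO, comment: str, first_lineno: int = 1) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(fh, start=first_lineno):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if comment and line.startswith(comment):
            continue
        yield lineno, line.split("\t")


def read_study_file(
    path: Union[str, Path],
    colmap: Optional[ColumnMap] = None,
    *,
    errlog: Optional[ErrorLog] = None,
    type_aliases: Optional[dict[str, str]] = None,
    assembly: Optional[str] = None,
) -> Iterator[SSVRecord]:
    """Yield one SSVRecord per data row, in file order.

    Rows failing the record invariants are routed to *errlog* with their
    line number and reason; they are never silently dropped.  When
    *assembly* is given, records whose assembly label mismatches are
    skipped (counted in the log, not treated as errors).
    """
    colmap = colmap or ColumnMap.default()
    errlog = errlog if errlog is not None else ErrorLog()
    source = str(path)
    skipped_assembly = 0
    with open(path) as fh:
        header: Optional[list[str]] = None
        if colmap.has_header:
            first = fh.readline().rstrip("\n")
            if not first:
                return  # empty file -> empty stream
            stripped = first.lstrip(colmap.comment) if colmap.comment else first
            header = stripped.split("\t")
        idx = colmap.indices_for(header)
        for lineno, fields in _iter_rows(fh, colmap.comment, first_lineno=2 if header else 1):
            try:
                rec = _row_to_record(fields, idx, type_aliases)
            except ValueError as exc:
                errlog.reject(source, lineno, str(exc), "\t".join(fields))
                continue
            if assembly and rec.assembly and rec.assembly != assembly:
                skipped_assembly += 1
                continue
            yield rec
    if skipped_assembly:
        logger.info("%s: skipped %d records on other assemblies", source, skipped_assembly)


def _row_to_record(
    fields: list[str], idx: dict[str, int], type_aliases: Optional[dict[str, str]]
) -> SSVRecord:
    def get(fld: str) -> Optional[str]:
        i = idx.get(fld)
        if i is None or i >= len(fields):
            return None
        return fields[i]

    kwargs: dict = {}
    for fld in MANDATORY_FIELDS:
        v = get(fld)
        if v is None or not v.strip():
            raise ValueError(f"missing value for mandatory field {fld!r}")
        kwargs[fld] = v.strip()
    kwargs["variant_type"] = normalize_variant_type(kwargs["variant_type"], type_aliases)
    for fld in COORD_FIELDS:
        v = get(fld)
        if v is None:
            kwargs[fld] = None
            continue
        try:
            kwargs[fld] = _parse_coord(v)
        except ValueError:
            raise ValueError(f"unparsable coordinate {fld}={v!r}")
    asm = get("assembly")
    kwargs["assembly"] = asm.strip() if asm else ""
    rec = SSVRecord(**kwargs)
    rec.validate()
    return rec


def resolve_placement(rec: SSVRecord, policy: str = "outermost") -> GenomicInterval:
    """Collapse fuzzy coordinate tiers into a concrete half-open interval.

    ``outermost`` takes the min available start tier and max available stop
    tier (conservative superset); ``innermost`` the opposite extremes.  The
    1-based inclusive pair (s, e) becomes the half-open interval [s-1, e).
    """
    starts = [getattr(rec, f) for f in START_TIERS if getattr(rec, f) is not None]
    stops = [getattr(rec, f) for f in STOP_TIERS if getattr(rec, f) is not None]
    if not starts or not stops:
        raise ValueError(f"{rec.ssv_id}: no resolvable coordinates")
    if policy == "outermost":
        s, e = min(starts), max(stops)
    elif policy == "innermost":
        s, e = max(starts), min(stops)
    else:
        raise ValueError(f"unknown placement policy {policy!r}")
    if s > e:
        raise ValueError(f"{rec.ssv_id}: resolved start {s} > stop {e} under {policy}")
    return GenomicInterval(rec.chrom, s - 1, e)


def merge_studies(
    paths: Iterable[Union[str, Path]],
    colmap: Optional[ColumnMap] = None,
    policy: str = "outermost",
    *,
    errlog: Optional[ErrorLog] = None,
    type_aliases: Optional[dict[str, str]] = None,
    assembly: Optional[str] = None,
    chrom_aliases: Optional[dict[str, str]] = None,
) -> list[tuple[SSVRecord, GenomicInterval]]:
    """Parse, resolve and genome-sort all study files into one stream.

    Output is sorted by (chromosome order, start, end, ssv_id) and is
    deterministic for identical inputs.  Duplicate ssv_ids across files are
    allowed but logged; per-record resolution failures go to *errlog*.
    """
    errlog = errlog if errlog is not None else ErrorLog()
    pairs: list[tuple[SSVRecord, GenomicInterval]] = []
    seen_ids: set[str] = set()
    for path in paths:
        for rec in read_study_file(
            path, colmap, errlog=errlog, type_aliases=type_aliases, assembly=assembly
        ):
            try:
                iv = resolve_placement(rec, policy)
            except ValueError as exc:
                errlog.reject(str(path), -1, str(exc))
                continue
            if rec.ssv_id in seen_ids:
                logger.info("duplicate ssv_id %s (kept)", rec.ssv_id)
            seen_ids.add(rec.ssv_id)
            pairs.append((rec, iv))
    pairs.sort(
        key=lambda p: (chrom_sort_key(p[1].chrom, chrom_aliases), p[1].start, p[1].end, p[0].ssv_id)
    )
    return pairs


MERGED_COLUMNS = ("chrom", "start0", "end0", "ssv_id", "study_id", "variant_type")


def write_merged_tsv(
    pairs: Iterable[tuple[SSVRecord, GenomicInterval]], path: Union[str, Path]
) -> None:
    """Write the merged stream as TSV with 0-based half-open coordinates."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(MERGED_COLUMNS) + "\n")
        for rec, iv in pairs:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.ssv_id}\t{rec.study_id}\t{rec.variant_type}\n"
            )


def read_merged_tsv(
    path: Union[str, Path], *, errlog: Optional[ErrorLog] = None
) -> list[tuple[SSVRecord, GenomicInterval]]:
    """Inverse of :func:`write_merged_tsv` (fuzzy tiers are not preserved)."""
    errlog = errlog if errlog is not None else ErrorLog()
    out: list[tuple[SSVRecord, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, fields in _iter_rows(fh, "#"):
            if len(fields) < 6:
                errlog.reject(str(path), lineno, "expected 6 columns")
                continue
            chrom, s, e, ssv_id, study_id, vtype = fields[:6]
            try:
                iv = GenomicInterval(chrom, int(s), int(e))
            except ValueError as exc:
                errlog.reject(str(path), lineno, str(exc))
                continue
            rec = SSVRecord(
                ssv_id=ssv_id,
                study_id=study_id,
                variant_type=vtype,
                chrom=chrom,
                start=iv.start + 1,
                stop=iv.end,
            )
            out.append((rec, iv))
    return out


def write_study_file(
    records: Iterable[SSVRecord], path: Union[str, Path], colmap: Optional[ColumnMap] = None
) -> None:
    """Serialize records back to the study TSV dialect described by *colmap*.

    Only name-based default-style maps are supported for writing; the
    column order follows the mandatory-then-optional field order.
    """
    colmap = colmap or ColumnMap.default()
    fields = [f for f in MANDATORY_FIELDS + OPTIONAL_FIELDS if f in colmap.columns]
    with open(path, "w") as fh:
        if colmap.has_header:
            names = [str(colmap.columns[f]) for f in fields]
            fh.write((colmap.comment or "") + "\t".join(names) + "\n")
        for rec in records:
            row = []
            for f in fields:
                v = getattr(rec, f)
                row.append("" if v is None else str(v))
            fh.write("\t".join(row) + "\n")


def innermost_within_outermost(rec: SSVRecord) -> bool:
    """True iff the innermost interval is contained in the outermost one."""
    outer = resolve_placement(rec, "outermost")
    inner = resolve_placement(rec, "innermost")
    return outer.contains(inner)
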
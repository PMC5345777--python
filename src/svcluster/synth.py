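"""Deterministic synthetic multi-study SSV data with known ground truth.

Emulates dbVar-style by-study files with controllable overlap structure,
variant-type mix and fuzzy-coordinate fraction, plus a literal per-base
counting oracle that is deliberately independent of the sweep-line
implementation in :mod:`svcluster.cluster`.
"""

from __future__ import annotations

import math
import random
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from svcluster.cluster import (
    COMBINED_BY_TYPE,
    STUDY_BY_TYPE,
    ClusterSet,
    SVCluster,
)
from svcluster.ssv_io import (
    ColumnMap,
    GenomicInterval,
    SSVRecord,
    chrom_sort_key,
    resolve_placement,
    write_study_file,
)


class SynthConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class SynthConfig:
    """All knobs of the generator; a single seed drives every draw."""

    seed: int = 0
    n_studies: int = 3
    ssv_per_study: int = 100
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 1_000_000})
    type_weights: dict[str, float] = field(
        default_factory=lambda: {"deletion": 0.5, "duplication": 0.3, "insertion": 0.2}
    )
    #: (interval, extra density multiplier) pairs; intensity k adds k times
    #: the baseline per-base placement rate inside the interval.
    overlap_hotspots: list[tuple[GenomicInterval, float]] = field(default_factory=list)
    fuzzy_fraction: float = 0.0
    size_range: tuple[int, int] = (50, 5_000)  # log-uniform bounds, bp
    assembly: str = "GRCh38"

    def validate(self) -> None:
        if self.n_studies < 1 or self.ssv_per_study < 0:
            raise SynthConfigError("need n_studies >= 1 and ssv_per_study >= 0")
        if not self.chrom_lengths:
            raise SynthConfigError("chrom_lengths must not be empty")
        weight_sum = sum(self.type_weights.values())
        if not self.type_weights or abs(weight_sum - 1.0) > 1e-6:
            raise SynthConfigError(f"type_weights must sum to 1 (got {weight_sum})")
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise SynthConfigError("size_range must satisfy 1 <= min <= max")
        if hi > min(self.chrom_lengths.values()):
            raise SynthConfigError("max size exceeds the shortest chromosome")
        for iv, intensity in self.overlap_hotspots:
            length = self.chrom_lengths.get(iv.chrom)
            if length is None or iv.end > length:
                raise SynthConfigError(f"hotspot {iv} outside configured chromosomes")
            if intensity < 0:
                raise SynthConfigError("hotspot intensity must be >= 0")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynthConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        hotspots = [
            (GenomicInterval(h["chrom"], int(h["start"]), int(h["end"])), float(h["intensity"]))
            for h in doc.pop("overlap_hotspots", [])
        ]
        if "size_range" in doc:
            doc["size_range"] = tuple(doc["size_range"])
        cfg = cls(overlap_hotspots=hotspots, **doc)
        cfg.validate()
        return cfg


def _sample_interval(
    rng: random.Random, cfg: SynthConfig, regions: Sequence[tuple[str, int, int]], weights: Sequence[float]
) -> tuple[str, int, int]:
    """Pick (chrom, start0, end0): region by weight, start uniform, size log-uniform."""
    chrom, rstart, rend = rng.choices(regions, weights=weights, k=1)[0]
    lo, hi = cfg.size_range
    size = round(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    size = max(1, min(size, cfg.chrom_lengths[chrom]))
    start = rng.randrange(rstart, rend)
    start = min(start, cfg.chrom_lengths[chrom] - size)
    return chrom, start, start + size


def generate_records(cfg: SynthConfig) -> list[SSVRecord]:
    """Draw all SSV records for the configured studies, reproducibly.

    Fuzzy records satisfy the tier-ordering invariants by construction.
    Records come out grouped by study, in generation order.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)

    # Background regions weighted by length; hotspots add intensity * length.
    regions: list[tuple[str, int, int]] = []
    weights: list[float] = []
    for chrom, length in sorted(cfg.chrom_lengths.items(), key=lambda kv: chrom_sort_key(kv[0])):
        regions.append((chrom, 0, length))
        weights.append(float(length))
    for iv, intensity in cfg.overlap_hotspots:
        regions.append((iv.chrom, iv.start, iv.end))
        weights.append(intensity * len(iv))

    types = sorted(cfg.type_weights)
    type_w = [cfg.type_weights[t] for t in types]

    records: list[SSVRecord] = []
    serial = 0
    for study_index in range(cfg.n_studies):
        study_id = f"nstd{study_index + 1}"
        for _ in range(cfg.ssv_per_study):
            serial += 1
            chrom, start0, end0 = _sample_interval(rng, cfg, regions, weights)
            start1, stop1 = start0 + 1, end0  # 1-based inclusive
            kwargs: dict = {}
            if rng.random() < cfg.fuzzy_fraction:
                size = stop1 - start1 + 1
                pad = rng.randint(1, 50)
                shrink = rng.randint(0, max(0, (size - 1) // 2))
                kwargs = {
                    "outer_start": max(1, start1 - pad),
                    "inner_start": start1 + shrink,
                    "inner_stop": stop1 - shrink,
                    "outer_stop": min(cfg.chrom_lengths[chrom], stop1 + pad),
                }
            rec = SSVRecord(
                ssv_id=f"essv{serial}",
                study_id=study_id,
                variant_type=rng.choices(types, weights=type_w, k=1)[0],
                chrom=chrom,
                start=start1,
                stop=stop1,
                assembly=cfg.assembly,
                **kwargs,
            )
            rec.validate()
            records.append(rec)
    return records


def generate_studies(
    cfg: SynthConfig, outdir: Union[str, Path]
) -> tuple[list[Path], list[SSVRecord]]:
    """Write one TSV per study (the dialect ssv_io reads) and return paths + records."""
    records = generate_records(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_study: dict[str, list[SSVRecord]] = defaultdict(list)
    for rec in records:
        by_study[rec.study_id].append(rec)
    paths: list[Path] = []
    for study_id in sorted(by_study, key=lambda s: (len(s), s)):
        path = outdir / f"{study_id}.tsv"
        write_study_file(by_study[study_id], path, ColumnMap.default())
        paths.append(path)
    return paths, records


def ground_truth_segmentation(
    records: Iterable[SSVRecord],
    grouping_mode: str = COMBINED_BY_TYPE,
    policy: str = "outermost",
    *,
    assembly: str = "",
) -> ClusterSet:
    """Expected segmentation by literal per-base counting.

    Walks every covered base, records the member multiset there, and merges
    maximal runs of consecutive bases with identical multisets into
    clusters.  O(total covered length); intended for modest coordinates and
    as an oracle, not for production use.
    """
    groups: dict[tuple, dict[str, dict[int, list[str]]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(list))
    )
    studies_by_ssv: dict[str, set[str]] = defaultdict(set)
    for rec in records:
        iv = resolve_placement(rec, policy)
        key = (
            (rec.variant_type, rec.study_id)
            if grouping_mode == STUDY_BY_TYPE
            else (rec.variant_type,)
        )
        per_base = groups[key][iv.chrom]
        for pos in range(iv.start, iv.end):
            per_base[pos].append(rec.ssv_id)
        studies_by_ssv[rec.ssv_id].add(rec.study_id)

    clusters: list[SVCluster] = []
    for key in sorted(groups):
        variant_type = key[0]
        study_id = key[1] if grouping_mode == STUDY_BY_TYPE else None
        for chrom in sorted(groups[key], key=chrom_sort_key):
            per_base = groups[key][chrom]
            run_start: Optional[int] = None
            run_members: Optional[tuple[str, ...]] = None
            prev_pos: Optional[int] = None

            def flush(end_pos: int) -> None:
                assert run_start is not None and run_members is not None
                clusters.append(
                    SVCluster(
                        interval=GenomicInterval(chrom, run_start, end_pos),
                        count=len(run_members),
                        variant_type=variant_type,
                        study_id=study_id,
                        members=run_members,
                        studies=frozenset(
                            s for m in run_members for s in studies_by_ssv[m]
                        ),
                    )
                )

            for pos in sorted(per_base):
                members = tuple(sorted(per_base[pos]))
                if run_start is None:
                    run_start, run_members, prev_pos = pos, members, pos
                    continue
                if pos == prev_pos + 1 and members == run_members:
                    prev_pos = pos
                    continue
                flush(prev_pos + 1)
                run_start, run_members, prev_pos = pos, members, pos
            if run_start is not None:
                flush(prev_pos + 1)
    return ClusterSet(grouping_mode=grouping_mode, assembly=assembly, clusters=clusters)
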
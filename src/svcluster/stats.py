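"""Summary statistics over cluster sets.

Per-type count/percent tables (integer percents, round-half-up, low-share
types pooled into "Others") and size/count distribution summaries.
"""

from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Union

from svcluster.cluster import ClusterSet

OTHERS_LABEL = "Others"
TOTAL_LABEL = "Total"


@dataclass(frozen=True)
class SummaryRow:
    variant_type: str
    svc_count: int
    percent: int


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _percent(n: int, total: int) -> int:
    """Integer percent share via exact rational round-half-up."""
    return int((Decimal(100 * n) / Decimal(total)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_counts(
    counts: Mapping[str, int], others_threshold: float = 0.01
) -> list[SummaryRow]:
    """Build the per-type summary table from raw per-type cluster counts.

    Body rows are sorted by descending count (ties by type name); types
    whose share falls below *others_threshold* are pooled into "Others";
    a final "Total" row carries 100%.  Percentages are round-half-up of
    100 * count / total, so the percent column may be off 100 by up to the
    number of body rows while counts always sum exactly.
    """
    total = sum(counts.values())
    if total == 0:
        return [SummaryRow(TOTAL_LABEL, 0, 0)]
    pooled = 0
    body: dict[str, int] = {}
    for vtype, n in counts.items():
        if vtype == OTHERS_LABEL or n / total < others_threshold:
            pooled += n
        else:
            body[vtype] = n
    rows = [
        SummaryRow(vtype, n, _percent(n, total))
        for vtype, n in sorted(body.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    if pooled:
        rows.append(SummaryRow(OTHERS_LABEL, pooled, _percent(pooled, total)))
    rows.append(SummaryRow(TOTAL_LABEL, total, 100))
    return rows


def summarize_by_type(cs: ClusterSet, others_threshold: float = 0.01) -> list[SummaryRow]:
    """Per-variant-type cluster counts and integer percent shares."""
    counts = Counter(c.variant_type for c in cs.clusters)
    return summarize_counts(counts, others_threshold)


SUMMARY_COLUMNS = ("Variant Type", "Percent Total (%)", "SVC Count")


def write_summary_tsv(rows: Iterable[SummaryRow], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.variant_type}\t{r.percent}%\t{r.svc_count}\n")


@dataclass(frozen=True)
class DistributionRow:
    """Five-number-ish summary of one metric within one variant-type group."""

    variant_type: str  # or "all"
    metric: str  # "length" or "count"
    n: int
    min: float
    median: float
    mean: float
    max: float


def distribution_stats(cs: ClusterSet) -> list[DistributionRow]:
    """Summaries of cluster length and count, per variant type and overall.

    Empty input yields an empty report.  Deterministic: rows are ordered
    by type (overall "all" first) then metric.
    """
    if not cs.clusters:
        return []
    by_type: dict[str, list] = defaultdict(list)
    for c in cs.clusters:
        by_type[c.variant_type].append(c)
        by_type["all"].append(c)

    rows: list[DistributionRow] = []
    order = ["all"] + sorted(t for t in by_type if t != "all")
    for vtype in order:
        clusters = by_type[vtype]
        for metric, values in (
            ("length", [c.size for c in clusters]),
            ("count", [c.count for c in clusters]),
        ):
            rows.append(
                DistributionRow(
                    variant_type=vtype,
                    metric=metric,
                    n=len(values),
                    min=min(values),
                    median=statistics.median(values),
                    mean=statistics.fmean(values),
                    max=max(values),
                )
            )
    return rows


def write_distribution_tsv(rows: Iterable[DistributionRow], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("variant_type\tmetric\tn\tmin\tmedian\tmean\tmax\n")
        for r in rows:
            fh.write(
                f"{r.variant_type}\t{r.metric}\t{r.n}\t{r.min:g}\t{r.median:g}\t{r.mean:g}\t{r.max:g}\n"
            )
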
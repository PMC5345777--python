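# svcluster

Structural variant cluster (SVC) toolkit: partitions submitted structural
variant (SSV) placements from multiple studies into disjoint genomic
regions demarcated by every SSV breakpoint, counts per-region concordance,
and provides the surrounding toolchain — merge, filter, compare, annotate,
summarize, and export as GVF / BED / bedGraph / WIG.

The core operation cuts each (variant type[, study], chromosome) stream of
intervals at every interval endpoint with a single sweep; between
consecutive breakpoints a cluster region is emitted whenever at least one
placement covers it, carrying the number of covering placements as its
count. Regions with count ≤ 2 are classified rare, count > 2 common.

## CLI

All functionality is exposed through subcommands of `svcluster`:

```sh
# Generate deterministic synthetic multi-study SSV files
svcluster simulate --seed 1 --n-studies 3 --ssv-per-study 1000 --outdir sim/

# Combine and genome-sort study TSVs (fuzzy coordinates resolved
# outermost by default; use --policy innermost for the tight bound)
svcluster merge sim/nstd*.tsv --out merged.tsv

# Partition into counted SVC regions, write GVF
svcluster cluster --in merged.tsv --group-by type --assembly GRCh38 --out svc.gvf

# Filter by type / chromosome / size / count (conjunction)
svcluster filter --in svc.gvf --type deletion --min-count 100 --out common.gvf

# Compare user intervals (BED3+name) against the SVC set
svcluster compare --svc svc.gvf --queries mine.bed --out hits.tsv

# Attach co-located features from BED4 / GFF3 files
svcluster annotate --svc svc.gvf --features gene=genes.bed --out annotated.gvf

# Per-type count/percent summary table and distributions
svcluster stats --in svc.gvf --out summary.tsv --distribution dist.tsv

# Browser tracks
svcluster tracks --in common.gvf --bedgraph svc.bedgraph --wig svc.wig --bed svc.bed
```

Input dialects are configurable: pass `--colmap map.yaml` to `merge` to map
your column names (or 0-based indices) onto the semantic fields
(`ssv_id`, `study_id`, `variant_type`, `chrom`, `outer_start`, `start`,
`inner_start`, `inner_stop`, `stop`, `outer_stop`, `assembly`).

## Coordinates

Inputs and GVF are 1-based inclusive; everything internal (and the merged
TSV, BED, bedGraph) is 0-based half-open. An interval ending at position p
and another starting at p do not overlap.

## Library layout

| module                  | contents                                                      |
|-------------------------|---------------------------------------------------------------|
| `svcluster.ssv_io`      | TSV parsing, fuzzy-coordinate resolution, merge/sort          |
| `svcluster.cluster`     | sweep-line `partition`, `cluster_records`, `assign_ids`       |
| `svcluster.formats`     | GVF reader/writer, bedGraph / WIG / BED3 export               |
| `svcluster.filter_query`| `FilterCriteria`, rare/common classification, `overlap_query` |
| `svcluster.annotate`    | BED/GFF3 feature intersection onto clusters                   |
| `svcluster.stats`       | per-type summary tables, size/count distributions             |
| `svcluster.synth`       | seeded synthetic data + independent per-base counting oracle  |
| `svcluster.cli`         | `svcluster` subcommand front-end                              |
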
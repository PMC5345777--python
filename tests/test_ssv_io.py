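"""Unit tests for parsing, coordinate resolution and study merging."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from svcluster.ssv_io import (
    ColumnMap,
    ConfigurationError,
    ErrorLog,
    GenomicInterval,
    SSVRecord,
    chrom_sort_key,
    innermost_within_outermost,
    merge_studies,
    normalize_variant_type,
    read_merged_tsv,
    read_study_file,
    resolve_placement,
    write_merged_tsv,
    write_study_file,
)

HEADER = "#ssv_id\tstudy_id\tvariant_type\tchrom\touter_start\tstart\tinner_start\tinner_stop\tstop\touter_stop\tassembly\n"


def write_rows(path, rows):
    with open(path, "w") as fh:
        fh.write(HEADER)
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def simple_row(ssv_id="essv1", study="nstd1", vtype="deletion", chrom="1", start=100, stop=300):
    return (ssv_id, study, vtype, chrom, "", start, "", "", stop, "", "GRCh38")


class TestReadStudyFile:
    def test_header_only_file_yields_empty_stream(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(HEADER)
        assert list(read_study_file(p)) == []

    def test_simple_row_maps_fields(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_rows(p, [simple_row()])
        (rec,) = read_study_file(p)
        assert rec.ssv_id == "essv1"
        assert rec.study_id == "nstd1"
        assert rec.variant_type == "deletion"
        assert rec.chrom == "1"
        assert rec.start == 100 and rec.stop == 300
        assert rec.outer_start is None and rec.inner_stop is None

    def test_unparsable_coordinate_is_rejected_not_fatal(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_rows(p, [simple_row(start="abc"), simple_row(ssv_id="essv2")])
        errlog = ErrorLog()
        recs = list(read_study_file(p, errlog=errlog))
        assert [r.ssv_id for r in recs] == ["essv2"]
        assert len(errlog) == 1
        assert errlog.rejections[0].line_number == 2
        assert "coordinate" in errlog.rejections[0].reason

    def test_out_of_order_tiers_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        row = ("essv1", "nstd1", "deletion", "1", 150, 100, "", "", 300, "", "GRCh38")
        write_rows(p, [row])
        errlog = ErrorLog()
        assert list(read_study_file(p, errlog=errlog)) == []
        assert len(errlog) == 1

    def test_assembly_filtering_skips_quietly(self, tmp_path):
        p = tmp_path / "s.tsv"
        rows = [simple_row(), simple_row(ssv_id="essv2")]
        rows[1] = rows[1][:-1] + ("GRCh37",)
        write_rows(p, rows)
        errlog = ErrorLog()
        recs = list(read_study_file(p, errlog=errlog, assembly="GRCh38"))
        assert [r.ssv_id for r in recs] == ["essv1"]
        assert len(errlog) == 0  # assembly mismatch is a skip, not an error

    def test_variant_type_normalized(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_rows(p, [simple_row(vtype="Copy  Number\tVariation".replace("\t", " "))])
        (rec,) = read_study_file(p)
        assert rec.variant_type == "copy number variation"

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("#a\tb\nx\ty\n")
        with pytest.raises(ConfigurationError):
            list(read_study_file(p))

    def test_roundtrip_reserializes_same_records(self, tmp_path):
        p = tmp_path / "s.tsv"
        rows = [
            simple_row(),
            ("essv2", "nstd2", "duplication", "2", 90, 100, 110, 280, 300, 320, "GRCh38"),
        ]
        write_rows(p, rows)
        recs = list(read_study_file(p))
        p2 = tmp_path / "s2.tsv"
        write_study_file(recs, p2)
        assert list(read_study_file(p2)) == recs


class TestColumnMap:
    def test_missing_mandatory_field_rejected(self):
        with pytest.raises(ConfigurationError):
            ColumnMap(columns={"ssv_id": "id"})

    def test_unknown_field_rejected(self):
        cols = {f: f for f in ("ssv_id", "study_id", "variant_type", "chrom")}
        with pytest.raises(ConfigurationError):
            ColumnMap(columns={**cols, "bogus": "x"})

    def test_from_yaml(self, tmp_path):
        p = tmp_path / "colmap.yaml"
        p.write_text(
            "columns:\n  ssv_id: variant_call_id\n  study_id: study\n"
            "  variant_type: type\n  chrom: chr\n  start: outermost_start\n  stop: outermost_stop\n"
            "has_header: true\n"
        )
        cm = ColumnMap.from_yaml(p)
        assert cm.columns["ssv_id"] == "variant_call_id"
        assert cm.has_header

    def test_index_based_map_without_header(self, tmp_path):
        cm = ColumnMap(
            columns={"ssv_id": 0, "study_id": 1, "variant_type": 2, "chrom": 3, "start": 4, "stop": 5},
            has_header=False,
        )
        p = tmp_path / "s.tsv"
        p.write_text("essv9\tnstd9\tinsertion\tX\t5\t6\n")
        (rec,) = read_study_file(p, cm)
        assert rec.ssv_id == "essv9" and rec.chrom == "X" and rec.start == 5


class TestResolvePlacement:
    def test_exact_coordinates_convert_to_half_open(self):
        rec = SSVRecord("a", "s", "deletion", "1", start=100, stop=300)
        assert resolve_placement(rec, "outermost") == GenomicInterval("1", 99, 300)

    def test_outermost_takes_extremes(self):
        rec = SSVRecord("a", "s", "deletion", "1", outer_start=90, start=100, stop=300, outer_stop=320)
        assert resolve_placement(rec, "outermost") == GenomicInterval("1", 89, 320)

    def test_innermost_takes_opposite_extremes(self):
        rec = SSVRecord("a", "s", "deletion", "1", outer_start=90, start=100, stop=300, outer_stop=320)
        assert resolve_placement(rec, "innermost") == GenomicInterval("1", 99, 300)

    def test_unknown_policy(self):
        rec = SSVRecord("a", "s", "deletion", "1", start=1, stop=2)
        with pytest.raises(ValueError):
            resolve_placement(rec, "midpoint")

    @given(
        outer_start=st.integers(1, 50),
        d1=st.integers(0, 10),
        d2=st.integers(0, 10),
        inner_len=st.integers(0, 30),
        d3=st.integers(0, 10),
        d4=st.integers(0, 10),
    )
    def test_innermost_contained_in_outermost(self, outer_start, d1, d2, inner_len, d3, d4):
        start = outer_start + d1
        inner_start = start + d2
        inner_stop = inner_start + inner_len
        stop = inner_stop + d3
        outer_stop = stop + d4
        rec = SSVRecord(
            "a", "s", "deletion", "1",
            outer_start=outer_start, start=start, inner_start=inner_start,
            inner_stop=inner_stop, stop=stop, outer_stop=outer_stop,
        )
        rec.validate()
        assert innermost_within_outermost(rec)


class TestChromOrder:
    def test_natural_order(self):
        names = ["10", "2", "X", "1", "MT", "Y", "22"]
        assert sorted(names, key=chrom_sort_key) == ["1", "2", "10", "22", "X", "Y", "MT"]

    def test_chr_prefix_recognized(self):
        assert chrom_sort_key("chr2") == chrom_sort_key("2")

    def test_unrecognized_lexicographic_after_canonical(self):
        assert chrom_sort_key("scaffold_12") > chrom_sort_key("MT")

    def test_refseq_alias_table(self):
        aliases = {"NC_000001.11": "1"}
        assert chrom_sort_key("NC_000001.11", aliases) == chrom_sort_key("1")


class TestMergeStudies:
    def test_cross_file_chromosome_order(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_rows(p1, [simple_row(ssv_id="e1", chrom="2", start=11, stop=20)])
        write_rows(p2, [simple_row(ssv_id="e2", chrom="1", start=6, stop=15)])
        pairs = merge_studies([p1, p2])
        assert [p[1].chrom for p in pairs] == ["1", "2"]

    def test_within_file_reordering(self, tmp_path):
        p = tmp_path / "a.tsv"
        write_rows(
            p,
            [
                simple_row(ssv_id="e1", start=51, stop=60),
                simple_row(ssv_id="e2", start=11, stop=20),
            ],
        )
        pairs = merge_studies([p])
        assert [r.ssv_id for r, _ in pairs] == ["e2", "e1"]

    def test_matches_full_sort_oracle(self, tmp_path):
        rng = random.Random(42)
        paths = []
        expected = []
        for i in range(3):
            rows = []
            for j in range(100):
                chrom = rng.choice(["1", "2", "10", "X"])
                start = rng.randint(1, 900)
                stop = start + rng.randint(0, 99)
                ssv_id = f"essv{i}_{j}"
                rows.append(simple_row(ssv_id=ssv_id, chrom=chrom, start=start, stop=stop))
                expected.append((chrom_sort_key(chrom), start - 1, stop, ssv_id))
            p = tmp_path / f"f{i}.tsv"
            write_rows(p, rows)
            paths.append(p)
        pairs = merge_studies(paths)
        got = [(chrom_sort_key(iv.chrom), iv.start, iv.end, rec.ssv_id) for rec, iv in pairs]
        assert got == sorted(expected)

    def test_output_totally_ordered_pairwise(self, tmp_path):
        p = tmp_path / "a.tsv"
        rng = random.Random(7)
        write_rows(
            p,
            [
                simple_row(ssv_id=f"e{j}", chrom=rng.choice(["1", "2"]), start=rng.randint(1, 50), stop=60)
                for j in range(50)
            ],
        )
        pairs = merge_studies([p])
        keys = [(chrom_sort_key(iv.chrom), iv.start, iv.end, rec.ssv_id) for rec, iv in pairs]
        assert all(a <= b for a, b in zip(keys, keys[1:]))

    def test_merged_tsv_roundtrip(self, tmp_path):
        p = tmp_path / "a.tsv"
        write_rows(p, [simple_row(), simple_row(ssv_id="essv2", start=5, stop=9)])
        pairs = merge_studies([p])
        out = tmp_path / "merged.tsv"
        write_merged_tsv(pairs, out)
        back = read_merged_tsv(out)
        assert [(r.ssv_id, iv) for r, iv in back] == [(r.ssv_id, iv) for r, iv in pairs]


def test_normalize_variant_type_aliases():
    assert normalize_variant_type(" Copy  Number LOSS ") == "copy number loss"
    aliases = {"cnv": "copy number variation"}
    assert normalize_variant_type("CNV", aliases) == "copy number variation"


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval("1", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("1", -1, 5)
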
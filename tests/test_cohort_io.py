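"""Mutation/clinical table IO and the variant-level filter rules."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutpanel.cohort_io import (
    ClinicalRecord,
    FilterConfig,
    MutationRecord,
    TableDialect,
    apply_variant_filters,
    read_clinical_table,
    read_mutation_table,
    write_mutation_table,
)

MAF_HEADER = "Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\tVariant_Type\tt_alt_count\tAF\tdbSNP_Common"


def _write_maf(path, rows):
    lines = [MAF_HEADER] + ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


# Hand-written 10-row fixture covering the dialect's classification map.
MAF_ROWS = [
    ("S1", "TP53", "Missense_Mutation", "SNP", 120, 0.0001, "false"),
    ("S1", "KRAS", "Nonsense_Mutation", "SNP", 80, "", "false"),
    ("S2", " zfhx3 ", "Missense_Mutation", "SNP", 200, 0.0, ""),
    ("S2", "EGFR", "Frame_Shift_Del", "DEL", 90, "", ""),
    ("S2", "STK11", "In_Frame_Ins", "INS", 55, "", ""),
    ("S3", "BRAC2", "Splice_Site", "SNP", 61, "", ""),
    ("S3", "TP53", "Silent", "SNP", 70, "", ""),
    ("S3", "KEAP1", "Intron", "SNP", 75, "", ""),
    ("S4", "MET", "Weird_New_Class", "SNP", 66, "", ""),
    ("S4", "ALK", "Missense_Mutation", "SNP", 30, 0.05, "true"),
]

EXPECTED_CLASSIFICATIONS = [
    "missense", "nonsense", "missense", "frameshift_indel", "inframe_indel",
    "splice", "silent", "intron", "other", "missense",
]


class TestMutationReader:
    def test_row_count_and_dialect_mapping(self, tmp_path):
        path = tmp_path / "muts.tsv"
        _write_maf(path, MAF_ROWS)
        records = read_mutation_table(path)
        assert len(records) == len(MAF_ROWS)
        assert [r.variant_classification for r in records] == EXPECTED_CLASSIFICATIONS
        assert records[0].variant_type == "SNV"
        assert records[3].variant_type == "deletion"
        assert records[4].variant_type == "insertion"

    def test_gene_symbols_uppercased_trimmed_and_alias(self, tmp_path):
        path = tmp_path / "muts.tsv"
        _write_maf(path, MAF_ROWS)
        records = read_mutation_table(path)
        assert records[2].gene == "ZFHX3"
        assert records[5].gene == "BRCA2"  # BRAC2 typo alias

    def test_missing_mandatory_column_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Tumor_Sample_Barcode\tVariant_Classification\nS1\tSilent\n")
        with pytest.raises(ValueError, match="Hugo_Symbol"):
            read_mutation_table(path)

    def test_empty_file_yields_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(MAF_HEADER + "\n")
        assert read_mutation_table(path) == []

    def test_round_trip_preserves_fields(self, tmp_path):
        path = tmp_path / "muts.tsv"
        _write_maf(path, MAF_ROWS)
        records = read_mutation_table(path)
        out = tmp_path / "rt.tsv"
        write_mutation_table(records, out)
        assert read_mutation_table(out) == records


class TestClinicalReader:
    def test_basic_parse(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime_months\tevent\nS1\t9.0\t1\nS2\t14.5\talive\n")
        recs = read_clinical_table(path)
        assert recs[0] == ClinicalRecord("S1", 9.0, 1)
        assert recs[1].event == 0

    def test_unparseable_time_reports_row_index(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime_months\tevent\nS1\t9.0\t1\nS2\tNA\t0\n")
        with pytest.raises(ValueError, match=r"\[1\]"):
            read_clinical_table(path)

    def test_negative_time_is_hard_error(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text("sample_id\ttime_months\tevent\nS1\t-2\t1\n")
        with pytest.raises(ValueError):
            read_clinical_table(path)


def _rec(**kw):
    base = dict(sample_id="S1", gene="TP53", variant_classification="missense",
                variant_type="SNV")
    base.update(kw)
    return MutationRecord(**base)


class TestVariantFilters:
    def test_silent_removed_missense_kept(self):
        recs = [_rec(variant_classification="silent"), _rec()]
        retained, report = apply_variant_filters(recs)
        assert len(retained) == 1 and retained[0].variant_classification == "missense"
        assert report.removals == {"silent": 1}

    def test_population_af_above_one_percent_removed(self):
        retained, _ = apply_variant_filters([_rec(population_af=0.02)])
        assert retained == []

    def test_read_support_boundary_is_strict_less_than(self):
        at, below = _rec(supporting_reads=50), _rec(supporting_reads=49)
        retained, report = apply_variant_filters([at, below])
        assert retained == [at]
        assert report.removals == {"read_support": 1}

    def test_intron_and_dbsnp_rules(self):
        recs = [_rec(variant_classification="intron"), _rec(dbsnp_common_flag=True)]
        retained, report = apply_variant_filters(recs)
        assert retained == []
        assert report.removals == {"intron": 1, "dbsnp_common": 1}

    def test_permissive_config_is_identity_on_missense(self):
        cfg = FilterConfig(
            drop_silent=False, drop_intronic=False, max_population_af=1.0,
            drop_dbsnp_common=False, min_supporting_reads=0, drop_cnv_fusion=False,
        )
        recs = [_rec(), _rec(gene="KRAS"), _rec(variant_classification="silent")]
        retained, _ = apply_variant_filters(recs, cfg)
        assert retained == recs

    def test_missing_optional_fields_fail_open(self):
        rec = _rec(supporting_reads=None, population_af=None, dbsnp_common_flag=None)
        retained, report = apply_variant_filters([rec])
        assert retained == [rec]
        assert set(report.skipped_rules) == {"population_af", "dbsnp_common", "read_support"}


record_strategy = st.builds(
    MutationRecord,
    sample_id=st.sampled_from(["S1", "S2", "S3"]),
    gene=st.sampled_from(["TP53", "KRAS", "ZFHX3"]),
    variant_classification=st.sampled_from(
        ["missense", "silent", "intron", "cnv", "fusion", "other"]
    ),
    variant_type=st.sampled_from(["SNV", "insertion", "deletion", "other"]),
    supporting_reads=st.one_of(st.none(), st.integers(0, 200)),
    population_af=st.one_of(st.none(), st.floats(0, 1, allow_nan=False)),
    dbsnp_common_flag=st.one_of(st.none(), st.booleans()),
)


@settings(max_examples=50, derandomize=True)
@given(st.lists(record_strategy, max_size=40))
def test_filter_conservation_and_idempotence(records):
    """Every record is retained or attributed to exactly one rule, and
    refiltering the retained set changes nothing."""
    retained, report = apply_variant_filters(records)
    assert report.retained_count + sum(report.removals.values()) == report.input_count
    again, report2 = apply_variant_filters(retained)
    assert again == retained
    assert report2.removals == {}


def test_mutation_record_validation():
    with pytest.raises(ValueError):
        MutationRecord(sample_id=" ", gene="TP53")
    with pytest.raises(ValueError):
        MutationRecord(sample_id="S1", gene="TP53", population_af=1.5)
    # unknown classification maps to "other", not an error
    assert MutationRecord("S1", "TP53", variant_classification="bogus").variant_classification == "other"
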
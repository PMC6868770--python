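"""Horizontal integration: delimiters, headers, semi-structures, the store."""
from __future__ import annotations

import itertools
import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from oncointegrate import semistructure as ss
from oncointegrate.errors import (
    DelimiterError,
    MissingAttributeHeaderError,
    SchemaViolationError,
    StoreFormatError,
)


def make_record(fields, i=0, data_type="clinical"):
    return ss.RawRecord(
        record_id=f"r{i}", sample_id=f"p{i}", data_type=data_type,
        fields={name: "x" for name in fields},
    )


class TestDetectDelimiter:
    @pytest.mark.parametrize(
        "lines, expected",
        [
            (["a,b,c", "1,2,3"], ","),
            (["a\tb", "1\t2"], "\t"),
            (["a;b", "1;2"], ";"),
            # comma gives 3 consistent columns, tab only 2: maximal wins
            (["a,b\tc,d", "1,2\t3,4"], ","),
        ],
    )
    def test_candidates(self, lines, expected):
        assert ss.detect_delimiter(lines) == expected

    def test_header_lines_are_ignored(self):
        assert ss.detect_delimiter(["#k=v", "a\tb", "1\t2"]) == "\t"

    def test_undetectable_names_the_file(self):
        with pytest.raises(DelimiterError, match="bad.txt"):
            ss.detect_delimiter(["abc", "def"], filename="bad.txt")

    def test_too_few_lines(self):
        with pytest.raises(DelimiterError):
            ss.detect_delimiter(["a,b"])


class TestParseHeader:
    def test_metadata_extraction(self):
        meta = ss.parse_header(["#technology=RNA-Seq", "#ref=EXP001", "id,stage", "1,2"])
        assert meta.technology == "RNA-Seq"
        assert list(meta.referenced_file_ids) == ["EXP001"]
        assert list(meta.attribute_names) == ["id", "stage"]

    def test_degenerate_header(self):
        meta = ss.parse_header(["id\tsize", "1\t2"])
        assert meta.technology == ""
        assert meta.referenced_file_ids == ()
        assert list(meta.attribute_names) == ["id", "size"]

    def test_missing_attribute_row(self):
        with pytest.raises(MissingAttributeHeaderError):
            ss.parse_header(["#technology=x"], filename="f.csv")

    def test_conflicting_technology_keeps_first(self):
        meta = ss.parse_header(
            ["#technology=A", "#technology=B", "id,stage", "1,2"]
        )
        assert meta.technology == "A"

    def test_roundtrip_against_generator_manifest(self, cohort_dir, manifest):
        for study, files in manifest["studies"].items():
            lines = (cohort_dir / files["clinical"]).read_text().splitlines()
            meta = ss.parse_header(lines)
            assert list(meta.referenced_file_ids) == [files["expression_file_id"]]
            assert meta.n_declared_attributes == 6


class TestFoldRecord:
    def test_base_case(self):
        semi = ss.fold_record(ss.empty_semistructure("clinical"), make_record(["a", "b"]))
        assert dict(semi.field_stats) == {"a": 1, "b": 1}
        assert semi.record_count == 1

    def test_multiset_counts_all_orders(self):
        records = [make_record(f, i) for i, f in enumerate([["a", "b"], ["a"], ["a", "c"]])]
        for perm in itertools.permutations(records):
            semi = ss.fold_records(ss.empty_semistructure("clinical"), perm)
            assert dict(semi.field_stats) == {"a": 3, "b": 1, "c": 1}
            assert semi.record_count == 3

    def test_duplicates_counted_not_deduplicated(self):
        rec = make_record(["a", "b"])
        semi = ss.fold_records(ss.empty_semistructure("clinical"), [rec, rec])
        assert dict(semi.field_stats) == {"a": 2, "b": 2}
        assert semi.record_count == 2

    def test_input_not_mutated(self):
        semi0 = ss.empty_semistructure("clinical")
        ss.fold_record(semi0, make_record(["a"]))
        assert semi0.record_count == 0 and not semi0.field_stats

    def test_data_type_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            ss.fold_record(
                ss.empty_semistructure("expression"), make_record(["a"])
            )

    @given(
        st.lists(
            st.lists(st.sampled_from("abcdefgh"), unique=True, max_size=6),
            max_size=6,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_incremental_equals_batch_oracle(self, field_sets):
        """Folding record by record equals a one-pass multiset count."""
        records = [make_record(f, i) for i, f in enumerate(field_sets)]
        semi = ss.fold_records(ss.empty_semistructure("clinical"), records)
        oracle = Counter(name for f in field_sets for name in f)
        assert dict(semi.field_stats) == dict(oracle)
        assert semi.record_count == len(records)
        # count conservation
        assert sum(semi.field_stats.values()) == sum(len(f) for f in field_sets)


class TestApplySchema:
    def test_projection_keeps_known_fields(self):
        rec = ss.RawRecord("r1", "p1", "clinical", {"stage": "2"})
        semi = ss.fold_record(ss.empty_semistructure("clinical"), rec)
        doc = ss.apply_schema(rec, semi)
        assert doc["fields"] == {"stage": "2"}
        assert doc["record_id"] == "r1" and doc["sample_id"] == "p1"

    def test_missing_sample_id_is_violation(self):
        rec = ss.RawRecord("r1", "", "clinical", {"stage": "2"})
        semi = ss.empty_semistructure("clinical")
        with pytest.raises(SchemaViolationError, match="ID/Sample ID"):
            ss.apply_schema(rec, semi)

    def test_unknown_field_dropped(self, caplog):
        semi = ss.fold_record(
            ss.empty_semistructure("clinical"),
            ss.RawRecord("r0", "p0", "clinical", {"stage": "1"}),
        )
        rec = ss.RawRecord("r1", "p1", "clinical", {"stage": "2", "foo": "x"})
        with caplog.at_level("WARNING"):
            doc = ss.apply_schema(rec, semi)
        assert "foo" not in doc["fields"]
        assert any("foo" in m for m in caplog.messages)


class TestDocumentStore:
    def test_empty_roundtrip(self, tmp_path):
        path = tmp_path / "docs.jsonl"
        ss.store_documents([], path)
        assert ss.load_documents(path) == []

    def test_roundtrip_and_canonical_bytes(self, tmp_path):
        rng = random.Random(0)
        docs = [
            {
                "record_id": f"r{i}",
                "sample_id": f"p{i}",
                "data_type": "clinical",
                "source_file": "f",
                "source_study": "s",
                "fields": {"stage": str(rng.randint(1, 4)), "age": str(rng.randint(1, 99))},
            }
            for i in range(100)
        ]
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        ss.store_documents(docs, p1)
        ss.store_documents(docs, p2)
        assert ss.load_documents(p1) == docs
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"a": 1}\nnot json\n')
        with pytest.raises(StoreFormatError, match="line 2"):
            ss.load_documents(path)


class TestReadRecords:
    def test_expression_matrix_transposed_to_patient_records(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("Hugo_Symbol\tp1\tp2\ntp53\t1.0\t2.0\nBRCA1\t3.0\t4.0\n")
        records = ss.read_records(path, "expression", "S")
        by_sample = {r.sample_id: r for r in records}
        assert set(by_sample) == {"p1", "p2"}
        assert by_sample["p2"].fields == {"TP53": "2.0", "BRCA1": "4.0"}

    def test_clinical_rows(self, tmp_path):
        path = tmp_path / "clin.csv"
        path.write_text("id,Sample ID,Stage\nr1,p1,III\nr2,p2,II\n")
        records = ss.read_records(path, "clinical", "S")
        assert [r.sample_id for r in records] == ["p1", "p2"]
        assert records[0].record_id == "r1"
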
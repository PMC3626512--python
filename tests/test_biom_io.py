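"""BIOM JSON parsing, canonical writing, and the format validator."""
import json

import pytest
from hypothesis import given, settings, strategies as st

from biomlite import (
    BiomFormatError,
    cells_equal,
    parse_biom,
    to_dense,
    validate,
    write_biom,
)
from biomlite.benchmark import SynthSpec, generate_table

from conftest import make_random_table


def codes(report, severity="error"):
    return {v.code for v in report.violations if v.severity == severity}


class TestParse:
    def test_minimal_sparse_document(self, minimal_sparse_doc):
        t = parse_biom(json.dumps(minimal_sparse_doc))
        assert t.shape == (1, 1)
        assert t.payload.triples == [(0, 0, 1)]
        assert t.observations[0].metadata is None

    def test_missing_type_key_is_a_format_error(self, minimal_sparse_doc):
        del minimal_sparse_doc["type"]
        with pytest.raises(BiomFormatError) as exc:
            parse_biom(json.dumps(minimal_sparse_doc))
        assert any("'type'" in v.message for v in exc.value.report.errors)

    def test_malformed_json_raises_parse_error(self):
        with pytest.raises(json.JSONDecodeError):
            parse_biom("not json {")

    def test_unknown_keys_preserved_on_extra_and_not_rewritten(self, minimal_sparse_doc):
        minimal_sparse_doc["comment"] = "hello"
        t = parse_biom(json.dumps(minimal_sparse_doc))
        assert t.extra == {"comment": "hello"}
        assert "comment" not in json.loads(write_biom(t))

    def test_parser_tolerates_whitespace_and_key_order(self, minimal_sparse_doc):
        reordered = dict(reversed(list(minimal_sparse_doc.items())))
        pretty = json.dumps(reordered, indent=4)
        assert cells_equal(parse_biom(pretty), parse_biom(json.dumps(minimal_sparse_doc)))


class TestWrite:
    @pytest.mark.parametrize("matrix_type", ["sparse", "dense"])
    @pytest.mark.parametrize("element_type", ["int", "float"])
    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_identity(self, seed, element_type, matrix_type):
        t = make_random_table(seed, element_type=element_type,
                              with_taxonomy=True, with_sample_metadata=True)
        if matrix_type == "dense":
            t = to_dense(t)
        assert parse_biom(write_biom(t, matrix_type)) == t

    def test_cross_form_agreement(self):
        t = make_random_table(42, with_taxonomy=True)
        via_sparse = parse_biom(write_biom(t, "sparse"))
        via_dense = parse_biom(write_biom(t, "dense"))
        assert cells_equal(via_sparse, via_dense)
        assert [e.id for e in via_sparse.observations] == [e.id for e in via_dense.observations]

    def test_all_zero_sparse_document_has_empty_data_and_validates(self, grid_table_factory):
        t = grid_table_factory([[0, 0], [0, 0]])
        text = write_biom(t, "sparse")
        assert '"data":[]' in text
        assert validate(text).is_valid

    def test_writer_is_deterministic(self):
        t = make_random_table(5, with_taxonomy=True)
        assert write_biom(t, "sparse") == write_biom(t, "sparse")
        assert write_biom(t, "dense") == write_biom(t, "dense")

    def test_writer_emits_compact_canonical_key_order(self, minimal_sparse_doc):
        t = parse_biom(json.dumps(minimal_sparse_doc))
        text = write_biom(t, "sparse")
        assert ": " not in text and ", " not in text
        keys = list(json.loads(text))
        assert keys == ["id", "format", "format_url", "type", "generated_by", "date",
                        "rows", "columns", "matrix_type", "matrix_element_type",
                        "shape", "data"]

    def test_sparse_smaller_than_dense_at_one_percent_density(self):
        t = generate_table(SynthSpec(n_samples=1000, n_observations=1000,
                                     density=0.01, seed=1))
        assert len(write_biom(t, "sparse")) < len(write_biom(t, "dense"))

    def test_float_values_render_with_decimal_point(self, grid_table_factory):
        t = grid_table_factory([[5]], element_type="float")
        assert json.loads(write_biom(t, "sparse"))["data"] == [[0, 0, 5.0]]
        assert "5.0" in write_biom(t, "sparse")

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_validate_accepts_every_written_table(self, seed):
        t = make_random_table(seed, with_taxonomy=seed % 2 == 0)
        for kind in ("sparse", "dense"):
            assert validate(write_biom(t, kind)).is_valid


class TestValidator:
    def test_minimal_document_has_zero_errors(self, minimal_sparse_doc):
        assert validate(json.dumps(minimal_sparse_doc)).is_valid

    def test_unreadable_json_is_a_single_error_entry(self):
        report = validate(b"\x00 not json")
        assert [v.code for v in report.violations] == ["json-malformed"]

    def test_rows_shape_mismatch(self, minimal_sparse_doc):
        minimal_sparse_doc["shape"] = [2, 2]
        minimal_sparse_doc["columns"].append({"id": "S2", "metadata": None})
        report = validate(json.dumps(minimal_sparse_doc))
        assert "shape/rows-length-mismatch" in codes(report)

    def test_sparse_index_out_of_range(self, minimal_sparse_doc):
        minimal_sparse_doc["data"] = [[5, 0, 1]]
        assert "index-out-of-range" in codes(validate(json.dumps(minimal_sparse_doc)))

    def test_duplicate_coordinate_is_error(self, minimal_sparse_doc):
        minimal_sparse_doc["data"] = [[0, 0, 1], [0, 0, 2]]
        assert "duplicate-coordinate" in codes(validate(json.dumps(minimal_sparse_doc)))

    def test_explicit_zero_is_warning_not_error(self, minimal_sparse_doc):
        minimal_sparse_doc["data"] = [[0, 0, 0]]
        report = validate(json.dumps(minimal_sparse_doc))
        assert report.is_valid
        assert "explicit-zero" in codes(report, "warning")

    def test_duplicate_row_ids_are_error(self, minimal_sparse_doc):
        minimal_sparse_doc["shape"] = [2, 1]
        minimal_sparse_doc["rows"] = [{"id": "O1", "metadata": None}] * 2
        assert "duplicate-row-id" in codes(validate(json.dumps(minimal_sparse_doc)))

    def test_bad_matrix_type_is_error(self, minimal_sparse_doc):
        minimal_sparse_doc["matrix_type"] = "diagonal"
        assert "matrix-type-malformed" in codes(validate(json.dumps(minimal_sparse_doc)))

    def test_dense_row_length_checked(self, minimal_sparse_doc):
        minimal_sparse_doc["matrix_type"] = "dense"
        minimal_sparse_doc["data"] = [[1, 2]]
        assert "dense-row-length-mismatch" in codes(validate(json.dumps(minimal_sparse_doc)))

    def test_unparseable_date_is_warning(self, minimal_sparse_doc):
        minimal_sparse_doc["date"] = "yesterday-ish"
        report = validate(json.dumps(minimal_sparse_doc))
        assert report.is_valid
        assert "date-not-iso8601" in codes(report, "warning")

    def test_format_string_mismatch_is_warning(self, minimal_sparse_doc):
        minimal_sparse_doc["format"] = "BIOM 9.9"
        report = validate(json.dumps(minimal_sparse_doc))
        assert report.is_valid
        assert "format-mismatch" in codes(report, "warning")

    def test_unconventional_table_type_is_warning(self, minimal_sparse_doc):
        minimal_sparse_doc["type"] = "Quasar table"
        report = validate(json.dumps(minimal_sparse_doc))
        assert report.is_valid
        assert "unknown-table-type" in codes(report, "warning")
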
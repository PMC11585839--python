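import numpy as np
import pandas as pd
import pytest

from macpolar import (ExpressionMatrix, ParseError, attach_gene_map,
                      ensure_log2, normalize_counts, read_annotation,
                      read_matrix, write_annotation, write_matrix)
from macpolar.expression_io import SampleAnnotation, looks_log_scaled

from conftest import annotation_for, matrix_from_rows


class TestReadMatrix:
    def test_tsv_with_empty_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ts2\ng1\t1.5\t2.5\ng2\t\t3.0\ng3\t4.0\t5.0\n")
        m = read_matrix(path)
        assert m.values.shape == (3, 2)
        assert np.isnan(m.values.loc["g2", "s1"])
        assert m.values.isna().sum().sum() == 1
        assert m.scale_tag == "unknown"

    def test_unparseable_cell_becomes_missing(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ts2\ng1\tfoo\t2.5\n")
        m = read_matrix(path)
        assert np.isnan(m.values.loc["g1", "s1"])

    def test_repeated_sample_column_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(ParseError, match="s1"):
            read_matrix(path)

    def test_duplicate_row_id_rejected_with_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ng1\t1\ng1\t2\n")
        with pytest.raises(ParseError, match="line 3"):
            read_matrix(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("id\ts1\ts2\ng1\t1\n")
        with pytest.raises(ParseError, match="line 2"):
            read_matrix(path)

    def test_series_matrix_fenced_table_and_metadata(self, tmp_path):
        path = tmp_path / "gse.txt"
        path.write_text(
            '!Series_title\t"demo"\n'
            '!Sample_title\t"a"\t"b"\n'
            '!Sample_characteristics_ch1\t"pre"\t"post"\n'
            "!series_matrix_table_begin\n"
            '"ID_REF"\t"GSM1"\t"GSM2"\n'
            '"g1"\t1.0\t2.0\n'
            '"g2"\t3.0\t4.0\n'
            "!series_matrix_table_end\n")
        m = read_matrix(path, format="series_matrix")
        assert list(m.sample_ids) == ["GSM1", "GSM2"]
        assert m.values.loc["g2", "GSM2"] == 4.0
        # !Sample_ lines retained as an annotation source; other metadata dropped
        assert m.metadata["Sample_characteristics_ch1"] == [["pre", "post"]]
        assert "Series_title" not in m.metadata

    def test_series_matrix_without_fences_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("id\ts1\ng1\t1\n")
        with pytest.raises(ParseError, match="fence"):
            read_matrix(path, format="series_matrix")


class TestRoundTrip:
    def test_write_then_read_preserves_values_and_ids(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(5, 2, size=(6, 4))
        vals[2, 1] = np.nan
        m = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(6)], columns=list("abcd")))
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path)
        pd.testing.assert_frame_equal(back.values, m.values)


class TestNormalizeCounts:
    def test_zero_count_maps_to_exactly_zero(self):
        counts = pd.DataFrame({"s1": [999999, 1, 0]}, index=["g1", "g2", "g3"])
        m = normalize_counts(counts, method="cpm")
        assert m.values.loc["g3", "s1"] == 0.0
        assert m.scale_tag == "log2cpm"

    def test_equal_counts_closed_form(self):
        counts = pd.DataFrame({"s1": [250, 250, 250, 250]},
                              index=list("abcd")) * 1000
        m = normalize_counts(counts, method="cpm")
        assert np.allclose(m.values["s1"], np.log2(250000 + 1))

    def test_cpm_hand_computed(self):
        # counts [10, 90], library 100 → CPM [1e5, 9e5]
        counts = pd.DataFrame({"s1": [10, 90]}, index=["g1", "g2"])
        m = normalize_counts(counts, method="cpm")
        assert m.values.loc["g1", "s1"] == pytest.approx(np.log2(100001), rel=1e-12)
        assert m.values.loc["g2", "s1"] == pytest.approx(np.log2(900001), rel=1e-12)

    def test_cpm_column_sums_recover_one_million(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 500, size=(50, 3)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("xyz"))
        m = normalize_counts(counts, method="cpm")
        sums = (2.0 ** m.values - 1.0).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_rpkm_requires_lengths_and_scales_by_kb(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="gene_lengths"):
            normalize_counts(counts, method="rpkm")
        lengths = pd.Series({"g1": 1.0, "g2": 2.0})
        m = normalize_counts(counts, method="rpkm", gene_lengths=lengths)
        # same counts, double length → half the RPKM
        r1 = 2 ** m.values.loc["g1", "s1"] - 1
        r2 = 2 ** m.values.loc["g2", "s1"] - 1
        assert r1 == pytest.approx(2 * r2)

    def test_negative_counts_rejected(self):
        counts = pd.DataFrame({"s1": [-1, 5]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="nonnegative"):
            normalize_counts(counts)


class TestAttachGeneMap:
    def test_two_probes_same_gene_both_retained(self):
        m = matrix_from_rows({"p1": [1, 2], "p2": [3, 4], "p3": [5, 6]})
        mapped = attach_gene_map(m, {"p1": "GENEA", "p2": "GENEA"})
        assert list(mapped.gene_of_row) == ["GENEA", "GENEA", "p3"]
        assert mapped.n_rows == 3
        assert list(mapped.rows_for_gene("GENEA")) == ["p1", "p2"]

    def test_empty_mapping_is_identity(self):
        m = matrix_from_rows({"p1": [1, 2]})
        mapped = attach_gene_map(m, {})
        assert list(mapped.gene_of_row) == ["p1"]

    def test_unknown_probe_ignored_with_warning(self, caplog):
        m = matrix_from_rows({"p1": [1, 2]})
        with caplog.at_level("WARNING", logger="macpolar"):
            mapped = attach_gene_map(m, {"nope": "G"})
        assert "match no row" in caplog.text
        assert list(mapped.gene_of_row) == ["p1"]


class TestScaleHeuristic:
    def test_linear_scale_detected_and_transformed(self):
        m = matrix_from_rows({"g1": [10000.0, 200.0], "g2": [1.0, 3000.0]})
        assert not looks_log_scaled(m)
        out = ensure_log2(m)
        assert out.values.loc["g1", "s1"] == pytest.approx(np.log2(10001))

    def test_log_scale_left_alone_and_force_override(self):
        m = matrix_from_rows({"g1": [4.0, 8.0]})
        assert looks_log_scaled(m)
        assert ensure_log2(m) is m
        forced = ensure_log2(m, force=True)
        assert forced.values.loc["g1", "s2"] == pytest.approx(np.log2(9))


class TestSampleAnnotation:
    def test_condition_split_infers_post_positive(self):
        ann = annotation_for(["a", "b", "c", "d"], ["pre", "post", "pre", "post"])
        neg, pos, neg_label, pos_label = ann.condition_split()
        assert (neg_label, pos_label) == ("pre", "post")
        assert neg == ["a", "c"] and pos == ["b", "d"]

    def test_sedentary_trained_split(self):
        ann = annotation_for(["a", "b"], ["trained", "sedentary"])
        _, pos, _, pos_label = ann.condition_split()
        assert pos_label == "trained" and pos == ["a"]

    def test_unknown_levels_need_explicit_positive(self):
        ann = annotation_for(["a", "b"], ["M1", "M2"])
        with pytest.raises(ValueError, match="positive"):
            ann.condition_split()
        _, pos, _, _ = ann.condition_split(positive_label="M2")
        assert pos == ["b"]

    def test_validate_requires_samples_in_matrix_and_two_levels(self):
        m = matrix_from_rows({"g1": [1, 2]})
        ann = annotation_for(["s1", "s2"], ["pre", "pre"])
        with pytest.raises(ValueError, match="two levels"):
            ann.validate_with_matrix(m)
        ann2 = annotation_for(["s1", "zz"], ["pre", "post"])
        with pytest.raises(ValueError, match="absent"):
            ann2.validate_with_matrix(m)

    def test_annotation_round_trip(self, tmp_path):
        ann = annotation_for(["a", "b"], ["pre", "post"], gender=["F", "M"])
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        back = read_annotation(path)
        pd.testing.assert_frame_equal(back.table, ann.table)
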
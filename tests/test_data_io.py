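"""File-format readers/writers and signature-integrity QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codegnet import (
    GeneSetLibrary,
    PPINetwork,
    StudyMetadata,
    read_expression_matrix,
    read_gmt,
    read_ppi,
    validate_signature_metadata,
    write_expression_matrix,
    write_gmt,
    write_ppi,
)
from codegnet.data_io import read_gene_list, write_gene_list

from conftest import make_study


class TestExpressionMatrix:
    def test_round_trip(self, tmp_path):
        study = make_study([[1.5, 2.0, 3.25, 4.0], [0.5, 1.0, 1.5, 2.0], [7.0, 8.0, 9.0, 10.0]])
        path = tmp_path / "m.tsv"
        write_expression_matrix(study, path)
        back = read_expression_matrix(path, study.case_samples, study.control_samples, "S1")
        assert back.genes == study.genes
        assert back.samples == study.samples
        np.testing.assert_array_equal(back.values, study.values)

    def test_duplicate_symbols_collapsed_by_mean(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\ntp53\t1.0\t2.0\nTP53\t3.0\t4.0\nKRAS\t5.0\t6.0\n")
        study = read_expression_matrix(path, ["s1"], ["s2"], "S1")
        assert study.genes == ["TP53", "KRAS"]
        np.testing.assert_allclose(study.values[0], [2.0, 3.0])

    def test_missing_sample_id_named_in_error(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\nA\t1\t2\n")
        with pytest.raises(ValueError, match="s9"):
            read_expression_matrix(path, ["s1", "s9"], ["s2"], "S1")

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\nA\t1\t2\nB\toops\t3\n")
        with pytest.raises(ValueError, match="'B'.*'s1'"):
            read_expression_matrix(path, ["s1"], ["s2"], "S1")

    def test_log2_transform(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("gene\ts1\ts2\nA\t3\t7\n")
        study = read_expression_matrix(path, ["s1"], ["s2"], "S1", log2_transform=True)
        np.testing.assert_allclose(study.values[0], [2.0, 3.0])

    def test_overlapping_groups_rejected_by_constructor(self):
        from codegnet import ExpressionStudy

        with pytest.raises(ValueError, match="both groups"):
            ExpressionStudy(
                study_id="X",
                genes=["A"],
                samples=["s1", "s2"],
                values=np.zeros((1, 2)),
                case_samples=["s1"],
                control_samples=["s1", "s2"],
            )


class TestGMT:
    def test_parse_two_terms(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("T1\tdesc\tA\tB\tC\nT2\tdesc\tD\tE\n")
        lib = read_gmt(path)
        assert len(lib) == 2
        assert lib.terms["T1"] == {"A", "B", "C"}
        assert lib.universe == {"A", "B", "C", "D", "E"}

    def test_duplicate_gene_uniqued(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("T1\tdesc\tA\ta\tB\n")
        assert read_gmt(path).terms["T1"] == {"A", "B"}

    def test_empty_file(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("")
        lib = read_gmt(path)
        assert len(lib) == 0 and lib.universe == frozenset()

    def test_short_line_errors_with_lineno(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("T1\tdesc\tA\nT2\tdesc\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)

    def test_blank_gene_fields_dropped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "lib.gmt"
        path.write_text("T1\tdesc\t\t\nT2\tdesc\tA\n")
        with caplog.at_level("WARNING"):
            lib = read_gmt(path)
        assert list(lib.terms) == ["T2"]
        assert "T1" in caplog.text

    def test_round_trip(self, tmp_path, toy_library):
        path = tmp_path / "lib.gmt"
        write_gmt(toy_library, path)
        assert read_gmt(path).terms == toy_library.terms


class TestPPI:
    def test_dedup_and_self_loop(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\nB\tA\nC\tC\n")
        net = read_ppi(path)
        assert net.edges == {("A", "B")}
        assert net.nodes == {"A", "B", "C"}  # C retained as isolated node

    def test_triangle(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\nB\tC\nC\tA\n")
        net = read_ppi(path)
        assert len(net.nodes) == 3 and len(net.edges) == 3

    def test_sif_dialect(self, tmp_path):
        path = tmp_path / "ppi.sif"
        path.write_text("A pp B\n")
        assert read_ppi(path).edges == {("A", "B")}

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\nA\tB\tpp\tX\n")
        with pytest.raises(ValueError, match=":2"):
            read_ppi(path)

    def test_round_trip(self, tmp_path):
        net = PPINetwork.build({"A", "B", "C", "D"}, [("A", "B"), ("B", "C")])
        path = tmp_path / "ppi.tsv"
        write_ppi(net, path)
        assert read_ppi(path) == net

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.sampled_from("abcdef"), st.sampled_from("abcdef")),
            max_size=20,
        )
    )
    def test_always_simple_and_undirected(self, edges):
        net = PPINetwork.build([], edges)
        for a, b in net.edges:
            assert a < b  # canonical order implies no duplicates or reversals
            assert a != b


class TestSignatureQC:
    def test_overlapping_sample_rejected(self):
        meta = StudyMetadata("S1", ["A", "B"], ["s1", "s2"], ["s2", "s3"])
        report = validate_signature_metadata(meta, {"A", "B"})
        assert report.status == "rejected"
        assert report.overlapping_samples == ["s2"]

    def test_invalid_symbols_counted(self):
        genes = [f"G{i}" for i in range(100)]
        valid = set(genes) - {"G1", "G2", "G3"}
        meta = StudyMetadata("S1", genes, ["s1"], ["s2"])
        report = validate_signature_metadata(meta, valid)
        assert report.status == "accepted"
        assert report.n_genes_retained == 97
        assert sorted(report.invalid_symbols) == ["G1", "G2", "G3"]

    def test_clean_study_accepted(self):
        study = make_study([[1.0, 2.0], [3.0, 4.0]], n_case=1)
        report = validate_signature_metadata(study, set(study.genes))
        assert report.status == "accepted"
        assert not report.invalid_symbols and not report.overlapping_samples

    def test_empty_valid_symbols_error(self):
        meta = StudyMetadata("S1", ["A"], ["s1"], ["s2"])
        with pytest.raises(ValueError):
            validate_signature_metadata(meta, set())


def test_gene_list_round_trip(tmp_path):
    path = tmp_path / "genes.txt"
    write_gene_list(["TP53", "KRAS"], path)
    assert read_gene_list(path) == ["TP53", "KRAS"]
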
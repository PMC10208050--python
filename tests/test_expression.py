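"""Expression preprocessing: I/O, filtering, quantile normalization, collapse, split."""

import numpy as np
import pandas as pd
import pytest

from cernet.expression import (
    ExpressionMatrix,
    collapse_probes,
    filter_unexpressed,
    log2_transform,
    quantile_normalize,
    read_expression_matrix,
    split_by_biotype,
)

from conftest import make_matrix


def write_fixture_files(tmp_path, matrix_text, group_text):
    mat_path = tmp_path / "expr.tsv"
    grp_path = tmp_path / "groups.tsv"
    mat_path.write_text(matrix_text)
    grp_path.write_text(group_text)
    return mat_path, grp_path


class TestReadExpressionMatrix:
    def test_round_trip_fixture(self, tmp_path):
        mat_path, grp_path = write_fixture_files(
            tmp_path,
            "id\tA\tB\tC\tD\np1\t1\t2\t3\t4\np2\t5\t6\t7\t8\np3\t9\t10\t11\t12\n",
            "sample\tgroup\nA\tday0\nB\tday0\nC\tday8\nD\tday8\n",
        )
        mat = read_expression_matrix(mat_path, grp_path)
        assert mat.values.shape == (3, 4)
        assert mat.group_samples("day0") == ["A", "B"]
        assert mat.group_samples("day8") == ["C", "D"]
        assert mat.scale == "linear" and mat.level == "probe"

    def test_unassigned_sample_is_named_in_error(self, tmp_path):
        mat_path, grp_path = write_fixture_files(
            tmp_path,
            "id\tA\tB\np1\t1\t2\n",
            "sample\tgroup\nA\tday0\n",
        )
        with pytest.raises(ValueError, match="B"):
            read_expression_matrix(mat_path, grp_path)

    def test_empty_file(self, tmp_path):
        mat_path, grp_path = write_fixture_files(tmp_path, "", "sample\tgroup\n")
        with pytest.raises(ValueError, match="no data rows"):
            read_expression_matrix(mat_path, grp_path)

    def test_non_numeric_cell(self, tmp_path):
        mat_path, grp_path = write_fixture_files(
            tmp_path,
            "id\tA\tB\np1\t1\toops\n",
            "sample\tgroup\nA\tday0\nB\tday8\n",
        )
        with pytest.raises(ValueError, match="non-numeric"):
            read_expression_matrix(mat_path, grp_path)


class TestFilterUnexpressed:
    def test_all_zero_row_removed(self):
        mat = make_matrix([[0, 0, 0, 0], [1, 2, 3, 4]], scale="linear", level="probe")
        out = filter_unexpressed(mat, min_value=0, min_fraction=1.0)
        assert list(out.values.index) == ["g1"]

    def test_minus_inf_threshold_is_identity(self):
        mat = make_matrix([[0, 0], [1, 2], [-5, -6]], scale="linear", level="probe")
        out = filter_unexpressed(mat, min_value=-np.inf, min_fraction=1.0)
        assert out.values.equals(mat.values)

    def test_hand_enumerated_keep_count(self):
        # 10 rows; exactly rows 0-3 exceed 5 in every sample
        rows = [[6 + i, 7 + i, 8 + i] for i in range(4)]
        rows += [[6, 5, 6]] * 3 + [[0, 0, 0]] * 3
        mat = make_matrix(rows, scale="linear", level="probe")
        out = filter_unexpressed(mat, min_value=5, min_fraction=1.0)
        assert out.values.shape[0] == 4

    def test_monotone_in_min_value(self):
        rng = np.random.default_rng(0)
        mat = make_matrix(rng.uniform(0, 10, size=(30, 6)), scale="linear", level="probe")
        kept_strict = set(filter_unexpressed(mat, min_value=5, min_fraction=0.5).values.index)
        kept_loose = set(filter_unexpressed(mat, min_value=3, min_fraction=0.5).values.index)
        assert kept_strict <= kept_loose

    def test_bad_fraction(self):
        mat = make_matrix([[1, 2]], scale="linear", level="probe")
        with pytest.raises(ValueError, match="min_fraction"):
            filter_unexpressed(mat, min_value=0, min_fraction=1.5)


class TestQuantileNormalize:
    def test_two_column_example(self):
        mat = make_matrix(np.array([[1, 4], [2, 5], [3, 6]]), scale="linear", level="probe")
        out = quantile_normalize(mat)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values.to_numpy(), expected)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        mat = make_matrix(rng.normal(size=(50, 6)), scale="linear", level="probe")
        once = quantile_normalize(mat)
        twice = quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-12)

    def test_columns_share_sorted_values(self):
        rng = np.random.default_rng(2)
        out = quantile_normalize(
            make_matrix(rng.normal(size=(50, 6)), scale="linear", level="probe")
        )
        arr = np.sort(out.values.to_numpy(), axis=0)
        for j in range(1, arr.shape[1]):
            np.testing.assert_allclose(arr[:, 0], arr[:, j], atol=1e-12)

    def test_ties_get_mean_of_spanned_targets(self):
        # column 0 has a tie at value 1 spanning the two smallest targets
        mat = make_matrix(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]),
                          scale="linear", level="probe")
        out = quantile_normalize(mat)
        col0 = out.values.iloc[:, 0].to_numpy()
        targets = np.sort(mat.values.to_numpy(), axis=0).mean(axis=1)
        assert col0[0] == col0[1] == pytest.approx((targets[0] + targets[1]) / 2)

    def test_single_column_warns_and_passes_through(self):
        mat = make_matrix([[1], [2]], samples=["A"], groups={"A": "day0"},
                          scale="linear", level="probe")
        with pytest.warns(UserWarning):
            out = quantile_normalize(mat)
        assert out.values.equals(mat.values)


class TestLog2Transform:
    def test_values(self):
        mat = make_matrix([[7, 0]], scale="linear", level="probe")
        out = log2_transform(mat, offset=1)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0]])
        assert out.scale == "log2"

    def test_double_log_guard(self):
        mat = make_matrix([[1, 2]], scale="log2")
        with pytest.raises(ValueError, match="log2"):
            log2_transform(mat)

    def test_zero_with_zero_offset(self):
        mat = make_matrix([[0, 1]], scale="linear", level="probe")
        with pytest.raises(ValueError, match="non-positive"):
            log2_transform(mat, offset=0)


class TestCollapseProbes:
    def make_annot(self, mapping):
        rows = [(p, g, "mRNA", "1q21", 1, 2) for p, g in mapping.items()]
        return pd.DataFrame(
            rows, columns=["probe_id", "gene_symbol", "biotype", "chromosome_band", "start", "end"]
        ).set_index("probe_id")

    def test_mean_of_two_probes(self):
        mat = make_matrix([[2, 4, 6], [4, 6, 8]], scale="log2", level="probe",
                          index=["p1", "p2"],
                          groups={"S0": "day0", "S1": "day0", "S2": "day8"})
        annot = self.make_annot({"p1": "G1", "p2": "G1"})
        out = collapse_probes(mat, annot)
        assert out.level == "gene"
        np.testing.assert_allclose(out.values.loc["G1"].to_numpy(), [3, 5, 7])

    def test_single_probe_pass_through(self):
        mat = make_matrix([[1.5, 2.5]], scale="log2", level="probe", index=["p1"])
        out = collapse_probes(mat, self.make_annot({"p1": "G1"}))
        np.testing.assert_allclose(out.values.loc["G1"].to_numpy(), [1.5, 2.5])

    def test_gene_count_on_fixture(self):
        # 100 probes over 40 genes: gene Gi owns probes p{i}_0 .. p{i}_k
        mapping = {}
        k = 0
        for i in range(40):
            n = 3 if i < 20 else 2  # 20*3 + 20*2 = 100
            for j in range(n):
                mapping[f"p{k}"] = f"G{i:02d}"
                k += 1
        assert len(mapping) == 100
        rng = np.random.default_rng(3)
        mat = make_matrix(rng.normal(size=(100, 4)), scale="log2", level="probe",
                          index=list(mapping))
        out = collapse_probes(mat, self.make_annot(mapping))
        assert out.values.shape[0] == 40

    def test_collapse_commutes_with_column_mean(self):
        rng = np.random.default_rng(4)
        mapping = {f"p{i}": f"G{i % 5}" for i in range(20)}
        mat = make_matrix(rng.normal(size=(20, 6)), scale="log2", level="probe",
                          index=list(mapping))
        collapsed = collapse_probes(mat, self.make_annot(mapping))
        via_genes = collapsed.values.mean(axis=1)
        via_probes = mat.values.mean(axis=1).groupby(pd.Series(mapping)).mean()
        np.testing.assert_allclose(via_genes.sort_index(), via_probes.sort_index(), atol=1e-12)

    def test_no_annotated_probe_errors(self):
        mat = make_matrix([[1, 2]], scale="log2", level="probe", index=["px"])
        with pytest.raises(ValueError, match="annotation"):
            collapse_probes(mat, self.make_annot({"other": "G"}))


class TestSplitByBiotype:
    def test_partition_counts(self, annot_13_genes):
        genes = list(annot_13_genes["gene_symbol"])
        mat = make_matrix(np.arange(26).reshape(13, 2), scale="log2", level="gene", index=genes)
        mrna, lnc = split_by_biotype(mat, annot_13_genes)
        assert mrna.values.shape[0] == 9
        assert lnc.values.shape[0] == 4
        assert mrna.values.shape[0] + lnc.values.shape[0] == mat.values.shape[0]

    def test_all_mrna_boundary(self, annot_13_genes):
        mrna_only = annot_13_genes[annot_13_genes["biotype"] == "mRNA"]
        mat = make_matrix(np.ones((9, 2)), scale="log2", level="gene",
                          index=list(mrna_only["gene_symbol"]))
        mrna, lnc = split_by_biotype(mat, mrna_only)
        assert lnc.values.shape[0] == 0

    def test_conflicting_biotypes_error(self):
        annot = pd.DataFrame(
            [("p1", "G1", "mRNA", "1q", 1, 2), ("p2", "G1", "lncRNA", "1q", 1, 2)],
            columns=["probe_id", "gene_symbol", "biotype", "chromosome_band", "start", "end"],
        ).set_index("probe_id")
        mat = make_matrix([[1, 2]], scale="log2", level="gene", index=["G1"])
        with pytest.raises(ValueError, match="G1"):
            split_by_biotype(mat, annot)


def test_matrix_invariants_enforced():
    with pytest.raises(ValueError, match="group"):
        ExpressionMatrix(values=pd.DataFrame([[1.0]], columns=["A"]), sample_groups={})
    with pytest.raises(ValueError, match="non-finite"):
        make_matrix([[np.nan, 1]])
    with pytest.raises(ValueError, match="duplicate"):
        make_matrix([[1, 2], [3, 4]], level="gene", index=["G1", "G1"])
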
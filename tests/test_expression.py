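"""Expression I/O, screening filters, stage summaries and qPCR utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrrnet.expression import (
    ExpressionMatrix,
    FormatError,
    QPCRRecord,
    ddct_fold_change,
    filter_expressed,
    read_expression_tsv,
    read_gmt,
    select_candidates,
    stage_means,
    validate_against_qpcr,
    zscore_profiles,
)
from conftest import toy_matrix


class TestExpressionMatrix:
    def test_rejects_duplicate_gene_ids(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["g1", "g1"], columns=["A_1", "A_2"])
        with pytest.raises(FormatError, match="duplicate gene"):
            ExpressionMatrix(df)

    def test_rejects_negative_values(self):
        with pytest.raises(FormatError, match="nonnegative"):
            toy_matrix({"g1": [1, -1, 0, 0]})

    def test_rejects_malformed_sample_id(self):
        df = pd.DataFrame([[1.0]], index=["g1"], columns=["sampleA"])
        with pytest.raises(FormatError, match="<stage>_<replicate>"):
            ExpressionMatrix(df)

    def test_stage_order_inferred_from_columns(self):
        m = toy_matrix({"g1": [1, 2, 3, 4]}, stages=("VS", "FI"))
        assert m.stage_order == ("VS", "FI")

    def test_tsv_round_trip(self, tmp_path):
        m = toy_matrix({"g1": [1.25, 2, 3, 4], "g2": [0, 0.5, 1, 7]})
        path = tmp_path / "expr.tsv"
        m.to_tsv(path)
        back = read_expression_tsv(path)
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)


class TestFilterExpressed:
    def test_hand_counted_stage_level_filter(self):
        # stage means: g1 all 1.9, g2 one stage 2.0, g3 all 0, g4 all 3, g5 one 2.1
        m = toy_matrix(
            {
                "g1": [1.9, 1.9, 1.9, 1.9],
                "g2": [2.0, 2.0, 1.0, 1.0],
                "g3": [0, 0, 0, 0],
                "g4": [3, 3, 3, 3],
                "g5": [1.0, 1.0, 2.1, 2.1],
            }
        )
        kept = filter_expressed(m, threshold=2.0)
        assert kept.gene_ids == ["g2", "g4", "g5"]

    def test_all_zero_gene_removed(self):
        m = toy_matrix({"g0": [0, 0, 0, 0], "g1": [5, 5, 5, 5]})
        assert filter_expressed(m).gene_ids == ["g1"]

    def test_single_hot_stage_retained(self):
        m = toy_matrix({"g": [0, 0, 5, 5], "pad": [9, 9, 9, 9]})
        assert "g" in filter_expressed(m, threshold=2.0).gene_ids

    def test_sample_level_flag_is_stricter_per_sample(self):
        # stage mean 2.0 passes stage-level; no single sample reaches 4
        m = toy_matrix({"g": [1.0, 3.0, 1.0, 3.0]})
        assert filter_expressed(m, 2.0, stage_level=True).gene_ids == ["g"]
        assert filter_expressed(m, 3.5, stage_level=False).gene_ids == []

    def test_idempotent(self, default_benchmark):
        _, _, matrix, *_ = default_benchmark
        once = filter_expressed(matrix)
        twice = filter_expressed(once)
        assert once.gene_ids == twice.gene_ids

    def test_empty_result_warns_not_raises(self):
        m = toy_matrix({"g": [0.1, 0.1, 0.1, 0.1]})
        with pytest.warns(UserWarning, match="no gene"):
            out = filter_expressed(m, threshold=2.0)
        assert out.gene_ids == []


class TestSelectCandidates:
    @staticmethod
    def deg(rows):
        return pd.DataFrame(rows, columns=["gene", "comparison", "log2fc", "fdr"])

    def test_boundary_rows_inclusive(self):
        table = self.deg([("g", "VS_vs_FI", 1.0, 0.05)])
        assert select_candidates(table) == {"g"}

    def test_sub_threshold_fold_change_rejected(self):
        table = self.deg([("g", "VS_vs_FI", 0.99, 0.01)])
        assert select_candidates(table) == set()

    def test_hand_evaluated_six_row_table(self):
        table = self.deg(
            [
                ("g1", "VS_vs_FI", 2.0, 0.01),
                ("g1", "FI_vs_FM", 0.2, 0.9),
                ("g2", "FI_vs_FM", -1.5, 0.04),
                ("g3", "VS_vs_FI", 0.5, 0.001),
                ("g3", "FI_vs_FM", 3.0, 0.2),
                ("g4", "VS_vs_FI", -0.1, 0.99),
            ]
        )
        assert select_candidates(table) == {"g1", "g2"}

    def test_extra_genes_always_included(self):
        table = self.deg([("g1", "VS_vs_FI", 2.0, 0.01)])
        assert select_candidates(table, extra={"curated"}) == {"g1", "curated"}

    @settings(max_examples=50, deadline=None)
    @given(
        fdr_a=st.floats(0.001, 0.5),
        fdr_b=st.floats(0.001, 0.5),
        lfc_a=st.floats(0.1, 3),
        lfc_b=st.floats(0.1, 3),
    )
    def test_monotone_in_both_thresholds(self, fdr_a, fdr_b, lfc_a, lfc_b):
        """Loosening either threshold never shrinks the candidate set."""
        table = self.deg(
            [(f"g{i}", "VS_vs_FI", lfc, fdr)
             for i, (lfc, fdr) in enumerate([(0.5, 0.01), (1.2, 0.2), (2.5, 0.04), (0.9, 0.4)])]
        )
        loose = select_candidates(table, max(fdr_a, fdr_b), min(lfc_a, lfc_b))
        tight = select_candidates(table, min(fdr_a, fdr_b), max(lfc_a, lfc_b))
        assert tight <= loose


class TestStageSummaries:
    def test_replicate_mean(self):
        m = toy_matrix({"g": [1, 2, 3, 10, 10, 10]}, stages=("A", "B"), reps=3)
        means = stage_means(m)
        assert means.loc["g", "A"] == 2.0
        assert means.loc["g", "B"] == 10.0

    def test_constant_gene_zscores_to_zero(self):
        profiles = pd.DataFrame({"A": [5.0], "B": [5.0], "C": [5.0]}, index=["g"])
        assert (zscore_profiles(profiles).loc["g"] == 0).all()

    def test_two_stage_zscore_population_sd(self):
        # stage means (1, 3): mean 2, population sd 1 -> z = (-1, +1)
        m = toy_matrix({"g": [1, 1, 3, 3]})
        z = zscore_profiles(stage_means(m))
        assert z.loc["g"].tolist() == [-1.0, 1.0]


class TestDdct:
    @staticmethod
    def record(ct_target, calibrator="VS_1"):
        ref = {s: 15.0 for s in ct_target}
        return QPCRRecord("gene", ct_target, ref, calibrator)

    def test_calibrator_fold_change_is_one(self):
        fc = ddct_fold_change(self.record({"VS_1": 20.0, "FI_1": 22.0}))
        assert fc["VS_1"] == 1.0

    def test_negative_ddct_doubles(self):
        fc = ddct_fold_change(self.record({"VS_1": 20.0, "FI_1": 19.0}))
        assert fc["FI_1"] == pytest.approx(2.0)

    def test_ddct_tenth(self):
        fc = ddct_fold_change(self.record({"VS_1": 20.0, "FI_1": 20.0 + 3.3219}))
        assert fc["FI_1"] == pytest.approx(0.1, abs=1e-3)

    def test_missing_calibrator_errors(self):
        with pytest.raises(ValueError, match="calibrator"):
            self.record({"FI_1": 20.0}, calibrator="VS_1")

    def test_missing_reference_errors(self):
        with pytest.raises(ValueError, match="reference Ct"):
            QPCRRecord("g", {"VS_1": 20.0}, {}, "VS_1")


class TestQpcrValidation:
    def test_affine_series_give_unit_correlation(self):
        m = toy_matrix({"g": [1, 1, 2, 2, 3, 3]}, stages=("A", "B", "C"), reps=2)
        fc = {"g": pd.Series({"A_1": 2.0, "B_1": 4.0, "C_1": 6.0})}
        assert validate_against_qpcr(fc, m)["g"] == pytest.approx(1.0)

    def test_inverted_series_give_minus_one(self):
        m = toy_matrix({"g": [1, 1, 2, 2, 3, 3]}, stages=("A", "B", "C"), reps=2)
        fc = {"g": pd.Series({"A_1": 3.0, "B_1": 2.0, "C_1": 1.0})}
        assert validate_against_qpcr(fc, m)["g"] == pytest.approx(-1.0)

    def test_zero_variance_reported_missing(self):
        m = toy_matrix({"g": [2, 2, 2, 2, 2, 2]}, stages=("A", "B", "C"), reps=2)
        fc = {"g": pd.Series({"A_1": 1.0, "B_1": 2.0, "C_1": 3.0})}
        assert np.isnan(validate_against_qpcr(fc, m)["g"])

    def test_fewer_than_three_stages_errors(self):
        m = toy_matrix({"g": [1, 1, 2, 2]})
        fc = {"g": pd.Series({"A_1": 1.0, "B_1": 2.0})}
        with pytest.raises(ValueError, match="3 stages"):
            validate_against_qpcr(fc, m)


class TestGmtReader:
    def test_reads_terms_and_universe(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("T1\tdesc one\tg1\tg2\nT2\t\tg2\tg3\n")
        annot = read_gmt(path)
        assert annot.terms["T1"] == frozenset({"g1", "g2"})
        assert annot.universe == frozenset({"g1", "g2", "g3"})

    def test_restriction_drops_empty_terms(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("T1\td\tg1\nT2\td\tg9\n")
        annot = read_gmt(path, universe={"g1"})
        assert "T2" not in annot.terms

    def test_malformed_line_reports_location(self, tmp_path):
        path = tmp_path / "a.gmt"
        path.write_text("T1\tdesc\tg1\nbroken line\n")
        with pytest.raises(FormatError, match="a.gmt:2"):
            read_gmt(path)
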
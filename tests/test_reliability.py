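import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connrel import (
    ICCMatrix,
    count_reproducible_links,
    icc_absolute_agreement,
    icc_batch,
    icc_summary,
    lausanne_roi_table,
    linkwise_icc,
    nodewise_metric_icc,
)
from conftest import cohort_stack, random_symmetric, stack_from_weights
from connrel.cohort import CohortParams
from oracles import anova_icc_oracle


class TestICCAbsoluteAgreement:
    def test_worked_two_rater_table(self):
        table = np.array([[1, 2], [2, 3], [3, 4]], dtype=float)
        assert icc_absolute_agreement(table) == pytest.approx(2 / 3, abs=1e-12)

    def test_identical_raters_give_perfect_agreement(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=6)
        table = np.column_stack([col, col, col])
        assert icc_absolute_agreement(table) == pytest.approx(1.0)

    def test_constant_table_is_undefined(self):
        assert np.isnan(icc_absolute_agreement(np.full((4, 2), 3.0)))

    def test_missing_cells_rejected(self):
        t = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="missing"):
            icc_absolute_agreement(t)

    def test_degenerate_dimensions_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones((1, 2)))
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones((3, 1)))

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            n = int(rng.integers(2, 11))
            k = int(rng.integers(2, 5))
            table = rng.normal(size=(n, k)) * rng.uniform(0.1, 10)
            assert icc_absolute_agreement(table) == pytest.approx(
                anova_icc_oracle(table), abs=1e-10
            )

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        for _ in range(5):
            n, k = 8, 3
            table = rng.normal(size=(n, k)) + rng.normal(size=(n, 1)) * 2
            df = pd.DataFrame(
                {
                    "target": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": table.ravel(),
                }
            )
            res = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                           ratings="score")
            sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
            icc2 = float(res.loc[sel, "ICC"].iloc[0])
            assert icc_absolute_agreement(table) == pytest.approx(icc2, abs=1e-6)

    def test_monte_carlo_recovers_variance_ratio(self):
        # subjects ~ N(0, 3), error ~ N(0, 1) -> ICC = 3/4
        rng = np.random.default_rng(2024)
        n, k = 500, 2
        subj = rng.normal(0, np.sqrt(3), size=(n, 1))
        table = subj + rng.normal(0, 1, size=(n, k))
        assert icc_absolute_agreement(table) == pytest.approx(0.75, abs=0.05)

    @given(st.integers(0, 2 ** 31 - 1), st.floats(-50, 50))
    @settings(max_examples=40, deadline=None)
    def test_invariant_under_row_permutation_and_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        table = rng.normal(size=(6, 3))
        base = icc_absolute_agreement(table)
        permuted = table[rng.permutation(6)]
        assert icc_absolute_agreement(permuted) == pytest.approx(base, abs=1e-9)
        assert icc_absolute_agreement(table + shift) == pytest.approx(base, abs=1e-7)


class TestLinkwiseICC:
    def _stack(self, n_subj=20, n_rois=46, duplicate=False, seed=5):
        rng = np.random.default_rng(seed)
        sessions = [("A1", "A"), ("A2", "A")]
        cells = {}
        for s in range(n_subj):
            w1 = random_symmetric(n_rois, rng)
            w2 = w1.copy() if duplicate else random_symmetric(n_rois, rng)
            np.fill_diagonal(w1, 0)
            np.fill_diagonal(w2, 0)
            cells[(f"s{s:02d}", "A1")] = w1
            cells[(f"s{s:02d}", "A2")] = w2
        from connrel import ROIRecord, ROITable

        recs = [ROIRecord(f"r{i}", "none", (float(i), 0, 0), 1.0, 1.0)
                for i in range(n_rois)]
        return stack_from_weights(ROITable(recs), cells, sessions)

    def test_duplicated_session_gives_unit_icc(self):
        stack = self._stack(n_subj=6, n_rois=8, duplicate=True)
        icc = linkwise_icc(stack, ("A1", "A2"))
        vals = icc.defined_values()
        assert len(vals) == 8 * 7 // 2
        assert np.allclose(vals, 1.0)

    def test_independent_sessions_give_null_icc(self):
        # 46 ROIs -> 1035 links, n=20 subjects
        stack = self._stack()
        vals = linkwise_icc(stack, ("A1", "A2")).defined_values()
        assert abs(float(vals.mean())) < 0.1

    def test_recovers_generator_truth(self):
        from connrel.cohort import recovery_params

        params = recovery_params(0.8, seed=301)
        stack, truth = cohort_stack(params)
        vals = linkwise_icc(stack, ("A1", "A2")).defined_values()
        assert float(vals.mean()) == pytest.approx(0.8, abs=0.1)

    def test_missing_session_rejected(self):
        stack = self._stack(n_subj=3, n_rois=5)
        with pytest.raises(ValueError, match="B9"):
            linkwise_icc(stack, ("A1", "B9"))


class TestNodewiseMetricICC:
    def test_duplicated_stack_gives_unit_icc(self):
        params = CohortParams(seed=33, n_subjects=5, n_rois=10, session_sd=0.0,
                              scanner_b_gain=1.0, scanner_b_extra_sd=0.0,
                              dropout_scale=1e9, count_noise=False,
                              regime="sparse_deterministic")
        stack, _ = cohort_stack(params)
        mt = nodewise_metric_icc(stack, "strength", ("A1", "A2"))
        assert mt.assessed
        assert np.allclose(mt.defined_values(), 1.0)

    def test_degree_not_assessed_on_dense_stack(self):
        params = CohortParams(seed=34, n_subjects=4, n_rois=10,
                              regime="dense_probabilistic")
        stack, _ = cohort_stack(params)
        mt = nodewise_metric_icc(stack, "degree", ("A1", "A2"))
        assert not mt.assessed
        assert len(mt.defined_values()) == 0

    def test_degree_assessed_on_sparse_stack(self):
        params = CohortParams(seed=35, n_subjects=4, n_rois=10,
                              regime="sparse_deterministic", mean_total_fibers=200)
        stack, _ = cohort_stack(params)
        assert nodewise_metric_icc(stack, "degree", ("A1", "A2")).assessed

    def test_unknown_metric_rejected(self):
        params = CohortParams(seed=36, n_subjects=3, n_rois=6)
        stack, _ = cohort_stack(params)
        with pytest.raises(ValueError, match="unknown metric"):
            nodewise_metric_icc(stack, "smallworldness", ("A1", "A2"))


class TestReproducibleLinkCount:
    def _icc_matrix(self, values):
        table = lausanne_roi_table()
        return ICCMatrix(table, ("A1", "A2"), "deterministic", values)

    def test_all_perfect_83_nodes(self):
        vals = np.ones((83, 83))
        icc = self._icc_matrix(vals)
        assert count_reproducible_links(icc) == 3403

    def test_all_undefined_counts_zero(self):
        icc = self._icc_matrix(np.full((83, 83), np.nan))
        assert count_reproducible_links(icc) == 0

    def test_strict_inequality_at_threshold(self):
        icc = self._icc_matrix(np.ones((83, 83)))
        assert count_reproducible_links(icc, threshold=1.0) == 0

    def test_summary_counts_are_consistent(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(-0.5, 1.0, size=(83, 83))
        vals = (vals + vals.T) / 2
        vals[0, :] = np.nan
        vals[:, 0] = np.nan
        icc = self._icc_matrix(vals)
        s = icc_summary(icc)
        assert s["n_defined"] + s["n_undefined"] == 3403
        assert s["n_above_threshold"] == count_reproducible_links(icc)
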
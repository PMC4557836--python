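import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connrel import (
    ConnectivityMatrix,
    FiberRecord,
    FiberSet,
    ROIRecord,
    ROITable,
    euclidean_distance,
    lausanne_roi_table,
    read_fibers,
    read_matrix,
    read_roi_table,
    read_stack,
    volume_features,
    write_fibers,
    write_matrix,
    write_roi_table,
    write_stack,
)
from conftest import cohort_stack, random_symmetric
from connrel.cohort import CohortParams


class TestROITable:
    def test_packaged_parcellation_has_83_nodes_and_42_regions(self):
        table = lausanne_roi_table()
        assert len(table) == 83
        assert len(set(table.labels)) == 42
        # 41 bilateral regions plus one unpaired brainstem node
        hemis = [r.hemisphere for r in table]
        assert hemis.count("left") == hemis.count("right") == 41
        assert hemis.count("none") == 1

    def test_single_row_file_roundtrip(self, tmp_path):
        p = tmp_path / "one.tsv"
        p.write_text(
            "label\themisphere\tcentroid_x\tcentroid_y\tcentroid_z\tvolume_mm3\tsurface_mm2\n"
            "insula\tleft\t-30\t5\t2\t5000\t1500\n"
        )
        table = read_roi_table(p)
        assert len(table) == 1
        assert table[0].key == "lh.insula"

    def test_nonpositive_volume_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "label\themisphere\tcentroid_x\tcentroid_y\tcentroid_z\tvolume_mm3\tsurface_mm2\n"
            "insula\tleft\t-30\t5\t2\t0\t1500\n"
        )
        with pytest.raises(ValueError, match="volume"):
            read_roi_table(p)

    def test_duplicate_label_hemisphere_rejected(self):
        rec = ROIRecord("x", "left", (0, 0, 0), 1.0, 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            ROITable([rec, rec])

    def test_roi_roundtrip_preserves_order_and_values(self, tmp_path, tiny_roi_table):
        p = tmp_path / "t.tsv"
        write_roi_table(tiny_roi_table, p)
        back = read_roi_table(p)
        assert back.keys == tiny_roi_table.keys
        assert np.allclose(back.volumes, tiny_roi_table.volumes)


class TestGeometryFeatures:
    @pytest.mark.parametrize(
        "ca, cb, expected",
        [((0, 0, 0), (3, 4, 0), 5.0), ((1, 1, 1), (1, 1, 1), 0.0),
         ((1, 1, 1), (2, 2, 2), math.sqrt(3))],
    )
    def test_euclidean_distance(self, ca, cb, expected):
        a = ROIRecord("a", "none", ca, 1.0, 1.0)
        b = ROIRecord("b", "none", cb, 1.0, 1.0)
        assert euclidean_distance(a, b) == pytest.approx(expected)
        assert euclidean_distance(b, a) == pytest.approx(expected)

    @given(st.lists(st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
                    min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_distance_triangle_inequality(self, centroids):
        recs = [ROIRecord(f"r{i}", "none", c, 1.0, 1.0) for i, c in enumerate(centroids)]
        dab = euclidean_distance(recs[0], recs[1])
        dbc = euclidean_distance(recs[1], recs[2])
        dac = euclidean_distance(recs[0], recs[2])
        assert dac <= dab + dbc + 1e-9

    @pytest.mark.parametrize(
        "va, vb, expected", [((10), 10, (20, 1.0)), (5, 20, (25, 4.0)), (20, 5, (25, 4.0))]
    )
    def test_volume_features(self, va, vb, expected):
        a = ROIRecord("a", "none", (0, 0, 0), va, 1.0)
        b = ROIRecord("b", "none", (0, 0, 0), vb, 1.0)
        assert volume_features(a, b) == pytest.approx(expected)


class TestMatrixIO:
    def test_symmetric_roundtrip_bit_identical(self, tmp_path, tiny_roi_table):
        rng = np.random.default_rng(0)
        w = random_symmetric(3, rng)
        np.fill_diagonal(w, 0.0)
        m = ConnectivityMatrix(tiny_roi_table, w)
        p = tmp_path / "m.tsv"
        write_matrix(m, p)
        back = read_matrix(p, tiny_roi_table)
        assert np.array_equal(back.weights, m.weights)
        # second trip through text is byte-identical
        p2 = tmp_path / "m2.tsv"
        write_matrix(back, p2)
        assert p.read_text() == p2.read_text()

    def test_symmetric_entries_read_back(self, tmp_path, tiny_roi_table):
        p = tmp_path / "m.tsv"
        p.write_text("0\t2\t0\n2\t0\t0\n0\t0\t0\n")
        m = read_matrix(p, tiny_roi_table)
        assert m.weights[0, 1] == 2.0

    def test_dimension_mismatch_rejected(self, tmp_path, tiny_roi_table):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\n1\t0\n")
        with pytest.raises(ValueError, match="expected 3x3"):
            read_matrix(p, tiny_roi_table)

    def test_negative_entries_rejected(self, tmp_path, tiny_roi_table):
        p = tmp_path / "m.tsv"
        p.write_text("0\t-1\t0\n-1\t0\t0\n0\t0\t0\n")
        with pytest.raises(ValueError, match="negative"):
            read_matrix(p, tiny_roi_table)

    def test_asymmetry_beyond_tolerance_rejected(self, tmp_path, tiny_roi_table):
        p = tmp_path / "m.tsv"
        p.write_text("0\t1\t0\n2\t0\t0\n0\t0\t0\n")
        with pytest.raises(ValueError, match="asymmetry"):
            read_matrix(p, tiny_roi_table)
        # generous tolerance symmetrizes by averaging instead
        m = read_matrix(p, tiny_roi_table, max_asymmetry=1.0)
        assert m.weights[0, 1] == pytest.approx(1.5)


class TestConnectivityMatrixInvariants:
    def test_rejects_negative_asymmetric_nonfinite(self, tiny_roi_table):
        with pytest.raises(ValueError):
            ConnectivityMatrix(tiny_roi_table, -np.ones((3, 3)))
        bad = np.zeros((3, 3))
        bad[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            ConnectivityMatrix(tiny_roi_table, bad)
        nanw = np.zeros((3, 3))
        nanw[0, 1] = nanw[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            ConnectivityMatrix(tiny_roi_table, nanw)

    def test_diagonal_forced_to_zero(self, tiny_roi_table):
        w = np.eye(3)
        m = ConnectivityMatrix(tiny_roi_table, w)
        assert np.all(np.diag(m.weights) == 0)


class TestFiberIO:
    def test_fiber_tsv_roundtrip(self, tmp_path):
        fs = FiberSet(
            "sub01", "A1", "A", "deterministic",
            [FiberRecord("lh.insula", "rh.insula", 42.0, 3.0),
             FiberRecord("lh.insula", "brainstem", 60.0, 1.0)],
        )
        p = tmp_path / "fibers.tsv"
        write_fibers([fs], p)
        back = read_fibers(p)
        assert len(back) == 1
        assert back[0].records == fs.records
        assert back[0].subject_id == "sub01"

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError, match="length"):
            FiberRecord("a", "b", 0.0, 1.0)
        with pytest.raises(ValueError, match="count"):
            FiberRecord("a", "b", 1.0, -1.0)


class TestStackIO:
    def test_stack_roundtrip(self, tmp_path):
        params = CohortParams(seed=5, n_subjects=3, n_rois=6)
        stack, _ = cohort_stack(params)
        manifest = write_stack(stack, tmp_path)
        back = read_stack(manifest)
        assert back.subjects == stack.subjects
        assert back.sessions == stack.sessions
        for subj in stack.subjects:
            for sess in stack.session_ids:
                assert np.allclose(
                    back.matrix(subj, sess).weights, stack.matrix(subj, sess).weights
                )

    def test_incomplete_stack_rejected(self, tiny_roi_table):
        from connrel import SessionStack

        m = ConnectivityMatrix(tiny_roi_table, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="missing"):
            SessionStack(["s1", "s2"], [("A1", "A")], {("s1", "A1"): m})
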
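"""Mask erosion, high-signal sinus thresholding, and feature assembly."""
import numpy as np
import pandas as pd
import pytest

from aslquant.errors import GridMismatchError, ValidationError
from aslquant.roi import (ROISet, erode_mask, extract_features, high_signal_roi,
                          roi_mean)


class TestErosion:
    def test_solid_cube_width2_gives_interior(self):
        mask = np.zeros((14, 14, 14), dtype=bool)
        mask[2:12, 2:12, 2:12] = True          # 10^3 cube
        out = erode_mask(mask, width=2)
        assert out.sum() == 9 ** 3
        # offsets {-1, 0}: the surviving cube keeps the high-index faces
        assert np.array_equal(np.argwhere(out).min(axis=0), [3, 3, 3])
        assert np.array_equal(np.argwhere(out).max(axis=0), [11, 11, 11])

    def test_single_voxel_erodes_to_empty_with_warning(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[4, 4, 4] = True
        with pytest.warns(UserWarning, match="emptied"):
            out = erode_mask(mask, width=2)
        assert not out.any()

    def test_anti_extensive(self, rng):
        mask = rng.random((16, 16, 8)) > 0.3
        mask[0, 0, 0] = True  # ensure non-empty
        e1 = erode_mask(mask, width=2)
        if e1.any():
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                e2 = erode_mask(e1, width=2)
            assert np.all(e2 <= e1)
        assert np.all(e1 <= mask)

    def test_matches_bruteforce_morphology(self, rng):
        mask = rng.random((10, 10, 6)) > 0.4
        mask[5, 5, 3] = True
        out = erode_mask(mask, width=2)
        offsets = (-1, 0)   # width-2 box, origin convention: offsets {-1, 0}
        expected = np.zeros_like(mask)
        for i in range(10):
            for j in range(10):
                for k in range(6):
                    vals = []
                    for di in offsets:
                        for dj in offsets:
                            for dk in offsets:
                                ii, jj, kk = i + di, j + dj, k + dk
                                inside = 0 <= ii < 10 and 0 <= jj < 10 and 0 <= kk < 6
                                vals.append(mask[ii, jj, kk] if inside else False)
                    expected[i, j, k] = all(vals)
        assert np.array_equal(out, expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            erode_mask(np.zeros((4, 4, 4), dtype=bool))


class TestHighSignalROI:
    def test_exactly_ten_percent_of_distinct_values(self, rng):
        shape = (10, 10, 10)
        cbf = rng.permutation(1000).astype(float).reshape(shape)
        mask = np.ones(shape, dtype=bool)
        roi, thr = high_signal_roi(cbf, mask, percentile=90.0)
        assert roi.sum() == 100
        assert set(cbf[roi]) == set(range(900, 1000))

    def test_constant_map_retains_all(self):
        cbf = np.full((5, 5, 5), 42.0)
        roi, thr = high_signal_roi(cbf, np.ones((5, 5, 5), bool))
        assert roi.all()
        assert thr == 42.0

    def test_matches_sort_and_cut_oracle(self, rng):
        cbf = rng.normal(size=(8, 8, 4)) * 50 + 100
        mask = rng.random((8, 8, 4)) > 0.5
        mask.flat[:20] = True
        roi, thr = high_signal_roi(cbf, mask)
        vals = np.sort(cbf[mask])
        thr_oracle = vals[np.floor(0.9 * (len(vals) - 1)).astype(int)] \
            + (0.9 * (len(vals) - 1) % 1) * np.diff(vals)[
                np.floor(0.9 * (len(vals) - 1)).astype(int)] \
            if len(vals) > 1 else vals[0]
        assert thr == pytest.approx(thr_oracle)
        assert np.array_equal(roi, mask & (cbf >= thr_oracle))

    def test_retained_fraction_bounds(self, rng):
        cbf = rng.permutation(321).astype(float).reshape((321, 1, 1))
        roi, _ = high_signal_roi(cbf, np.ones((321, 1, 1), bool))
        frac = roi.sum() / 321
        assert 0.10 <= frac <= 0.10 + 1 / 321 + 1e-12

    def test_too_few_voxels_names_subject(self):
        cbf = np.ones((3, 3, 1))
        mask = np.zeros((3, 3, 1), bool)
        mask[0, :, 0] = True
        with pytest.raises(ValidationError, match="sub-042"):
            high_signal_roi(cbf, mask, subject_id="sub-042")

    def test_nonfinite_voxels_excluded(self, rng):
        cbf = rng.normal(size=(4, 4, 2)) + 10
        cbf[0, 0, 0] = np.nan
        mask = np.ones((4, 4, 2), bool)
        roi, _ = high_signal_roi(cbf, mask)
        assert not roi[0, 0, 0]


class TestROIMean:
    def test_constant_map(self):
        m = np.full((4, 4, 2), 3.5)
        roi = np.zeros((4, 4, 2), bool)
        roi[1:3, 1:3, :] = True
        mean, n, cov = roi_mean(m, roi)
        assert mean == 3.5 and n == 8 and cov == 1.0

    def test_two_voxel_mean(self):
        m = np.zeros((3, 3, 1))
        roi = np.zeros((3, 3, 1), bool)
        m[0, 0, 0], m[1, 1, 0] = 10.0, 20.0
        roi[0, 0, 0] = roi[1, 1, 0] = True
        assert roi_mean(m, roi)[0] == 15.0

    def test_partial_coverage(self):
        m = np.full((4, 4, 1), 2.0)
        m[0, :, 0] = np.nan
        roi = np.ones((4, 4, 1), bool)
        mean, n, cov = roi_mean(m, roi)
        assert mean == 2.0 and n == 12 and cov == pytest.approx(0.75)

    def test_empty_intersection(self):
        mean, n, cov = roi_mean(np.full((2, 2, 1), np.nan), np.ones((2, 2, 1), bool))
        assert np.isnan(mean) and n == 0 and cov == 0.0

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            roi_mean(np.ones((2, 2, 2)), np.ones((3, 3, 3), bool))

    def test_high_signal_mean_dominates_full_mask_mean(self, rng):
        cbf = rng.normal(100, 30, size=(10, 10, 4))
        mask = rng.random((10, 10, 4)) > 0.6
        mask.flat[:30] = True
        roi, _ = high_signal_roi(cbf, mask)
        assert roi_mean(cbf, roi)[0] >= roi_mean(cbf, mask)[0]


class TestExtractFeatures:
    @staticmethod
    def _rois(shape=(6, 6, 2)):
        gm = np.zeros(shape, bool); gm[0:2, :, :] = True
        wm = np.zeros(shape, bool); wm[2:4, :, :] = True
        sinus = np.zeros(shape, bool); sinus[4:6, :, :] = True
        return ROISet(gm=gm, wm=wm, sinus_full=sinus, sinus_high=sinus)

    def test_constant_maps_recovered(self):
        rois = self._rois()
        shape = (6, 6, 2)
        maps = {"singleTI": {"cbf": np.full(shape, 50.0)},
                "multiTI": {"cbf": np.full(shape, 120.0),
                            "bat": np.full(shape, 0.8)}}
        row = extract_features(maps, rois, subject_id="s1")
        assert row["cbf_sti_gm"] == 50.0
        assert row["cbf_mti_sinus"] == 120.0
        assert row["bat_mti_wm"] == pytest.approx(0.8)
        assert row["cbf_sti_gm_coverage"] == 1.0

    def test_missing_sequence_keeps_row(self):
        rois = self._rois()
        row = extract_features({"singleTI": {"cbf": np.full((6, 6, 2), 50.0)}},
                               rois, subject_id="s2")
        assert row["cbf_sti_gm"] == 50.0
        assert np.isnan(row["cbf_mti_gm"]) and np.isnan(row["bat_mti_sinus"])

    def test_three_subject_assembly_matches_hand_expectation(self):
        rois = self._rois()
        shape = (6, 6, 2)
        rows = []
        for i, val in enumerate([40.0, 50.0, 60.0]):
            maps = {"singleTI": {"cbf": np.full(shape, val)},
                    "multiTI": {"cbf": np.full(shape, 2 * val),
                                "bat": np.full(shape, 1.0)}}
            rows.append(extract_features(maps, rois, subject_id=f"s{i}"))
        table = pd.DataFrame(rows)
        assert table["cbf_sti_gm"].tolist() == [40.0, 50.0, 60.0]
        assert table["cbf_mti_wm"].tolist() == [80.0, 100.0, 120.0]
        assert table["bat_mti_sinus"].tolist() == [1.0, 1.0, 1.0]

    def test_requires_sinus_high(self):
        rois = self._rois()
        rois.sinus_high = None
        with pytest.raises(ValidationError):
            extract_features({}, rois)
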
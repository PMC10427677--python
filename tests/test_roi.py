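import numpy as np
import pandas as pd
import pytest

from rsalight.roi import (
    build_roi,
    group_ancova,
    leave_one_region_out,
    roi_zscore,
    subject_roi_scores,
)
from rsalight.searchlight import SimilarityMap


def _map(data, subject="sub-001", condition="anxiety_minus_neutral", valid=None):
    data = np.asarray(data, dtype=float)
    if valid is None:
        valid = np.isfinite(data)
    return SimilarityMap(subject_id=subject, condition=condition, data=data,
                         valid=valid, radius_voxels=2, n_trials=60)


def _records(n_a=6, n_b=6, seed=0):
    rng = np.random.default_rng(seed)
    n = n_a + n_b
    return pd.DataFrame({
        "subject_id": [f"sub-{i:03d}" for i in range(n)],
        "group": ["AN"] * n_a + ["control"] * n_b,
        "age": rng.uniform(11, 19, n).round(1),
        "pds": rng.uniform(5, 20, n).round(1),
    })


class TestBuildRoi:
    def test_merge_is_voxelwise_union(self, rng):
        shape = (8, 8, 8)
        regions = {f"r{i}": rng.random(shape) for i in range(6)}
        thresholds = {"r0": 0.5, "r1": 0.5, "r2": 0.5, "r3": 0.5,
                      "r4": 0.001, "r5": 0.001}
        roiset = build_roi(regions, thresholds)
        union = np.zeros(shape, bool)
        for name, vol in regions.items():
            union |= vol >= thresholds[name]
        assert np.array_equal(roiset.merged_mask, union)

    def test_threshold_zero_keeps_support(self, rng):
        vol = rng.random((5, 5, 5))
        roiset = build_roi({"a": vol}, 0.0)
        assert np.array_equal(roiset.merged_mask, vol >= 0.0)

    def test_threshold_comparison_is_inclusive(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = 0.5
        roiset = build_roi({"a": vol}, 0.5)
        assert roiset.merged_mask[1, 1, 1]

    def test_disjoint_regions_counts_add(self):
        a = np.zeros((6, 6, 6)); a[:2] = 1.0
        b = np.zeros((6, 6, 6)); b[4:] = 1.0
        roiset = build_roi({"a": a, "b": b}, 0.5)
        assert roiset.merged_mask.sum() == (a >= 0.5).sum() + (b >= 0.5).sum()

    def test_empty_region_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            build_roi({"tiny": np.zeros((4, 4, 4))}, 0.5)


class TestRoiZscore:
    def test_zero_map_gives_zero(self):
        sm = _map(np.zeros((5, 5, 5)))
        assert roi_zscore(sm, np.ones((5, 5, 5), bool)).z_value == 0.0

    def test_constant_half_matches_atanh(self):
        sm = _map(np.full((5, 5, 5), 0.5))
        z = roi_zscore(sm, np.ones((5, 5, 5), bool)).z_value
        assert z == pytest.approx(0.5 * np.log(3), abs=1e-12)

    def test_symmetric_values_cancel(self):
        data = np.full((2, 1, 1), np.nan)
        data[0, 0, 0], data[1, 0, 0] = 0.5, -0.5
        sm = _map(data)
        assert roi_zscore(sm, np.ones((2, 1, 1), bool)).z_value == pytest.approx(0.0)

    def test_saturated_r_clipped_with_warning(self):
        data = np.full((3, 1, 1), 1.0)
        sm = _map(data)
        with pytest.warns(RuntimeWarning, match="clipped"):
            score = roi_zscore(sm, np.ones((3, 1, 1), bool))
        assert np.isfinite(score.z_value)

    def test_monotone_in_any_voxel(self, rng):
        data = rng.uniform(-0.5, 0.5, (4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        z0 = roi_zscore(_map(data.copy()), mask).z_value
        data[2, 2, 2] += 0.1
        assert roi_zscore(_map(data), mask).z_value > z0

    def test_invalid_voxels_excluded_and_counted(self):
        data = np.full((4, 1, 1), 0.3)
        valid = np.ones((4, 1, 1), bool)
        valid[0] = False
        score = roi_zscore(_map(data, valid=valid), np.ones((4, 1, 1), bool))
        assert score.n_voxels_used == 3


class TestGroupAncova:
    def test_denominator_df_is_n_minus_4(self):
        rec = _records(25, 22)
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=47), index=rec.subject_id)
        res = group_ancova(scores, rec)
        assert (res.df_num, res.df_den) == (1, 43)

    def test_no_covariates_f_equals_squared_t(self, rng):
        rec = _records(10, 10)
        x = rng.normal(size=20)
        scores = pd.Series(x, index=rec.subject_id)
        res = group_ancova(scores, rec, covariates=())
        from scipy import stats

        t, _ = stats.ttest_ind(x[:10], x[10:])
        assert res.f_stat == pytest.approx(t**2, rel=1e-10)

    def test_missing_covariates_dropped_listwise(self, rng):
        rec = _records(6, 6)
        rec.loc[3, "pds"] = np.nan
        scores = pd.Series(rng.normal(size=12), index=rec.subject_id)
        with pytest.warns(UserWarning, match="listwise"):
            res = group_ancova(scores, rec)
        assert res.n_used == 11
        assert res.df_den == 11 - 4

    def test_singular_design_rejected(self, rng):
        rec = _records(5, 5)
        rec["pds"] = rec["age"]  # perfectly collinear
        scores = pd.Series(rng.normal(size=10), index=rec.subject_id)
        with pytest.raises(ValueError, match="singular"):
            group_ancova(scores, rec)

    def test_tiny_group_rejected(self, rng):
        rec = _records(1, 8)
        scores = pd.Series(rng.normal(size=9), index=rec.subject_id)
        with pytest.raises(ValueError, match="two groups"):
            group_ancova(scores, rec)


class TestLeaveOneRegionOut:
    @staticmethod
    def _setup(rng, effect_region="A"):
        shape = (8, 8, 8)
        regions = {
            "A": np.zeros(shape), "B": np.zeros(shape), "C": np.zeros(shape),
        }
        regions["A"][:2, :2, :2] = 1.0
        regions["B"][5:, :2, :2] = 1.0
        regions["C"][:2, 5:, :2] = 1.0
        rec = _records(8, 8, seed=1)
        maps = {}
        for i, sid in enumerate(rec.subject_id):
            data = rng.normal(0, 0.02, shape)
            if rec.group[i] == "AN":
                data[regions[effect_region] > 0] += 0.4
            maps[sid] = _map(data, subject=sid)
        return regions, rec, maps

    def test_three_regions_give_four_results(self, rng):
        regions, rec, maps = self._setup(rng)
        results = leave_one_region_out(regions, 0.5, maps, rec)
        assert len(results) == 4
        assert results[0][0] is None
        assert {omit for omit, _ in results[1:]} == {"A", "B", "C"}

    def test_omitting_effect_region_minimizes_group_f(self, rng):
        regions, rec, maps = self._setup(rng, effect_region="A")
        results = leave_one_region_out(regions, 0.5, maps, rec)
        fs = {omit: res.f_stat for omit, res in results if omit is not None}
        assert min(fs, key=fs.get) == "A"

    def test_region_without_valid_voxels_equals_full_mask(self, rng):
        regions, rec, maps = self._setup(rng)
        for sm in maps.values():
            sm.valid[regions["C"] > 0] = False
            sm.data[regions["C"] > 0] = np.nan
        results = dict(leave_one_region_out(regions, 0.5, maps, rec))
        assert results["C"].f_stat == pytest.approx(results[None].f_stat, rel=1e-12)

    def test_fewer_than_two_regions_rejected(self, rng):
        _, rec, maps = self._setup(rng)
        with pytest.raises(ValueError, match="at least 2"):
            leave_one_region_out({"A": np.ones((8, 8, 8))}, 0.5, maps, rec)


def test_ancova_null_pvalues_uniform():
    """Type-I error calibration: p ~ U(0,1) under a pure-noise null."""
    from scipy import stats

    rng = np.random.default_rng(99)
    rec = _records(12, 12, seed=2)
    ps = []
    for _ in range(400):
        scores = pd.Series(rng.normal(size=24), index=rec.subject_id)
        ps.append(group_ancova(scores, rec).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
    assert np.mean(np.array(ps) < 0.05) == pytest.approx(0.05, abs=0.03)
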
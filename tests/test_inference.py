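import numpy as np
import pytest

from rsalight.inference import (
    PermutationResult,
    TFCEParams,
    cluster_table,
    permute_correlation,
    permute_one_sample,
    permute_two_sample,
    tfce,
)


def naive_tfce(stat, E, H, dh, connectivity=26):
    """Independent re-implementation: per-threshold flood-fill components."""
    stat = np.asarray(stat, dtype=float)
    pos = np.where(stat > 0, stat, 0.0)
    out = np.zeros_like(pos)
    if pos.max() <= 0:
        return out
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [
            (a, b, c)
            for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if (a, b, c) != (0, 0, 0)
            and (connectivity == 26 or abs(a) + abs(b) + abs(c) <= 2)
        ]
    h = dh
    while h <= pos.max() + 1e-12:
        supra = pos >= h
        seen = np.zeros_like(supra)
        for start in np.argwhere(supra):
            start = tuple(start)
            if seen[start]:
                continue
            comp, stack = [], [start]
            seen[start] = True
            while stack:
                p = stack.pop()
                comp.append(p)
                for d in neigh:
                    q = tuple(np.add(p, d))
                    if all(0 <= q[i] < supra.shape[i] for i in range(3)):
                        if supra[q] and not seen[q]:
                            seen[q] = True
                            stack.append(q)
            contrib = len(comp) ** E * h**H * dh
            for p in comp:
                out[p] += contrib
        h += dh
    return out


class TestTfce:
    def test_isolated_voxel_integrates_height_squared(self):
        stat = np.zeros((7, 7, 7))
        stat[3, 3, 3] = 1.0
        out = tfce(stat, TFCEParams(E=0.5, H=2.0, dh=0.01))
        assert out[3, 3, 3] == pytest.approx(1 / 3, rel=0.02)
        assert np.all(out[stat == 0] == 0)

    def test_all_zero_map(self):
        assert np.all(tfce(np.zeros((5, 5, 5))) == 0)

    def test_translated_blobs_get_identical_values(self, rng):
        stat = np.zeros((12, 12, 12))
        blob = rng.random((2, 2, 2)) + 0.5
        stat[1:3, 1:3, 1:3] = blob
        stat[8:10, 8:10, 8:10] = blob
        out = tfce(stat, TFCEParams(dh=0.05))
        assert np.allclose(out[1:3, 1:3, 1:3], out[8:10, 8:10, 8:10])

    def test_monotone_under_scaling(self, rng):
        stat = rng.random((8, 8, 8))
        params = TFCEParams(dh=0.02)
        assert np.all(tfce(2.0 * stat, params) >= tfce(stat, params) - 1e-12)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_naive_flood_fill(self, rng, connectivity):
        stat = rng.normal(0.2, 0.5, (8, 8, 8))
        dh = 0.1
        mine = tfce(stat, TFCEParams(dh=dh, connectivity=connectivity))
        oracle = naive_tfce(stat, 0.5, 2.0, dh, connectivity)
        assert np.allclose(mine, oracle, atol=1e-10)

    def test_nonfinite_rejected(self):
        stat = np.zeros((4, 4, 4))
        stat[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            tfce(stat)


class TestPermutationDesigns:
    def test_all_zero_maps_nothing_significant(self):
        maps = np.zeros((8, 6, 6, 6))
        res = permute_one_sample(maps, n_perm=200, seed=0)
        assert np.all(res.fwe_p_map == 1.0)

    def test_p_floor_is_one_over_nperm_plus_one(self, rng):
        maps = rng.normal(1.0, 0.1, (10, 6, 6, 6))  # strong constant signal
        res = permute_one_sample(maps, n_perm=500, seed=0)
        assert res.fwe_p_map.min() >= 1 / (res.n_permutations + 1) - 1e-12

    def test_exhaustive_sign_flips_small_n(self, rng):
        maps = rng.normal(size=(6, 5, 5, 5))
        res = permute_one_sample(maps, n_perm=200, seed=0)
        assert res.exhaustive
        assert res.n_permutations == 64

    def test_group_symmetric_data_never_significant(self, rng):
        half = rng.normal(size=(6, 5, 5, 5))
        maps = np.concatenate([half, half])  # identical groups
        labels = np.array([True] * 6 + [False] * 6)
        res = permute_two_sample(maps, labels, n_perm=200, seed=1)
        assert np.allclose(res.stat_map, 0.0, atol=1e-10)
        # only numeric jitter competes with the null; nothing approaches significance
        assert res.fwe_p_map.min() > 0.2

    def test_injected_group_difference_detected(self, rng):
        maps = rng.normal(0, 0.1, (20, 8, 8, 8))
        maps[:10, 2:5, 2:5, 2:5] += 1.0
        labels = np.array([True] * 10 + [False] * 10)
        res = permute_two_sample(maps, labels, n_perm=300, seed=2)
        region = np.zeros((8, 8, 8), bool)
        region[2:5, 2:5, 2:5] = True
        assert (res.fwe_p_map[region] < 0.05).mean() > 0.8
        assert (res.fwe_p_map[~region] < 0.05).mean() < 0.05

    def test_correlation_recovers_coupled_region(self, rng):
        n = 30
        x = rng.normal(size=n)
        maps = rng.normal(0, 0.1, (n, 8, 8, 8))
        maps[:, 5:8, 5:8, 5:8] += 0.5 * x[:, None, None, None]
        res = permute_correlation(maps, x, n_perm=300, seed=3)
        region = np.zeros((8, 8, 8), bool)
        region[5:8, 5:8, 5:8] = True
        assert (res.fwe_p_map[region] < 0.05).mean() > 0.8

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            permute_correlation(rng.normal(size=(8, 4, 4, 4)), np.ones(8), n_perm=100)

    def test_duplicated_nuisance_collinear(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="collinear"):
            permute_correlation(
                rng.normal(size=(10, 4, 4, 4)), x, nuisance=x, n_perm=100
            )

    def test_bitwise_reproducible_given_seed(self, rng):
        maps = rng.normal(size=(12, 5, 5, 5))
        labels = np.array([True] * 6 + [False] * 6)
        cov = rng.normal(size=(12, 2))
        a = permute_two_sample(maps, labels, cov, n_perm=150, seed=42)
        b = permute_two_sample(maps, labels, cov, n_perm=150, seed=42)
        assert np.array_equal(a.max_null, b.max_null)
        assert np.array_equal(a.fwe_p_map, b.fwe_p_map)

    def test_one_sample_direction_flips_sign(self, rng):
        maps = rng.normal(-0.5, 0.2, (10, 5, 5, 5))
        res = permute_one_sample(maps, n_perm=200, seed=0, direction="less")
        assert res.stat_map.max() > 0  # negated maps give positive t


class TestClusterTable:
    @staticmethod
    def _result(stat, fwe):
        return PermutationResult(
            stat_map=stat, tfce_map=np.abs(stat), fwe_p_map=fwe,
            max_null=np.ones(10), n_permutations=10, seed=0, design="test",
        )

    def test_no_significant_voxels_empty_table(self, rng):
        stat = rng.random((6, 6, 6))
        tab = cluster_table(self._result(stat, np.ones((6, 6, 6))), 0.05)
        assert len(tab) == 0

    def test_cubic_blob_size_and_peak(self):
        stat = np.zeros((9, 9, 9))
        stat[3:6, 3:6, 3:6] = 1.0
        stat[4, 4, 4] = 5.0
        fwe = np.ones((9, 9, 9))
        fwe[3:6, 3:6, 3:6] = 0.01
        tab = cluster_table(self._result(stat, fwe), 0.05)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.size_voxels == 27
        assert (row.x, row.y, row.z) == (4, 4, 4)
        assert row.t_max == 5.0

    def test_rows_sorted_by_peak_statistic(self):
        stat = np.zeros((10, 10, 10))
        stat[1, 1, 1] = 2.0
        stat[7, 7, 7] = 9.0
        fwe = np.ones((10, 10, 10))
        fwe[1, 1, 1] = fwe[7, 7, 7] = 0.01
        tab = cluster_table(self._result(stat, fwe), 0.05)
        assert list(tab.t_max) == [9.0, 2.0]
        assert list(tab.cluster) == [1, 2]
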
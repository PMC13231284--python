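import itertools

import numpy as np
import pandas as pd
import pytest

from qseg.errors import (
    ConfigurationError,
    MappingError,
    ShapeError,
    UndefinedMetricError,
    UndefinedTestError,
)
from qseg.evaluation import (
    compute_metric_records,
    dice,
    group_metrics,
    hd99,
    merge_labels,
    significance_marker,
    wilcoxon_one_sided,
)


class TestMergeLabels:
    def test_identity(self):
        vol = np.array([[0, 1], [2, 1]])
        out = merge_labels(vol, {0: 0, 1: 1, 2: 2})
        np.testing.assert_array_equal(out, vol)

    def test_merge_counts_conserved(self):
        vol = np.zeros(20, dtype=int)
        vol[:5] = 8
        vol[5:8] = 7
        out = merge_labels(vol, {0: 0, 7: 7, 8: 7})
        assert (out == 7).sum() == 8
        assert (out == 8).sum() == 0
        assert out.size == vol.size

    def test_idempotent(self):
        vol = np.array([0, 7, 8, 8])
        m = {0: 0, 7: 7, 8: 7}
        once = merge_labels(vol, m)
        np.testing.assert_array_equal(merge_labels(once, m), once)

    def test_uncovered_label_named(self):
        with pytest.raises(MappingError, match="3"):
            merge_labels(np.array([0, 3]), {0: 0})


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0

    def test_hand_counts(self):
        # |A| = 4, |B| = 6, |A ∩ B| = 3 -> 2*3/10 = 0.6
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[1:7] = True
        assert dice(a, b) == pytest.approx(0.6)

    def test_both_empty_is_one(self):
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    def test_symmetry_and_oracle_random_masks(self, rng):
        for _ in range(100):
            a = rng.random((16, 16, 16)) < 0.3
            b = rng.random((16, 16, 16)) < 0.3
            expected = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
            assert dice(a, b) == pytest.approx(expected, rel=1e-12)
            assert dice(a, b) == dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def brute_force_hd99(a, b, spacing):
    """Oracle: explicit boundary extraction and all-pairs distances."""
    def boundary(m):
        pts = []
        for p in np.argwhere(m):
            for axis in range(m.ndim):
                for d in (-1, 1):
                    q = p.copy()
                    q[axis] += d
                    if np.any(q < 0) or np.any(q >= np.array(m.shape)) or not m[tuple(q)]:
                        pts.append(p)
                        break
                else:
                    continue
                break
        return np.array(pts, dtype=float)

    pa = boundary(a) * spacing
    pb = boundary(b) * spacing
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(p - q) for q in pa) for p in pb]
    return np.percentile(d_ab + d_ba, 99)


class TestHD99:
    def test_identical_masks_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert hd99(m, m) == 0.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd99(a, b) == pytest.approx(3.0)

    def test_percentile_convention(self):
        # sort-and-interpolate oracle for the linear convention:
        # rank = 0.99 * (n - 1) on the sorted pooled multiset
        def manual(pooled):
            srt = np.sort(pooled)
            rank = 0.99 * (len(pooled) - 1)
            lo, hi = int(np.floor(rank)), int(np.ceil(rank))
            return srt[lo] + (rank - lo) * (srt[hi] - srt[lo])

        # 100 pooled distances, 99 zeros + one 10: the interpolation window
        # straddles the outlier -> value strictly between 0 and 10
        pooled = np.array([0.0] * 99 + [10.0])
        expected = np.percentile(pooled, 99)
        assert expected == pytest.approx(manual(pooled))
        assert 0.0 < expected < 10.0
        # 200 pooled distances, 199 zeros + one 10: the 99th-percentile rank
        # (197.01) falls among the zeros -> exactly 0 under this convention
        pooled = np.array([0.0] * 199 + [10.0])
        assert np.percentile(pooled, 99) == pytest.approx(manual(pooled)) == 0.0

    def test_empty_mask_undefined(self):
        m = np.ones((3, 3, 3), bool)
        with pytest.raises(UndefinedMetricError):
            hd99(m, np.zeros((3, 3, 3), bool))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            a = np.zeros((16, 16, 16), bool)
            b = np.zeros((16, 16, 16), bool)
            ca, cb = rng.integers(4, 12, 3), rng.integers(4, 12, 3)
            ra, rb = rng.integers(2, 4), rng.integers(2, 4)
            grid = np.indices((16, 16, 16)).transpose(1, 2, 3, 0)
            a[np.linalg.norm(grid - ca, axis=-1) < ra] = True
            b[np.linalg.norm(grid - cb, axis=-1) < rb] = True
            if not (a.any() and b.any()):
                continue
            expected = brute_force_hd99(a, b, 1.0)
            assert hd99(a, b) == pytest.approx(expected, abs=1e-9)

    def test_spacing_scales_linearly(self, rng):
        a = rng.random((10, 10, 10)) < 0.2
        b = rng.random((10, 10, 10)) < 0.2
        assert hd99(a, b, 2.5) == pytest.approx(2.5 * hd99(a, b, 1.0), rel=1e-9)

    def test_symmetry(self, rng):
        a = rng.random((10, 10, 10)) < 0.2
        b = rng.random((10, 10, 10)) < 0.2
        assert hd99(a, b) == pytest.approx(hd99(b, a), rel=1e-12)


def enumeration_p_value(diffs, alternative="greater"):
    """Oracle: enumerate all 2^n sign assignments of the observed magnitudes."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([1, -1], repeat=n):
        stats.append(ranks[np.array(signs) > 0].sum())
    stats = np.array(stats)
    if alternative == "greater":
        return (stats >= w_obs - 1e-12).mean()
    return (stats <= w_obs + 1e-12).mean()


class TestWilcoxonOneSided:
    def test_all_positive_n6(self):
        # exact: only the all-positive assignment reaches W+ = 21 -> 1/64
        p = wilcoxon_one_sided(np.arange(1, 7, dtype=float))
        assert p == pytest.approx(1 / 64)

    def test_equal_magnitude_pair(self):
        # enumeration oracle over (+1, -1): W+ values {0, 1.5, 1.5, 3};
        # P(W+ >= 1.5) = 3/4
        diffs = np.array([1.0, -1.0])
        assert wilcoxon_one_sided(diffs) == pytest.approx(
            enumeration_p_value(diffs))
        assert wilcoxon_one_sided(diffs) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_n_le_10(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        diffs = np.round(rng.standard_normal(n), 1)
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            return
        for alt in ("greater", "less"):
            assert wilcoxon_one_sided(diffs, alt) == pytest.approx(
                enumeration_p_value(diffs, alt), abs=1e-12)

    def test_zero_differences_dropped(self):
        p1 = wilcoxon_one_sided(np.array([0.0, 1.0, 2.0, 0.0, 3.0]))
        p2 = wilcoxon_one_sided(np.array([1.0, 2.0, 3.0]))
        assert p1 == p2

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_one_sided(np.zeros(5))

    def test_large_n_normal_approx_close_to_exact_tail(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0.3, 1.0, 40)
        p = wilcoxon_one_sided(diffs)
        from scipy import stats as ss
        ref = ss.wilcoxon(diffs, alternative="greater",
                          correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, abs=5e-3)

    def test_less_alternative_mirrors_greater(self):
        diffs = np.array([1.0, 2.0, -0.5, 3.0])
        pg = wilcoxon_one_sided(diffs, "greater")
        pl = wilcoxon_one_sided(-diffs, "less")
        assert pg == pytest.approx(pl)


class TestSignificanceMarker:
    @pytest.mark.parametrize("p,mark", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.2, "n.s."),
        (0.001, "**"), (0.01, "*"), (0.05, "n.s."),
    ])
    def test_thresholds(self, p, mark):
        assert significance_marker(p) == mark


class TestGroupMetrics:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["participant", "region", "metric",
                                           "value", "undefined"])

    def test_single_region_group(self):
        df = self._records([("p1", 1, "DSC", 0.9, False)])
        out = group_metrics(df, {1: "wm"})
        assert out["value"].iloc[0] == 0.9

    def test_mean_over_regions(self):
        df = self._records([
            ("p1", 1, "DSC", 0.9, False),
            ("p1", 2, "DSC", 0.8, False),
            ("p1", 3, "DSC", 0.7, False),
        ])
        out = group_metrics(df, {1: "g", 2: "g", 3: "g"})
        assert out["value"].iloc[0] == pytest.approx(0.8)

    def test_undefined_excluded_with_count(self):
        df = self._records([
            ("p1", 1, "HD99", 2.0, False),
            ("p1", 2, "HD99", np.nan, True),
            ("p1", 3, "HD99", 4.0, False),
        ])
        out = group_metrics(df, {1: "csf", 2: "csf", 3: "csf"})
        assert out["value"].iloc[0] == pytest.approx(3.0)
        assert out["n_excluded"].iloc[0] == 1

    def test_uncovered_region(self):
        df = self._records([("p1", 9, "DSC", 0.5, False)])
        with pytest.raises(MappingError):
            group_metrics(df, {1: "wm"})

    def test_empty_group_rejected(self):
        df = self._records([("p1", 1, "DSC", 0.5, False)])
        with pytest.raises(ConfigurationError):
            group_metrics(df, {1: "wm", 2: "ghost-group"})


class TestComputeMetricRecords:
    def test_records_shape_and_flags(self):
        ref = np.zeros((6, 6, 6), int)
        ref[2:4, 2:4, 2:4] = 1
        pred = ref.copy()
        pred[2, 2, 2] = 0
        df = compute_metric_records(pred, ref, [1, 2], "p0")
        assert len(df) == 4  # two regions x two metrics
        row = df.query("region == 1 and metric == 'DSC'").iloc[0]
        assert 0.8 < row.value < 1.0
        hd_row = df.query("region == 2 and metric == 'HD99'").iloc[0]
        assert hd_row.undefined and np.isnan(hd_row.value)
        dsc2 = df.query("region == 2 and metric == 'DSC'").iloc[0]
        assert dsc2.value == 1.0 and dsc2.undefined  # both empty, flagged
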
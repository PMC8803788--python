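"""VOI statistics, lesion segmentation, and agreement statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from petdle import evalsuite
from petdle.evalsuite import (VOI, AllDifferencesZero, UndefinedKappa,
                              aggregate_reader_tables, bland_altman,
                              find_organ_vois, percent_difference,
                              quadratic_weighted_kappa, scatter_slope,
                              segment_lesion, transfer_rois,
                              validate_rank_vector, voi_stats,
                              wilcoxon_signed_rank)


class TestVoiStats:
    def test_constant_volume_zero_noise(self):
        vol = np.full((20, 20, 20), 2.5)
        vois = [VOI((5, 5, 5), "liver"), VOI((14, 14, 14), "liver")]
        m = voi_stats(vol, vois)
        assert np.allclose(m.voi_sds, 0.0)
        assert m.background_variability == 0.0
        assert m.organ_suv_mean == pytest.approx(2.5)

    def test_consecutive_integer_block_oracle(self):
        # values 1..343 in one VOI: mean 172, population SD of 1..N
        vol = np.zeros((9, 9, 9))
        vol[1:8, 1:8, 1:8] = np.arange(1, 344).reshape(7, 7, 7)
        m = voi_stats(vol, [VOI((4, 4, 4), "liver")])
        n = 343
        assert m.voi_means[0] == pytest.approx(172.0)
        assert m.voi_sds[0] == pytest.approx(np.sqrt((n * n - 1) / 12.0))

    def test_affine_equivariance(self, rng):
        vol = rng.random((16, 16, 16))
        vois = [VOI((5, 5, 5), "liver"), VOI((10, 10, 10), "liver")]
        base = voi_stats(vol, vois)
        shifted = voi_stats(vol + 3.0, vois)
        scaled = voi_stats(2.0 * vol, vois)
        assert np.allclose(shifted.voi_means, base.voi_means + 3.0)
        assert np.allclose(shifted.voi_sds, base.voi_sds)
        assert np.allclose(scaled.voi_sds, 2.0 * base.voi_sds)

    def test_out_of_bounds_voi_named(self):
        with pytest.raises(ValueError, match=r"\(2, 8, 8\)"):
            voi_stats(np.zeros((16, 16, 16)), [VOI((2, 8, 8), "liver")])

    def test_find_organ_vois_inside_and_disjoint(self):
        mask = np.zeros((30, 30, 14), bool)
        mask[2:28, 2:28, 2:12] = True
        vois = find_organ_vois(mask, "liver", n=5)
        assert len(vois) == 5
        for a, b in itertools.combinations(vois, 2):
            assert np.max(np.abs(np.subtract(a.center, b.center))) >= 7
        for v in vois:
            assert mask[v.slices()].all()

    def test_find_organ_vois_too_small(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:6, 2:6, 2:6] = True
        with pytest.raises(ValueError):
            find_organ_vois(mask, "lung", n=1)


class TestSegmentLesion:
    def test_threshold_rule_and_boundary_inclusion(self):
        vol = np.zeros((9, 9, 9))
        vol[1:8, 1:8, 1:8] = 0.0
        vol[4, 4, 4] = 10.0
        vol[4, 4, 5] = 0.42 * 10.0  # exactly at T = min + 0.42 (max - min)
        vol[4, 4, 3] = 4.19
        roi = segment_lesion(vol, (4, 4, 4))
        assert roi.threshold == pytest.approx(4.2)
        assert roi.mask[3, 3, 3]          # the arg-max voxel
        assert roi.mask[3, 3, 4]          # boundary value included (>= rule)
        assert not roi.mask[3, 3, 2]
        assert roi.suv_max == 10.0

    def test_constant_box_degenerates_to_full_mask(self):
        vol = np.full((9, 9, 9), 5.0)
        roi = segment_lesion(vol, (4, 4, 4))
        assert roi.mask.all()
        assert roi.suv_max == 5.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_exhaustive_scan(self, seed):
        vol = np.random.default_rng(seed).random((9, 9, 9)) * 10
        roi = segment_lesion(vol, (4, 4, 4))
        box = vol[1:8, 1:8, 1:8]
        t = box.min() + 0.42 * (box.max() - box.min())
        brute = np.zeros((7, 7, 7), bool)
        for i in range(7):
            for j in range(7):
                for k in range(7):
                    brute[i, j, k] = box[i, j, k] >= t
        assert np.array_equal(roi.mask, brute)
        assert roi.mask[np.unravel_index(box.argmax(), box.shape)]


class TestTransferRois:
    def test_identical_series_identical_metrics(self, rng):
        vol = rng.random((20, 20, 20)) + 1.0
        vois = [VOI((6, 6, 6), "liver"), VOI((13, 13, 13), "lung")]
        a = transfer_rois(vol, vol, vois, [(10, 10, 10)], "a")
        assert a[0].organ_suv_mean == voi_stats(vol, vois[:1]).organ_suv_mean

    def test_constant_shift_moves_means_exactly(self, rng):
        vol = rng.random((20, 20, 20)) + 1.0
        vois = [VOI((6, 6, 6), "liver")]
        liver_a, _, _ = transfer_rois(vol, vol, vois, [], "a")
        liver_b, _, _ = transfer_rois(vol, vol + 1.0, vois, [], "b")
        assert liver_b.organ_suv_mean == pytest.approx(
            liver_a.organ_suv_mean + 1.0)

    def test_lesion_masks_adapt_per_series(self):
        # a different noise realisation shifts the adaptive threshold, so
        # the mask differs between series while the bbox stays fixed
        base = np.zeros((20, 20, 20))
        base[10, 10, 10] = 10.0
        base[10, 10, 11] = 4.5   # above T_A = 4.2
        noisy = base.copy()
        noisy[10, 10, 10] = 12.0  # noise spike: T_B = 5.04 excludes 4.5
        _, _, les_a = transfer_rois(base, base, [], [(10, 10, 10)], "clean")
        _, _, les_b = transfer_rois(base, noisy, [], [(10, 10, 10)], "noisy")
        assert les_a[0].bbox_center == les_b[0].bbox_center
        assert not np.array_equal(les_a[0].mask, les_b[0].mask)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            transfer_rois(np.zeros((8, 8, 8)), np.zeros((9, 8, 8)), [], [])


class TestPairedStatistics:
    def test_percent_difference(self):
        assert percent_difference(10.0, 10.0) == 0.0
        assert percent_difference(7.8, 10.0) == pytest.approx(-22.0)
        with pytest.raises(ZeroDivisionError):
            percent_difference(1.0, 0.0)

    def test_scatter_slope_identity_and_known_gradient(self):
        x = np.array([2.0, 4.0, 6.0, 9.0])
        b, a = scatter_slope(x, x)
        assert (b, a) == (pytest.approx(1.0), pytest.approx(0.0))
        b, a = scatter_slope(x, 0.77 * x)
        assert b == pytest.approx(0.77)

    def test_scatter_slope_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([2.0, 2.5, 5.0, 8.5])
        n = len(x)
        b_ref = (n * (x * y).sum() - x.sum() * y.sum()) / \
            (n * (x * x).sum() - x.sum() ** 2)
        a_ref = y.mean() - b_ref * x.mean()
        b, a = scatter_slope(x, y)
        assert b == pytest.approx(b_ref)
        assert a == pytest.approx(a_ref)
        with pytest.raises(ValueError, match="zero variance"):
            scatter_slope(np.ones(4), y)

    def test_bland_altman_hand_computed(self):
        res = bland_altman([(0.0, 1.0), (0.0, -1.0)])
        assert res.mean_difference == 0.0
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_bland_altman_identical_series(self):
        res = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert (res.mean_difference, res.loa_low, res.loa_high) == (0, 0, 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=2, max_size=20),
           st.floats(-10, 10))
    def test_bland_altman_brackets_mean_and_shift_invariant(self, pairs, c):
        res = bland_altman(pairs)
        assert res.loa_low <= res.mean_difference <= res.loa_high
        shifted = bland_altman([(a + c, b + c) for a, b in pairs])
        assert shifted.mean_difference == pytest.approx(res.mean_difference,
                                                        abs=1e-9)
        assert shifted.loa_high == pytest.approx(res.loa_high, abs=1e-9)


def _exact_wilcoxon_p(d):
    """Independent enumeration oracle for the two-sided exact p value."""
    from scipy.stats import rankdata
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    totals = [np.dot(signs, ranks)
              for signs in itertools.product((0, 1), repeat=len(d))]
    totals = np.array(totals, float)
    p = 2 * min((totals <= w + 1e-9).mean(), (totals >= w - 1e-9).mean())
    return min(1.0, p)


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        w, p = wilcoxon_signed_rank(x, np.zeros(6))
        assert w == 21.0
        assert p == pytest.approx(2 / 64)

    def test_identical_samples_undefined(self):
        with pytest.raises(AllDifferencesZero):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_exact_branch_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        d = np.round(rng.normal(0.3, 1.0, n), 1)
        d[d == 0] = 0.5
        _, p = wilcoxon_signed_rank(d, np.zeros(n))
        assert p == pytest.approx(_exact_wilcoxon_p(d), abs=1e-12)

    def test_exact_and_approx_agree_at_n12(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            d = rng.normal(0.5, 1.0, 12)
            d[d == 0] = 0.1
            _, p_exact = wilcoxon_signed_rank(d, np.zeros(12))
            _, p_approx = wilcoxon_signed_rank(d, np.zeros(12), exact_max_n=0)
            # the continuity-corrected normal approximation is good to
            # about a percentage point at n = 12
            assert abs(p_exact - p_approx) < 0.015

    def test_approx_branch_matches_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon
        rng = np.random.default_rng(3)
        x = rng.normal(0.4, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        w, p = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, correction=True, method="approx")
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestKappa:
    def test_perfect_agreement(self):
        res = quadratic_weighted_kappa([0, 1, 2, 3], [0, 1, 2, 3], 4)
        assert res.kappa == pytest.approx(1.0)

    def test_hand_built_table(self):
        a = [0, 1, 2]
        b = [2, 1, 0]
        k = 3
        obs = np.zeros((k, k))
        for i, j in zip(a, b):
            obs[i, j] += 1
        n = 3
        exp = np.outer(obs.sum(1), obs.sum(0)) / n
        w = np.array([[(i - j) ** 2 for j in range(k)] for i in range(k)]) / 4
        expected = 1 - (w * obs).sum() / (w * exp).sum()
        res = quadratic_weighted_kappa(a, b, k)
        assert res.kappa == pytest.approx(expected)

    def test_relabeling_invariance(self):
        a = [0, 1, 1, 2, 3]
        b = [1, 1, 2, 2, 3]
        k1 = quadratic_weighted_kappa(a, b, 4).kappa
        k2 = quadratic_weighted_kappa([v + 1 for v in a], [v + 1 for v in b],
                                      5).kappa
        # weights depend only on score differences scaled by (k-1)^2;
        # growing the range rescales both numerator and denominator alike
        assert k2 == pytest.approx(k1, abs=1e-12)

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedKappa):
            quadratic_weighted_kappa([2, 2, 2], [2, 2, 2], 6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                    min_size=2, max_size=40))
    def test_matches_sklearn_and_stays_in_range(self, pairs):
        from sklearn.metrics import cohen_kappa_score
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        try:
            res = quadratic_weighted_kappa(a, b, 6)
        except UndefinedKappa:
            return
        assert -1.0 - 1e-9 <= res.kappa <= 1.0 + 1e-9
        ref = cohen_kappa_score(a, b, labels=list(range(6)),
                                weights="quadratic")
        assert res.kappa == pytest.approx(ref, abs=1e-9)


class TestReaderTables:
    def _table(self, scores, ranks, series=("a", "b", "c")):
        rows = []
        for s, sc, rk in zip(series, scores, ranks):
            rows.append({"case": 1, "series": s, "metric": "iq",
                         "reader": 1, "score": sc, "rank": rk})
        return pd.DataFrame(rows)

    def test_all_fours(self):
        out = aggregate_reader_tables(self._table([4, 4, 4], [1, 2, 3]))
        assert (out["mean_score"] == 4).all()
        assert (out["sd_score"].isna() | (out["sd_score"] == 0)).all()
        assert (out["pct_score_ge_3"] == 100.0).all()

    def test_two_scores_hand_arithmetic(self):
        t = pd.concat([self._table([3, 1, 2], [1, 3, 2]),
                       self._table([5, 1, 2], [1, 3, 2]).assign(case=2)])
        out = aggregate_reader_tables(t)
        row = out[out["series"] == "a"].iloc[0]
        assert row["mean_score"] == pytest.approx(4.0)
        assert row["sd_score"] == pytest.approx(np.sqrt(2.0))
        assert row["pct_score_ge_3"] == 100.0

    def test_competition_ranking_validation(self):
        validate_rank_vector([1, 1, 3])
        with pytest.raises(ValueError):
            validate_rank_vector([1, 1, 2])
        with pytest.raises(ValueError):
            validate_rank_vector([2, 3, 4])
        aggregate_reader_tables(self._table([3, 3, 2], [1, 1, 3]))
        with pytest.raises(ValueError, match="competition"):
            aggregate_reader_tables(self._table([3, 3, 2], [1, 1, 2]))

    def test_missing_cells_listed(self):
        t = self._table([4, 4, 4], [1, 2, 3])
        t = pd.concat([t, t.assign(case=2).iloc[:2]])
        with pytest.raises(ValueError, match="missing cells"):
            aggregate_reader_tables(t)

    def test_score_range_enforced(self):
        with pytest.raises(ValueError, match="0..5"):
            aggregate_reader_tables(self._table([4, 6, 4], [1, 2, 3]))
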
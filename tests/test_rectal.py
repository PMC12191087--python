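"""Few-shot rectum segmentation, area measurement, group tests, breakpoints."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from adcqual import phantom
from adcqual.rectal import (
    SupportSet,
    compare_groups,
    fit_piecewise_logistic,
    measure_area,
    measure_cohort_areas,
    segment_rectum,
    support_set_from_visits,
)


def simulate_breakpoint_data(rng, n=400, psi=700.0, *, lo=200.0, hi=1400.0,
                             b0=-2.5, b1=0.0, b2=0.012):
    """Areas uniform on [lo, hi]; failure odds jump in slope at psi."""
    areas = rng.uniform(lo, hi, n)
    logit = b0 + b1 * areas + b2 * np.maximum(areas - psi, 0.0)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return areas, y


class TestSupportSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            SupportSet(images=[], masks=[])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SupportSet(images=[np.zeros((8, 8))], masks=[np.zeros((4, 4))])


class TestSegmentation:
    @pytest.fixture(scope="class")
    def rendered(self):
        cfg = phantom.PhantomConfig(
            n_patients=16, n_sites=1, slices_per_volume=3, image_size=64,
            pixel_spacing=2.0, seed=17,
        )
        visits, _ = phantom.generate_cohort(cfg)
        return visits

    def test_self_retrieval(self, rendered):
        support = support_set_from_visits(rendered[:10], 10, seed=0)
        soft = segment_rectum(support.images[0], support, seed=0)
        corr = np.corrcoef(soft.ravel(),
                           support.masks[0].astype(float).ravel())[0, 1]
        assert corr >= 0.9

    def test_empty_support_masks_give_zero_mask(self, rendered):
        support = support_set_from_visits(rendered[:5], 5, seed=0)
        empty = SupportSet(images=support.images,
                           masks=[np.zeros_like(m) for m in support.masks],
                           spacing=support.spacing)
        soft = segment_rectum(support.images[0], empty, seed=0)
        assert np.all(soft == 0)

    def test_dice_on_held_out_phantoms(self, rendered):
        support = support_set_from_visits(rendered[:10], 10, seed=0)
        dices = []
        for v in rendered[10:15]:
            img = v.t2_stack[v.masks["central_slice"]]
            truth = v.masks["rectum_mask"]
            soft = segment_rectum(img, support, seed=0)
            hard = soft >= 0.5
            inter = np.logical_and(hard, truth).sum()
            dices.append(2 * inter / (hard.sum() + truth.sum() + 1e-9))
        assert np.mean(dices) >= 0.7


class TestMeasureArea:
    def test_zero_mask(self):
        assert measure_area(np.zeros((10, 10)), 1.0) == 0.0

    def test_block_of_ones(self):
        assert measure_area(np.ones((10, 10)), 1.0) == pytest.approx(100.0)

    def test_soft_sum_with_spacing(self):
        assert measure_area(np.full((10, 10), 0.5), 2.0) == pytest.approx(200.0)

    def test_threshold_variant(self):
        m = np.full((10, 10), 0.4)
        assert measure_area(m, 1.0, threshold=0.5) == 0.0
        assert measure_area(m, 1.0, threshold=0.3) == pytest.approx(100.0)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            measure_area(np.ones((2, 2)), 0.0)


def kruskal_by_definition(groups):
    """H from the rank-sum definition, computed directly (no ties)."""
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = len(pooled)
    h, i = 0.0, 0
    for g in groups:
        r = ranks[i : i + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        i += len(g)
    return 12.0 / (n * (n + 1)) * h


class TestCompareGroups:
    def test_identical_observations_give_zero_H(self):
        areas = np.full(30, 5.0)
        labels = np.r_[np.ones(10), np.full(10, 2), np.full(10, 3)]
        r = compare_groups(areas, labels)
        assert r.H == 0.0 and r.p_kruskal == 1.0

    def test_H_matches_rank_definition(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                  np.array([7.0, 8, 9])]
        areas = np.concatenate(groups)
        labels = np.r_[np.ones(3), np.full(3, 2), np.full(3, 3)]
        r = compare_groups(areas, labels)
        assert r.H == pytest.approx(kruskal_by_definition(groups), abs=1e-10)

    def test_dunn_adjustment_never_decreases(self, rng):
        areas = rng.normal(size=60)
        labels = np.repeat([1, 2, 3], 20)
        r = compare_groups(areas, labels)
        for pair in r.dunn_p_raw:
            assert r.dunn_p_adjusted[pair] >= r.dunn_p_raw[pair] - 1e-12

    def test_t_test_reported_for_pairs(self, rng):
        areas = np.r_[rng.normal(0, 1, 20), rng.normal(2, 1, 20)]
        labels = np.r_[np.ones(20), np.full(20, 3)]
        r = compare_groups(areas, labels)
        t, p = r.t_tests[(1, 3)]
        assert p < 0.01 and t < 0


class TestPiecewiseLogistic:
    def test_planted_jump_recovered(self):
        rng = np.random.default_rng(42)
        areas, y = simulate_breakpoint_data(rng, n=400, psi=700.0)
        fit = fit_piecewise_logistic(areas, y)
        assert fit.converged
        assert abs(fit.breakpoint - 700.0) <= 0.15 * 700.0
        assert fit.slope_post > fit.slope_pre

    def test_null_data_chance_auc(self):
        rng = np.random.default_rng(7)
        areas = rng.uniform(200, 1400, 400)
        y = (rng.random(400) < 0.3).astype(int)
        fit = fit_piecewise_logistic(areas, y)
        assert abs(fit.auc - 0.5) < 0.07
        # breakpoint term adds little likelihood under the null
        assert fit.loglik - fit.loglik_null < 5.0

    def test_perfect_separation_brackets_breakpoint(self):
        rng = np.random.default_rng(1)
        areas = np.r_[rng.uniform(200, 600, 30), rng.uniform(800, 1200, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        fit = fit_piecewise_logistic(areas, y)
        assert areas[:30].max() - 1 <= fit.breakpoint <= areas[30:].min() + 1
        assert fit.auc == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_piecewise_logistic(np.arange(10), np.r_[np.zeros(5), np.ones(5)])
        with pytest.raises(ValueError):
            fit_piecewise_logistic(np.arange(30), np.zeros(30, int))


class TestCohortLinkage:
    def test_measured_areas_track_true_areas(self):
        cfg = phantom.PhantomConfig(
            n_patients=25, n_sites=1, slices_per_volume=3, image_size=64,
            pixel_spacing=2.0, seed=5,
        )
        visits, _ = phantom.generate_cohort(cfg)
        support = support_set_from_visits(visits[:10], 10, seed=0)
        areas = measure_cohort_areas(visits[10:], support, seed=0)
        truth = np.array([v.rectal_area_true for v in visits[10:]])
        assert np.corrcoef(areas, truth)[0, 1] > 0.85
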
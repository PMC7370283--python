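"""Per-chip sprouting readouts: distance, gated area, nuclei count."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sproutassay.metrics import (
    SproutMetrics,
    estimate_baseline,
    migration_distance,
    nuclei_in_sprouts,
    quantify_chip,
    total_sprout_area,
)
from sproutassay.segmentation import SegmentationResult


def make_seg(mask, nuclei_um, baseline_y=400.0, pixel_size=1.0):
    return SegmentationResult(
        vessel_mask=mask.astype(bool),
        skeleton=np.zeros_like(mask, dtype=bool),
        nuclei=np.asarray(nuclei_um, dtype=float).reshape(-1, 2),
        baseline_y=baseline_y,
        pixel_size=pixel_size,
    )


def brute_distance(nuclei, baseline, k):
    ys = sorted(y for _, y in nuclei if y > baseline)
    if not ys:
        return 0.0
    return float(np.mean(ys[-k:]) - baseline)


class TestMigrationDistance:
    def test_no_nuclei_beyond_baseline_is_zero(self):
        pts = [(10, 100), (20, 399)]
        assert migration_distance(np.array(pts), 400.0) == 0.0

    def test_twelve_nuclei_top_ten(self):
        # y = 400, 410, ..., 510; top-10 are 420..510, mean 465
        pts = [(float(i), 400.0 + 10 * i) for i in range(12)]
        assert migration_distance(np.array(pts), 400.0) == pytest.approx(65.0)

    def test_fewer_than_k_averages_all(self):
        pts = [(0, 450.0), (1, 500.0), (2, 600.0)]
        result = migration_distance(np.array(pts), 400.0)
        assert result == pytest.approx(516.666667 - 400.0, abs=1e-4)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(1000):
            n = rng.integers(0, 40)
            pts = np.column_stack(
                [rng.uniform(0, 1000, n), rng.uniform(0, 900, n)]
            )
            k = int(rng.integers(1, 15))
            base = float(rng.uniform(0, 500))
            assert migration_distance(pts, base, k) == pytest.approx(
                brute_distance(pts, base, k), abs=1e-9
            )

    @settings(deadline=None, max_examples=100)
    @given(
        ys=st.lists(st.floats(0, 1000), min_size=0, max_size=30),
        k=st.integers(1, 12),
        base=st.floats(0, 600),
    )
    def test_oracle_property(self, ys, k, base):
        pts = np.column_stack([np.zeros(len(ys)), np.asarray(ys)])
        assert migration_distance(pts, base, k) == pytest.approx(
            brute_distance([(0, y) for y in ys], base, k), abs=1e-9
        )

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            migration_distance(np.empty((0, 2)), -1.0)
        with pytest.raises(ValueError):
            migration_distance(np.empty((0, 2)), 0.0, k=0)


class TestTotalSproutArea:
    def test_only_nucleated_components_count(self):
        # 500-px component with nuclei + 300-px component without, 0.677 µm/px
        mask = np.zeros((1200, 100), dtype=bool)
        mask[700:750, 10:20] = True   # 500 px, gets 2 nuclei
        mask[800:830, 50:60] = True   # 300 px, anucleate
        px = 0.677
        nuclei = [(14 * px, 710 * px), (15 * px, 730 * px), (30, 100)]
        seg = make_seg(mask, nuclei, baseline_y=400.0, pixel_size=px)
        assert total_sprout_area(seg) == pytest.approx(500 * px**2)

    def test_empty_mask(self):
        seg = make_seg(np.zeros((600, 50)), [(10, 500)])
        assert total_sprout_area(seg) == 0.0

    def test_vacuous_gate_equals_full_gel_area(self):
        mask = np.zeros((600, 50), dtype=bool)
        mask[450:470, 10:20] = True
        seg = make_seg(mask, [(15, 460)])
        assert total_sprout_area(seg) == pytest.approx(mask[400:].sum())

    def test_bounded_by_total_gel_mask_area(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            mask = rng.random((120, 60)) > 0.6
            nuclei = np.column_stack(
                [rng.uniform(0, 60, 15), rng.uniform(0, 120, 15)]
            )
            seg = make_seg(mask, nuclei, baseline_y=40.0)
            gel_area = mask[40:].sum() * 1.0
            assert total_sprout_area(seg) <= gel_area + 1e-9


class TestNucleiInSprouts:
    def test_counts_only_gel_nuclei_inside_mask(self):
        mask = np.zeros((600, 100), dtype=bool)
        mask[380:550, 40:60] = True
        gel_inside = [(50.0, 420 + 20 * i) for i in range(5)]
        monolayer = [(50.0, 100.0), (45.0, 200.0), (55.0, 390.0)]
        outside = [(90.0, 450.0)]
        seg = make_seg(mask, gel_inside + monolayer + outside)
        assert nuclei_in_sprouts(seg) == 5

    def test_no_nuclei(self):
        seg = make_seg(np.ones((500, 20)), np.empty((0, 2)))
        assert nuclei_in_sprouts(seg) == 0


class TestQuantifyChip:
    def _site(self):
        mask = np.zeros((600, 100), dtype=bool)
        mask[420:520, 40:50] = True
        nuclei = [(45.0, 430.0 + 10 * i) for i in range(8)]
        return make_seg(mask, nuclei)

    def test_two_identical_sites_average_distance_sum_area(self):
        s = self._site()
        single = quantify_chip([s], "one")
        double = quantify_chip([s, s], "two")
        assert double.migration_distance == pytest.approx(single.migration_distance)
        assert double.total_area == pytest.approx(2 * single.total_area)
        assert double.nuclei_in_sprouts == 2 * single.nuclei_in_sprouts
        assert double.n_sites == 2

    def test_single_site_passthrough(self):
        s = self._site()
        m = quantify_chip([s], "chip")
        assert m.migration_distance == pytest.approx(
            migration_distance(s.nuclei, s.baseline_y)
        )
        assert m.total_area == pytest.approx(total_sprout_area(s))

    def test_mismatched_pixel_sizes_rejected(self):
        a = self._site()
        b = make_seg(np.zeros((600, 100)), [(1, 1)], pixel_size=2.0)
        with pytest.raises(ValueError):
            quantify_chip([a, b], "bad")

    def test_x_translation_invariance(self):
        mask = np.zeros((600, 200), dtype=bool)
        mask[420:520, 40:50] = True
        nuclei = np.array([(45.0, 430.0 + 10 * i) for i in range(8)])
        seg = make_seg(mask, nuclei)
        shifted = make_seg(np.roll(mask, 60, axis=1), nuclei + [60.0, 0.0])
        m0, m1 = quantify_chip([seg], "a"), quantify_chip([shifted], "b")
        assert m0.migration_distance == m1.migration_distance
        assert m0.total_area == m1.total_area
        assert m0.nuclei_in_sprouts == m1.nuclei_in_sprouts

    def test_negative_metrics_rejected(self):
        with pytest.raises(ValueError):
            SproutMetrics("x", total_area=-1, migration_distance=0,
                          nuclei_in_sprouts=0, total_length=0)


class TestEstimateBaseline:
    def test_finds_monolayer_band(self):
        rng = np.random.default_rng(5)
        mono = np.column_stack([rng.uniform(0, 500, 200),
                                rng.uniform(350, 400, 200)])
        sprouts = np.column_stack([rng.uniform(0, 500, 30),
                                   rng.uniform(400, 700, 30)])
        est = estimate_baseline(np.vstack([mono, sprouts]))
        assert 360 <= est <= 420

    def test_requires_nuclei(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.empty((0, 2)))
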
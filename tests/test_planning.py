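"""Spot placement, dose-ratio selection, collimation and trimmer geometry."""

import math

import numpy as np
import pytest

from dcplan import planning, targets
from dcplan.beamlets import OPEN_CONFIG, TrimmerConfig
from dcplan.planning import (
    CandidateSpot,
    KernelSampler,
    assign_collimation,
    dose_ratio,
    place_spots,
    plan_from_table,
    plan_to_table,
    select_spots,
    trimmer_positions_for_spot,
)


class TestPlaceSpots:
    def test_lattice_spacing(self):
        t = targets.make_circle_target(80.0, spacing=0.5, padding=20.0)
        spots = place_spots(t, 2.5)
        xs = np.unique(spots.positions[:, 0])
        assert np.allclose(np.diff(xs), 2.5)

    def test_finer_spacing_gives_more_spots(self):
        t = targets.make_kidney_bean_target("small", spacing=0.5)
        coarse = place_spots(t, 2.5)
        fine = place_spots(t, 1.0)
        assert len(fine.positions) > len(coarse.positions)

    def test_lattice_contains_centroid(self, circle3):
        spots = place_spots(circle3, 2.5)
        cx, cy = circle3.centroid()
        d = np.abs(spots.positions - [cx, cy]).sum(axis=1)
        assert d.min() < 1e-9

    def test_margin_extends_beyond_bounding_box(self, circle3):
        spots = place_spots(circle3, 2.5, margin=10.0)
        assert spots.positions[:, 0].max() >= 15.0 + 7.5

    def test_invalid_spacing(self, circle3):
        with pytest.raises(ValueError):
            place_spots(circle3, 0.0)


class TestDoseRatio:
    def test_half_plane_target_gives_100(self, library_nrs5):
        # straight-edged half-plane: dose splits evenly by symmetry
        n = 241
        mask = np.zeros((n, n), dtype=bool)
        mask[:, : (n + 1) // 2] = True
        mask[0, :] = mask[-1, :] = mask[:, 0] = False
        t = targets.TargetGeometry(
            mask=mask, spacing=0.5, origin=(-60.0, -60.0), shape_label="half"
        )
        # beamlet centered on the edge at x = +0.25 (mask boundary between nodes)
        dr = dose_ratio(library_nrs5.uncollimated, (0.25, 0.0), t)
        assert dr == pytest.approx(100.0, rel=0.01)

    def test_far_outside_is_negligible(self, library_nrs5, circle3):
        dr = dose_ratio(library_nrs5.uncollimated, (15.0 + 80.0, 0.0), circle3)
        assert dr < 0.1

    def test_center_beats_boundary(self, library_nrs5):
        t = targets.make_circle_target(80.0, spacing=0.5, padding=30.0)
        center = dose_ratio(library_nrs5.uncollimated, (0.0, 0.0), t)
        edge = dose_ratio(library_nrs5.uncollimated, (40.0, 0.0), t)
        assert center > edge

    def test_matches_brute_force_double_sum(self, library_nrs5):
        # oracle: explicit python loop over every grid node
        t = targets.make_circle_target(20.0, spacing=1.0, padding=15.0)
        kernel = library_nrs5.kernel_for(TrimmerConfig("X2", "Y1", 1.0, 2.0))
        pos = (6.0, -3.0)
        interp = kernel.interpolator()
        din = dout = 0.0
        for iy, y in enumerate(t.y_coords):
            for ix, x in enumerate(t.x_coords):
                v = float(interp((y - pos[1], x - pos[0])))
                if t.mask[iy, ix]:
                    din += v
                else:
                    dout += v
        expected = 100.0 * din / dout
        assert dose_ratio(kernel, pos, t) == pytest.approx(expected, rel=1e-9)

    def test_sampler_agrees_with_direct_evaluation(self, library_nrs5, circle3):
        sampler = KernelSampler(library_nrs5, circle3)
        for pos in [(0.0, 0.0), (14.5, -3.0), (-10.25, 7.75)]:
            direct = dose_ratio(library_nrs5.uncollimated, pos, circle3)
            fast = sampler.dose_ratio(OPEN_CONFIG, pos)
            assert fast == pytest.approx(direct, rel=1e-6)


class TestSelection:
    def test_zero_threshold_keeps_all(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        kept = select_spots(spots, library_nrs5, circle3, 0.0)
        assert len(kept) == len(spots.positions)

    def test_unattainable_threshold_empties_selection(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        kept = select_spots(spots, library_nrs5, circle3, 1e9)
        assert kept == []

    def test_lower_threshold_adds_outside_spots(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        strict = select_spots(spots, library_nrs5, circle3, 30.0)
        loose = select_spots(spots, library_nrs5, circle3, 16.0)
        assert len(loose) >= len(strict)
        extra = set(s.position for s in loose) - set(s.position for s in strict)
        assert extra
        r = 15.0
        assert all(math.hypot(*p) > r for p in extra)

    def test_kept_count_non_increasing_in_threshold(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        counts = [
            len(select_spots(spots, library_nrs5, circle3, dr))
            for dr in (0.0, 10.0, 20.0, 30.0, 60.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCollimationAssignment:
    def test_zero_level_collimates_nothing(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        kept = select_spots(spots, library_nrs5, circle3, 16.0)
        out = assign_collimation(kept, library_nrs5, circle3, 0.0)
        assert all(s.config.engaged == 0 for s in out)

    def test_count_non_decreasing_in_level(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        kept = select_spots(spots, library_nrs5, circle3, 16.0)
        sampler = KernelSampler(library_nrs5, circle3)
        counts = [
            sum(
                s.config.engaged > 0
                for s in assign_collimation(kept, library_nrs5, circle3, t, sampler)
            )
            for t in (0.0, 20.0, 40.0, 65.0, 70.0, 100.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_interior_sentinel_never_collimated(self, library_nrs5):
        # a spot whose kernel lies entirely inside the target has Dout = 0
        t = targets.make_circle_target(260.0, spacing=2.0, padding=20.0)
        spot = CandidateSpot(position=(0.0, 0.0), config=OPEN_CONFIG, dr=math.inf)
        out = assign_collimation([spot], library_nrs5, t, 100.0)
        assert out[0].config.engaged == 0
        assert out[0].dr == math.inf

    def test_configs_stay_within_library(self, library_nrs5, circle3):
        spots = place_spots(circle3, 2.5)
        kept = select_spots(spots, library_nrs5, circle3, 16.0)
        out = assign_collimation(kept, library_nrs5, circle3, 70.0)
        allowed = set(library_nrs5.configs()) | {OPEN_CONFIG}
        assert {s.config for s in out} <= allowed

    def test_invalid_level_rejected(self, library_nrs5, circle3):
        with pytest.raises(ValueError):
            assign_collimation([], library_nrs5, circle3, 120.0)


class TestTrimmerPositions:
    def test_engaged_edge_coordinates(self):
        spot = CandidateSpot(
            position=(10.0, 0.0),
            config=TrimmerConfig("X2", "Out", 1.0, None),
            dr=50.0,
        )
        assert trimmer_positions_for_spot(spot) == (None, 11.0, None, None)

    def test_one_blade_each_side(self):
        spot = CandidateSpot(
            position=(-4.0, 2.5),
            config=TrimmerConfig("X1", "Y2", 2.0, 1.0),
            dr=50.0,
        )
        assert trimmer_positions_for_spot(spot) == (-6.0, None, None, 3.5)

    def test_sub_minimum_offset_rejected(self):
        spot = CandidateSpot(
            position=(0.0, 0.0),
            config=TrimmerConfig("X2", "Out", 0.5, None),
            dr=50.0,
        )
        with pytest.raises(ValueError, match="minimum"):
            trimmer_positions_for_spot(spot)

    def test_same_axis_pairing_forbidden(self):
        with pytest.raises(ValueError):
            TrimmerConfig("X1", "X2", 1.0, 1.0)


def test_plan_table_round_trip(circle3_pair):
    plan = circle3_pair.coll.plan
    text = plan_to_table(plan)
    back = plan_from_table(text)
    assert len(back.spots) == len(plan.spots)
    assert back.beam == plan.beam
    assert np.allclose(back.weights, plan.weights, rtol=1e-5)
    for a, b in zip(back.spots, plan.spots):
        assert a.config == b.config
        assert a.position == pytest.approx(b.position, abs=1e-3)
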
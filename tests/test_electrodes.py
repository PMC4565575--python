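"""Needle geometry, star configuration, schedules, rasterization, collisions."""

import numpy as np
import pytest

from ectplan.phantom import (
    BONE,
    VESSEL,
    Cylinder,
    PhantomConfig,
    Slab,
    VoxelPhantom,
    make_phantom,
)
from ectplan.electrodes import (
    ElectrodeArray,
    NeedleElectrode,
    PulseSchedule,
    ScheduleEntry,
    STAR_PAIR_ORDER,
    check_collisions,
    rasterize,
    star_array,
    star_schedule,
    voltage_to_distance_ratio,
)


class TestStarArray:
    def test_adjacent_peripheral_spacing_is_14_mm(self):
        array = star_array((0, 0, 0), (0, 0, 1), center_to_outer=10.0)
        d = array.pair_distance(1, 2)
        assert round(d / 10.0, 1) == 1.4  # cm, as printed in the protocol

    def test_opposite_peripheral_distance_is_twice_radius(self):
        array = star_array((0, 0, 0), (0, 0, 1), center_to_outer=10.0)
        assert array.pair_distance(1, 3) == pytest.approx(20.0)

    def test_center_electrode_is_id_5(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        for outer in (1, 2, 3, 4):
            assert array.pair_distance(outer, 5) == pytest.approx(10.0)

    def test_needles_parallel(self):
        array = star_array((0, 0, 0), (1, 1, 1))
        dirs = [e.direction for e in array]
        for d in dirs[1:]:
            assert np.dot(dirs[0], d) == pytest.approx(1.0)

    def test_geometry_invariant_under_direction_rotation(self):
        a1 = star_array((0, 0, 0), (0, 0, 1))
        a2 = star_array((0, 0, 0), (0.3, -0.8, 0.52))
        pairs = [(1, 2), (2, 3), (1, 3), (1, 5), (4, 5)]
        for p in pairs:
            assert a1.pair_distance(*p) == pytest.approx(a2.pair_distance(*p))

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError):
            star_array((0, 0, 0), (0, 0, 0))

    def test_tips_at_equal_depth(self):
        array = star_array((1.0, 2.0, 3.0), (0, 0, 1), active_tip=30.0)
        depths = [np.dot(e.tip, (0, 0, 1)) for e in array]
        assert np.ptp(depths) == pytest.approx(0.0)


class TestStarSchedule:
    def test_protocol_counts(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        schedule = star_schedule(array)
        assert len(schedule) == 8
        assert schedule.total_pulses == 64

    def test_pair_order_and_voltages(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        schedule = star_schedule(array)
        assert [e.pair for e in schedule] == STAR_PAIR_ORDER
        for e in schedule:
            assert e.voltage == (1000.0 if 5 in e.pair else 1200.0)
            assert e.n_pulses == 8
            assert e.pulse_duration_us == 100.0

    def test_total_pulses_linear_in_n_pulses(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        assert star_schedule(array, n_pulses=1).total_pulses == 8
        assert star_schedule(array, n_pulses=3).total_pulses == 24

    def test_non_star_array_rejected(self):
        electrodes = [
            NeedleElectrode(id=i, entry=(x, 0, 0), tip=(x, 0, 50), active_tip_length=30)
            for i, x in ((1, 0.0), (2, 10.0))
        ]
        array = ElectrodeArray(electrodes, (0, 0, 1))
        with pytest.raises(ValueError, match="star"):
            star_schedule(array)


class TestVoltageToDistanceRatio:
    def test_center_outer_is_1000_v_per_cm(self):
        array = star_array((0, 0, 0), (0, 0, 1), center_to_outer=10.0)
        entry = ScheduleEntry(pair=(1, 5), voltage=1000.0)
        assert voltage_to_distance_ratio(entry, array) == pytest.approx(1000.0)

    def test_outer_outer_ratio(self):
        array = star_array((0, 0, 0), (0, 0, 1), center_to_outer=10.0)
        entry = ScheduleEntry(pair=(1, 2), voltage=1200.0)
        # 1200 V over sqrt(2) cm
        assert voltage_to_distance_ratio(entry, array) == pytest.approx(848.5, abs=0.5)

    def test_zero_voltage_gives_zero(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        entry = ScheduleEntry(pair=(1, 5), voltage=0.0)
        assert voltage_to_distance_ratio(entry, array) == 0.0


def _block_phantom(shape=(40, 40, 60), spacing=1.0):
    return make_phantom(PhantomConfig(shape=shape, spacing=spacing))


class TestRasterize:
    def test_axis_aligned_needle_is_a_voxel_column(self):
        phantom = _block_phantom()
        # axis through voxel centers (x=20.5, y=20.5), active tip 30 mm
        e = NeedleElectrode(id=1, entry=(20.5, 20.5, 2.0), tip=(20.5, 20.5, 45.0),
                            active_tip_length=30.0, radius=0.4)
        array = ElectrodeArray([e], (0, 0, 1))
        mask = rasterize(array, phantom)[1]
        assert mask.sum() == 30
        cols = np.argwhere(mask)
        assert (cols[:, 0] == 20).all() and (cols[:, 1] == 20).all()

    def test_masks_disjoint_for_separated_needles(self):
        phantom = _block_phantom()
        electrodes = [
            NeedleElectrode(id=i, entry=(x, 20.5, 2.0), tip=(x, 20.5, 45.0),
                            active_tip_length=30.0, radius=0.4)
            for i, x in ((1, 15.5), (2, 25.5))
        ]
        masks = rasterize(ElectrodeArray(electrodes, (0, 0, 1)), phantom)
        assert not (masks[1] & masks[2]).any()

    def test_tip_outside_grid_rejected(self):
        phantom = _block_phantom()
        e = NeedleElectrode(id=1, entry=(20.5, 20.5, 2.0), tip=(20.5, 20.5, 80.0),
                            active_tip_length=30.0, radius=0.4)
        with pytest.raises(ValueError, match="outside"):
            rasterize(ElectrodeArray([e], (0, 0, 1)), phantom)

    def test_mask_grows_monotonically_with_radius(self):
        phantom = _block_phantom()
        counts = []
        for radius in (0.4, 0.8, 1.6, 2.4):
            e = NeedleElectrode(id=1, entry=(20.5, 20.5, 2.0), tip=(20.5, 20.5, 45.0),
                                active_tip_length=30.0, radius=radius)
            counts.append(rasterize(ElectrodeArray([e], (0, 0, 1)), phantom)[1].sum())
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert counts[0] < counts[-1]


class TestCheckCollisions:
    @staticmethod
    def _anatomy_phantom():
        return make_phantom(
            PhantomConfig(
                shape=(40, 40, 60), spacing=1.0,
                vessel=Cylinder(point=(20.0, 20.0, 30.0), direction=(0, 1, 0), radius=3.0),
                bone=Slab(normal=(1, 0, 0), offset=36.0, thickness=6.0),
            )
        )

    def test_needle_through_vessel_reported(self):
        phantom = self._anatomy_phantom()
        e = NeedleElectrode(id=1, entry=(20.5, 20.5, 2.0), tip=(20.5, 20.5, 50.0),
                            active_tip_length=30.0, radius=0.4)
        violations = check_collisions(ElectrodeArray([e], (0, 0, 1)), phantom)
        assert [(v.electrode_id, v.tissue_code) for v in violations] == [(1, VESSEL)]

    def test_clear_soft_tissue_star_is_admissible(self):
        phantom = self._anatomy_phantom()
        array = star_array((10.0, 10.0, 25.0), (0, 0, 1), center_to_outer=5.0,
                           active_tip=20.0)
        assert check_collisions(array, phantom) == []

    def test_radius_inflation_catches_near_miss(self):
        # bone voxel centers start at x = 33.25; a 0.4 mm-radius shaft at
        # x = 33.0 reaches them although the shaft axis stays outside bone
        phantom = make_phantom(
            PhantomConfig(
                shape=(80, 80, 80), spacing=0.5,
                bone=Slab(normal=(1, 0, 0), offset=36.0, thickness=6.0),
            )
        )
        for x, expect_hit in ((33.0, True), (32.0, False)):
            e = NeedleElectrode(id=1, entry=(x, 20.25, 2.25), tip=(x, 20.25, 35.25),
                                active_tip_length=20.0, radius=0.4)
            violations = check_collisions(ElectrodeArray([e], (0, 0, 1)), phantom)
            assert bool(violations) is expect_hit
            if expect_hit:
                assert violations[0].tissue_code == BONE


class TestScheduleValidation:
    def test_unknown_ids_rejected(self):
        array = star_array((0, 0, 0), (0, 0, 1))
        schedule = PulseSchedule([ScheduleEntry(pair=(1, 9), voltage=1000.0)])
        with pytest.raises(ValueError, match="unknown electrode"):
            schedule.validate_against(array)

    def test_entry_invariants(self):
        with pytest.raises(ValueError):
            ScheduleEntry(pair=(1, 2), voltage=-5.0)
        with pytest.raises(ValueError):
            ScheduleEntry(pair=(1, 2), voltage=100.0, n_pulses=0)
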
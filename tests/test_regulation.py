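"""Clocks, division decisions, zone transitions and growth rules."""

import numpy as np
import pytest

from rootsim.core_mesh import Role, Zone, build_root_grid
from rootsim.regulation import (
    AuxinThresholdExit, ConstantIncrement, CounterExit, GaThresholdExit,
    LayerDrivenGrowth, RelativeGrowth, RuleConfig, RulerExit, SizerDivision,
    TimerDivision, TimerExit, apply_growth, layer_driven_follow,
    resample_noise, should_divide, update_clocks, zone_transition,
)


@pytest.fixture
def grid():
    """3 x 6 grid: 3 QC rows + 3 body rows of 10 x 10 µm cells."""
    return build_root_grid(3, 6, [10.0] * 3, row_height=10.0)


def body_rows(mesh):
    """Body cells grouped by axial position, tipmost first."""
    body = [c for c in mesh.cells.values() if c.role is Role.BODY]
    rows = {}
    for c in body:
        rows.setdefault(round(mesh.axial_position(c), 6), []).append(c)
    return [rows[k] for k in sorted(rows)]


class TestClocks:
    def test_contact_cells_stay_stem_with_zero_clock(self, grid):
        for _ in range(10):
            update_clocks(grid, 30.0)
        rows = body_rows(grid)
        for cell in rows[0]:          # adjacent to the QC block
            assert cell.zone is Zone.STEM
            assert cell.t_release == 0.0
            assert cell.division_count == 0

    def test_released_cells_accumulate_time(self, grid):
        for _ in range(4):
            update_clocks(grid, 30.0)
        rows = body_rows(grid)
        for cell in rows[1] + rows[2]:
            assert cell.t_release == pytest.approx(120.0)

    def test_clock_counts_from_release_step(self, grid):
        """A cell marked STEM only starts its clock after it loses QC
        contact (hand-simulated release at step k)."""
        rows = body_rows(grid)
        probe = rows[1][0]
        probe.zone = Zone.STEM        # pretend it was in contact until now
        probe.t_release = 0.0
        update_clocks(grid, 30.0)     # release happens in this step
        assert probe.zone is Zone.DZ
        for _ in range(3):
            update_clocks(grid, 30.0)
        assert probe.t_release == pytest.approx(120.0)

    def test_reset_set_equals_contact_set(self, grid):
        update_clocks(grid, 30.0)
        contact = grid.qc_contact_cells()
        zeroed = {
            cid for cid, c in grid.cells.items()
            if c.role is Role.BODY and c.t_release == 0.0
        }
        assert zeroed == contact


class TestDivisionRules:
    def test_timer_boundary(self, grid, rng):
        rule = TimerDivision(cct=900.0)
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.DZ
        cell.t_since_division = 899.0
        assert not should_divide(cell, grid, rule, rng)
        cell.t_since_division = 900.0
        assert should_divide(cell, grid, rule, rng)

    def test_sizer_layer_thresholds(self, rng):
        """Outer files divide at 360 µm², inner at 180 µm²."""
        mesh = build_root_grid(4, 5, [15.0, 7.5, 7.5, 15.0], row_height=15.0)
        rule = SizerDivision(threshold=360.0,
                             threshold_by_file={1: 180.0, 2: 180.0})
        outer = next(c for c in mesh.cells.values()
                     if c.role is Role.BODY and c.file_index == 0)
        inner = next(c for c in mesh.cells.values()
                     if c.role is Role.BODY and c.file_index == 2)
        outer.zone = inner.zone = Zone.DZ
        # outer cell at 15x15 = 225 < 360: no division
        assert not should_divide(outer, mesh, rule, rng)

        def set_height(cell, width, height):
            bottom = max(mesh.nodes[n].y for n in cell.ring)
            for nid in set(cell.ring):
                if mesh.nodes[nid].y == bottom:
                    mesh.nodes[nid].y = height
            assert mesh.area(cell) == pytest.approx(width * height)

        set_height(outer, 15.0, 365.0 / 15.0)   # area 365 >= 360: divide
        assert should_divide(outer, mesh, rule, rng)
        set_height(inner, 7.5, 170.0 / 7.5)     # area 170 < 180: no
        assert not should_divide(inner, mesh, rule, rng)

    def test_noise_multipliers_respect_bounds(self, grid, rng):
        rule = TimerDivision(cct=900.0, noise=0.25, first_noise=0.10)
        cell = body_rows(grid)[1][0]
        firsts, laters = [], []
        for _ in range(300):
            cell.division_count = 0
            resample_noise(cell, rule, rng)
            firsts.append(cell.noise_mult)
            cell.division_count = 2
            resample_noise(cell, rule, rng)
            laters.append(cell.noise_mult)
        assert max(abs(m) for m in firsts) <= 0.10
        assert max(abs(m) for m in laters) <= 0.25
        assert max(abs(m) for m in laters) > 0.10   # noise actually used

    def test_divide_only_in_stem_or_dz(self, grid, rng):
        rule = TimerDivision(cct=900.0)
        cell = body_rows(grid)[1][0]
        cell.t_since_division = 5000.0
        cell.zone = Zone.EZ
        assert not should_divide(cell, grid, rule, rng)


class TestZoneTransitions:
    def test_ruler_positions(self, grid):
        rules = RuleConfig(dz_exit=RulerExit(240.0), ez_exit=RulerExit(750.0))
        cell = body_rows(grid)[1][0]

        def at(pos):
            face = grid.qc_face_y()
            span = grid.cell_length(cell)
            target_mid = face - pos
            current_mid = np.mean([grid.nodes[n].y for n in cell.ring])
            for nid in set(cell.ring):
                grid.nodes[nid].y += target_mid - current_mid
            return cell

        cell.zone = Zone.DZ
        assert zone_transition(at(200.0), grid, rules) is Zone.DZ
        cell.zone = Zone.DZ
        assert zone_transition(at(500.0), grid, rules) is Zone.EZ
        cell.zone = Zone.DZ
        assert zone_transition(at(800.0), grid, rules) is Zone.MZ

    def test_auxin_two_threshold_scheme(self, grid):
        rules = RuleConfig(
            dz_exit=AuxinThresholdExit(upper=13.5, lower=8.8),
            ez_exit=AuxinThresholdExit(upper=13.5, lower=8.8),
        )
        cell = body_rows(grid)[1][0]
        area = grid.area(cell)
        cell.zone = Zone.DZ
        cell.chem["auxin"] = 14.0 * area
        assert zone_transition(cell, grid, rules) is Zone.DZ
        cell.chem["auxin"] = 10.0 * area
        assert zone_transition(cell, grid, rules) is Zone.EZ
        cell.zone = Zone.DZ
        cell.chem["auxin"] = 5.0 * area
        assert zone_transition(cell, grid, rules) is Zone.MZ

    def test_counter_exit_after_three_divisions(self, grid):
        rules = RuleConfig(dz_exit=CounterExit(3), ez_exit=TimerExit(4440.0))
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.DZ
        cell.division_count = 2
        assert zone_transition(cell, grid, rules) is Zone.DZ
        cell.division_count = 3
        assert zone_transition(cell, grid, rules) is Zone.EZ

    def test_transitions_are_one_way(self, grid):
        rules = RuleConfig(dz_exit=TimerExit(100.0), ez_exit=TimerExit(200.0))
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.EZ
        cell.t_release = 0.0          # signal says DZ, but no going back
        assert zone_transition(cell, grid, rules) is Zone.EZ

    def test_ga_dilution_exit(self, grid):
        rules = RuleConfig(dz_exit=TimerExit(1.0),
                           ez_exit=GaThresholdExit(min_conc=0.5))
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.EZ
        cell.chem["ga"] = 0.6 * grid.area(cell)
        assert zone_transition(cell, grid, rules) is Zone.EZ
        cell.chem["ga"] = 0.4 * grid.area(cell)
        assert zone_transition(cell, grid, rules) is Zone.MZ

    def test_missing_signal_raises(self, grid):
        rules = RuleConfig(dz_exit=AuxinThresholdExit())
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.DZ
        cell.chem.clear()
        with pytest.raises(ValueError):
            zone_transition(cell, grid, rules)


class TestGrowthRules:
    def test_constant_increment_ignores_size(self, grid):
        rule = ConstantIncrement(20.0)
        rows = body_rows(grid)
        small, large = rows[1][0], rows[1][1]
        large.target_area = 500.0
        small.target_area = 50.0
        small.zone = large.zone = Zone.DZ
        apply_growth(small, grid, rule, 30.0)
        apply_growth(large, grid, rule, 30.0)
        assert small.target_area == pytest.approx(70.0)
        assert large.target_area == pytest.approx(520.0)

    def test_relative_ez_rate(self, grid):
        rule = RelativeGrowth(rate_dz=0.02, rate_ez=0.2)
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.EZ
        cell.target_area = 100.0
        apply_growth(cell, grid, rule, 30.0)
        assert cell.target_area == pytest.approx(120.0)

    def test_mz_and_qc_targets_frozen(self, grid):
        rule = RelativeGrowth(rate_dz=0.02, rate_ez=0.2)
        cell = body_rows(grid)[1][0]
        cell.zone = Zone.MZ
        cell.target_area = 100.0
        for _ in range(10):
            apply_growth(cell, grid, rule, 30.0)
        assert cell.target_area == 100.0
        qc = next(c for c in grid.cells.values() if c.role is Role.COLUMELLA_QC)
        a0 = qc.target_area
        apply_growth(qc, grid, rule, 30.0)
        assert qc.target_area == a0

    def test_layer_driven_follow_contract(self, grid):
        rule = LayerDrivenGrowth(driver_files=(1,),
                                 inner=RelativeGrowth(0.1, 0.2))
        for cell in grid.cells.values():
            if cell.role is Role.BODY:
                cell.zone = Zone.DZ
                apply_growth(cell, grid, rule, 30.0)
        layer_driven_follow(grid, rule.driver_files)
        for cell in grid.cells.values():
            if cell.role is not Role.BODY:
                continue
            if cell.file_index == 1:
                # driver keeps an expanding potential (A_T > A)
                assert cell.target_area > grid.area(cell)
            else:
                # follower resets to its actual area exactly
                assert cell.target_area == pytest.approx(grid.area(cell))
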
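"""Wall fluxes, source modes, conservation and the hormone network."""

import math

import numpy as np
import pytest

from rootsim.core_mesh import OUTSIDE, Role, Zone, build_root_grid
from rootsim.transport import (
    ChemSystem, TransportParams, apply_sources_and_sinks, assign_pin_layout,
    pin_repression_factor, steady_state_amounts, step_chemistry, total_amount,
    wall_flux,
)


def interior_wall(mesh):
    return next(w for w in mesh.walls() if w.cell_b != OUTSIDE)


def closed_params(**kw):
    """No sources, no degradation, no importer: pure diffusion."""
    base = dict(k_deg=0.0, k_import=0.0, boundary_flux=0.0,
                k_prod_area=0.0, k_prod_cell=0.0)
    base.update(kw)
    return TransportParams(**base)


class TestWallFlux:
    def test_zero_at_equal_concentrations(self, small_grid):
        w = interior_wall(small_grid)
        for cid in (w.cell_a, w.cell_b):
            cell = small_grid.cells[cid]
            cell.chem["auxin"] = 2.0 * small_grid.area(cell)
        f = wall_flux(small_grid, w.cell_a, w.cell_b, w, TransportParams())
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_zero_at_zero_amounts(self, small_grid):
        w = interior_wall(small_grid)
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = 0.0
        assert wall_flux(
            small_grid, w.cell_a, w.cell_b, w, TransportParams()
        ) == 0.0

    def test_antisymmetry_exact(self, small_grid, rng):
        params = TransportParams()
        layout = assign_pin_layout(small_grid, "reverse_fountain", 0.7)
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = float(rng.uniform(0, 50)) * small_grid.area(cell)
        for w in small_grid.walls():
            if w.cell_b == OUTSIDE:
                continue
            fab = wall_flux(small_grid, w.cell_a, w.cell_b, w, params, layout)
            fba = wall_flux(small_grid, w.cell_b, w.cell_a, w, params, layout)
            assert fab == pytest.approx(-fba, abs=1e-12 * max(1, abs(fab)))

    def test_two_cell_diffusion_matches_finite_difference_oracle(self):
        """Backward-Euler relaxation of an isolated 2-cell system against
        an independent explicit finite-difference integration of
        dq/dt = g (q_b/A - q_a/A) with g = (D/d) L_w."""
        from rootsim.core_mesh import Mesh

        mesh = Mesh()
        ids = [mesh.new_node(x, y) for x, y in
               [(0, 0), (10, 0), (20, 0), (20, 10), (10, 10), (0, 10)]]
        a = mesh.new_cell(ring=[ids[0], ids[1], ids[4], ids[5]],
                          target_area=100.0, initial_width=10.0)
        b = mesh.new_cell(ring=[ids[1], ids[2], ids[3], ids[4]],
                          target_area=100.0, initial_width=10.0)
        from rootsim.core_mesh import polygon_signed_area
        for cell in mesh.cells.values():
            if polygon_signed_area(mesh.ring_xy(cell)) < 0:
                cell.ring.reverse()
        mesh.invalidate()
        params = closed_params(diffusion=60.0, dt_chem=0.01)
        for cell in mesh.cells.values():
            cell.chem["auxin"] = 0.0
        a.chem["auxin"] = 200.0   # conc 2.0 vs 0.0
        area = mesh.area(a)
        g = params.diffusion / params.wall_thickness * 10.0  # L_w = 10 µm
        w = next(
            ww for ww in mesh.walls()
            if {ww.cell_a, ww.cell_b} == {a.id, b.id}
        )
        got = wall_flux(mesh, a.id, b.id, w, params)
        assert got == pytest.approx(g * 2.0, rel=1e-12)
        # relax for 1 min and compare against dense explicit oracle
        step_chemistry(mesh, params, None, dt=1.0, mode="PROD_CELL",
                       species=("auxin",))
        qa, qb = 200.0, 0.0
        dt = 1e-5
        for _ in range(int(1.0 / dt)):
            f = g * (qa - qb) / area
            qa -= f * dt
            qb += f * dt
        assert a.chem["auxin"] == pytest.approx(qa, rel=5e-3)
        assert b.chem["auxin"] == pytest.approx(qb, rel=5e-3)

    def test_negative_amounts_rejected(self, small_grid):
        w = interior_wall(small_grid)
        small_grid.cells[w.cell_a].chem["auxin"] = -1.0
        with pytest.raises(ValueError):
            wall_flux(small_grid, w.cell_a, w.cell_b, w, TransportParams())


class TestConservationAndDecay:
    def test_closed_system_conserves_mass_1e9(self, rng):
        """10⁴ implicit sub-steps of pure diffusion keep the total
        amount constant to 1e-9 relative."""
        mesh = build_root_grid(3, 5, [10.0] * 3, row_height=10.0)
        for cell in mesh.cells.values():
            cell.chem["auxin"] = float(rng.uniform(0, 100))
        params = closed_params(diffusion=6000.0, dt_chem=0.1)
        q0 = total_amount(mesh, "auxin")
        step_chemistry(mesh, params, None, dt=1000.0, mode="PROD_CELL",
                       species=("auxin",))
        assert total_amount(mesh, "auxin") == pytest.approx(q0, rel=1e-9)
        assert min(c.chem["auxin"] for c in mesh.cells.values()) >= 0.0

    def test_pure_degradation_matches_exponential(self, small_grid):
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = 10.0
        params = closed_params(diffusion=0.0, k_deg=3e-4, dt_chem=0.05)
        t = 2000.0
        step_chemistry(small_grid, params, None, dt=t, mode="PROD_CELL",
                       species=("auxin",))
        expect = 10.0 * math.exp(-3e-4 * t)
        for cell in small_grid.cells.values():
            assert cell.chem["auxin"] == pytest.approx(expect, rel=1e-3)

    def test_apply_sources_per_cell_production(self, small_grid):
        params = closed_params(k_prod_cell=5.0)
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = 0.0
        apply_sources_and_sinks(small_grid, params, "PROD_CELL", dt=2.0)
        for cell in small_grid.cells.values():
            assert cell.chem["auxin"] == pytest.approx(10.0)


class TestSourceModesOnGrowingTissue:
    """Limits of whole-root auxin concentration under uniform growth.

    Growth is emulated by inflating the mesh axially at a fixed
    relative rate between chemistry steps, isolating source-mode
    behaviour from mechanics.
    """

    def _grow(self, mesh, factor):
        for node in mesh.nodes.values():
            node.y *= factor

    def test_area_production_concentration_approaches_limit(self):
        mesh = build_root_grid(3, 6, [10.0] * 3, row_height=10.0)
        params = closed_params(diffusion=6000.0, k_prod_area=2.0, dt_chem=0.5)
        g = 0.01  # relative area growth per minute
        conc = []
        for _ in range(300):
            self._grow(mesh, 1.0 + g)
            step_chemistry(mesh, params, None, dt=1.0, mode="PROD_AREA",
                           species=("auxin",))
            conc.append(total_amount(mesh, "auxin") / mesh.total_area())
        # analytic limit for exponential growth: k_prod_area / g
        assert conc[-1] == pytest.approx(2.0 / g, rel=0.05)
        tail = np.abs(np.diff(conc[-50:]))
        head = np.abs(np.diff(conc[:50]))
        assert tail.mean() < head.mean()  # converging, not drifting

    def test_external_source_dilutes_to_zero(self):
        mesh = build_root_grid(3, 6, [10.0] * 3, row_height=10.0)
        params = TransportParams(
            diffusion=6000.0, k_deg=3e-4, boundary_flux=1e4,
            k_prod_area=0.0, k_prod_cell=0.0, dt_chem=0.5,
        )
        g = 0.01
        conc = []
        for _ in range(400):
            self._grow(mesh, 1.0 + g)
            step_chemistry(mesh, params, None, dt=1.0, mode="EXTERNAL",
                           species=("auxin",))
            conc.append(total_amount(mesh, "auxin") / mesh.total_area())
        peak = max(conc)
        assert conc[-1] < 0.5 * peak          # risen then decaying
        assert conc[-1] < conc[-100]          # still heading down


class TestSteadyGradients:
    def _steady_profile(self, params, density=1.0):
        mesh = build_root_grid(6, 10, [12.0] * 6, row_height=12.0)
        layout = assign_pin_layout(mesh, "reverse_fountain", density)
        steady_state_amounts(mesh, params, layout, mode="MIXED")
        body = [c for c in mesh.cells.values() if c.role is Role.BODY]
        pos = np.array([mesh.axial_position(c) for c in body])
        conc = np.array([c.chem["auxin"] / mesh.area(c) for c in body])
        order = np.argsort(pos)
        return pos[order], conc[order]

    def test_transport_ratio_invariance(self):
        """Scaling every transport permeability 6-fold rescales the
        steady profile without changing its shape."""
        p1 = TransportParams(diffusion=1000.0, k_export=1200.0,
                             k_import=600.0, k_deg=3e-4, k_prod_area=1.0,
                             boundary_flux=1e6)
        p6 = TransportParams(diffusion=6000.0, k_export=7200.0,
                             k_import=3600.0, k_deg=3e-4, k_prod_area=1.0,
                             boundary_flux=1e6)
        _, c1 = self._steady_profile(p1)
        _, c6 = self._steady_profile(p6)
        n1 = c1 / c1.mean()
        n6 = c6 / c6.mean()
        assert np.max(np.abs(n1 - n6)) < 1e-3 * np.max(n1)

    def test_diffusion_flattens_gradient(self):
        base = dict(k_export=1200.0, k_import=600.0, k_deg=3e-4,
                    k_prod_area=1.0, boundary_flux=1e6)
        _, slow = self._steady_profile(TransportParams(diffusion=1000.0, **base))
        _, fast = self._steady_profile(TransportParams(diffusion=36000.0, **base))
        assert np.std(fast / fast.mean()) < np.std(slow / slow.mean())

    def test_sources_scale_profile_up(self):
        base = dict(diffusion=6000.0, k_export=1200.0, k_import=600.0,
                    k_deg=3e-4)
        _, lo = self._steady_profile(
            TransportParams(k_prod_area=0.5, boundary_flux=2e4, **base)
        )
        _, hi_prod = self._steady_profile(
            TransportParams(k_prod_area=12.5, boundary_flux=2e4, **base)
        )
        _, hi_flux = self._steady_profile(
            TransportParams(k_prod_area=0.5, boundary_flux=5e5, **base)
        )
        assert np.all(hi_prod >= lo - 1e-9)
        assert hi_prod.mean() > 2 * lo.mean()
        assert hi_flux.mean() > 2 * lo.mean()

    def test_stronger_pin_sharpens_apical_maximum(self):
        """In a polar-dominant regime, doubling all PIN densities at
        fixed diffusion steepens the auxin maximum near the tip."""
        params = TransportParams(diffusion=1000.0, k_export=7200.0,
                                 k_import=600.0, k_deg=3e-4,
                                 k_prod_area=1.0, boundary_flux=1e6)
        def tip_contrast(density):
            pos, conc = self._steady_profile(params, density=density)
            tip = conc[pos <= np.quantile(pos, 0.25)].mean()
            return tip / conc.mean()
        c_half, c_ref, c_double = map(tip_contrast, (0.5, 1.0, 2.0))
        assert c_half < c_ref < c_double


class TestPinLayoutAndNetwork:
    def test_apolar_scheme_carries_no_pin(self, small_grid):
        layout = assign_pin_layout(small_grid, "apolar")
        assert layout.export == {}
        assert small_grid.pin == {}

    def test_unknown_scheme_rejected(self, small_grid):
        with pytest.raises(ValueError):
            assign_pin_layout(small_grid, "fountain_of_youth")

    def test_reverse_fountain_polarity(self):
        mesh = build_root_grid(12, 8)
        layout = assign_pin_layout(mesh, "reverse_fountain")
        x_mid = np.mean([mesh.centroid(c)[0] for c in mesh.cells.values()])
        rootward, shootward, inward = 0, 0, 0
        for (a, b), dens in layout.export.items():
            ca, cb = mesh.cells[a], mesh.cells[b]
            if ca.role is not Role.BODY:
                continue
            (xa, ya), (xb, yb) = mesh.centroid(ca), mesh.centroid(cb)
            if ca.file_index in (3, 4, 5, 6, 7, 8):
                assert yb > ya     # inner files export toward the tip
                rootward += 1
            elif abs(yb - ya) >= abs(xb - xa):
                assert yb < ya     # outer files export shootward ...
                shootward += 1
            else:
                # ... and laterally inward, closing the reflux loop
                assert abs(xb - x_mid) < abs(xa - x_mid)
                inward += 1
        assert rootward > 0 and shootward > 0 and inward > 0

    def test_shy2_represses_pin(self, small_grid):
        params = TransportParams(pin_K=2.0, pin_hill=4.0)
        assert pin_repression_factor(0.0, params) == 1.0
        assert pin_repression_factor(2.0, params) == pytest.approx(0.5)
        assert pin_repression_factor(20.0, params) < 1e-3

    def test_zero_auxin_gives_maximal_cytokinin_production(self, small_grid):
        params = TransportParams(ck_prod_area=1.0, ck_K_aux=10.0)
        system = ChemSystem(small_grid)
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = 0.0
        s0 = system.ck_source(params)
        for cell in small_grid.cells.values():
            cell.chem["auxin"] = 10.0 * small_grid.area(cell)
        s_rep = ChemSystem(small_grid).ck_source(params)
        assert np.all(s0 >= 2 * s_rep - 1e-12)  # half-repression at K
        assert s0.sum() == pytest.approx(small_grid.total_area())

    def test_ga_dilution_halves_with_doubling_area(self, small_grid):
        cell = next(
            c for c in small_grid.cells.values() if c.role is Role.BODY
        )
        cell.zone = Zone.EZ           # no further GA production
        cell.chem["ga"] = 50.0
        conc0 = cell.chem["ga"] / small_grid.area(cell)
        for nid in set(cell.ring):
            node = small_grid.nodes[nid]
        # double the cell axially by stretching its rootward nodes
        ys = [small_grid.nodes[n].y for n in cell.ring]
        ymax = max(ys)
        h = ymax - min(ys)
        for nid in set(cell.ring):
            if small_grid.nodes[nid].y == ymax:
                small_grid.nodes[nid].y += h
        conc1 = cell.chem["ga"] / small_grid.area(cell)
        assert conc1 == pytest.approx(conc0 / 2)
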
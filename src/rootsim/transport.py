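"""Reaction-transport of auxin, cytokinin, SHY2 and GA on the cell grid.

Cells exchange chemicals across shared walls.  Walls are treated as thin
membranes of thickness ``d`` (no explicit apoplast compartment): the
a-polar conductance of a wall of interface length ``L_w`` is
``(D/d + k_import) * L_w`` -- diffusion plus symmetric AUX/LAX-type
import -- while PIN-mediated efflux adds the polar term
``k_export * L_w * (PIN_ab * c_a - PIN_ba * c_b)`` with per-side carrier
densities.  Concentrations are amounts divided by cell area.

Auxin can enter the tissue three ways (source modes): a strictly
external source (net influx through the shootward walls of the inner
files, with export through the outer epidermal walls), production
proportional to cell area, or a constant production per cell; modes can
be mixed.  First-order degradation is available in every mode.

The regulatory couplings of the hormone cross-talk network are:
cytokinin (diffusing in from the shootward boundary, locally produced
at a rate repressed by auxin) up-regulates the cell-local transcription
factor SHY2; auxin promotes SHY2 degradation; SHY2 above a threshold
represses the cell's PIN densities.  GA is produced in dividing cells
proportionally to their width at birth and is conserved afterwards, so
its concentration dilutes as cells elongate.

Numerics: within a simulation step the geometry is frozen and the
transport operator is linear in the amounts, so species are advanced by
backward-Euler sub-steps (sparse direct solves).  The implicit update is
unconditionally stable and non-negativity preserving, which matters
because the printed permeabilities make the system stiff on small
cells; it also conserves mass exactly in closed systems (the transport
matrix has zero column sums).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .core_mesh import Mesh, Role, Zone, OUTSIDE

MODES = ("EXTERNAL", "PROD_AREA", "PROD_CELL", "MIXED")


@dataclass
class TransportParams:
    # auxin transport (values from the reference polar-transport regime)
    diffusion: float = 6000.0         # D, µm²/min
    wall_thickness: float = 1.0       # d, µm
    k_export: float = 1200.0          # PIN efflux permeability, µm/min
    k_import: float = 600.0           # a-polar importer permeability, µm/min
    k_deg: float = 3e-4               # min^-1
    k_prod_area: float = 0.0          # AU µm^-2 min^-1
    k_prod_cell: float = 0.0          # AU min^-1 per cell
    k_prod_qc: float = 0.0            # AU min^-1 per columella/QC cell
    boundary_flux: float = 0.0        # F', AU min^-1 net influx, top row
    # cytokinin
    ck_diffusion: float = 1200.0      # µm²/min
    ck_source: float = 0.0            # AU min^-1 via the shootward boundary
    ck_prod_area: float = 0.0         # maximal production, AU µm^-2 min^-1
    ck_K_aux: float = 20.0            # AU; auxin level halving ck production
    ck_deg: float = 2e-3              # min^-1
    # SHY2 (cell-local)
    shy2_prod: float = 0.0            # maximal production, AU µm^-2 min^-1
    shy2_K_ck: float = 5.0            # AU cytokinin half-activation
    shy2_deg0: float = 2e-3           # min^-1 basal turnover
    shy2_deg_aux: float = 0.0         # min^-1 extra, auxin-saturable
    shy2_K_aux: float = 20.0          # AU
    pin_K: float = None               # SHY2 conc. half-repressing PIN
    pin_hill: float = 4.0
    # GA
    ga_prod_per_width: float = 0.0    # AU min^-1 per µm of birth width
    # integration
    dt_chem: float = 0.5              # min

    def __post_init__(self):
        if self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be positive")
        for name in ("diffusion", "k_export", "k_import", "k_deg",
                     "k_prod_area", "k_prod_cell", "ck_diffusion", "ck_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PinLayout:
    """Wall-face PIN polarity: base densities per directed cell pair."""

    scheme: str
    density: float = 1.0
    export: dict = field(default_factory=dict)   # (cell, neighbour) -> density

    def base(self, cell_a, cell_b):
        return self.export.get((cell_a, cell_b), 0.0)


def assign_pin_layout(mesh, scheme, density=1.0):
    """Attach a named PIN polarity scheme to the mesh.

    ``apolar`` carries no PIN at all.  ``reverse_fountain`` sends auxin
    rootward through the inner (vascular) files, laterally outward
    through the columella/QC block, and shootward through the outer
    (epidermal/border) files, reproducing the canonical root-tip
    circulation.
    """
    if scheme == "apolar":
        layout = PinLayout(scheme, density, {})
        mesh.pin = {}
        return layout
    if scheme != "reverse_fountain":
        raise ValueError(f"unknown PIN scheme {scheme!r}")
    files = [c.file_index for c in mesh.cells.values()]
    n_files = max(files) + 1
    n_out = max(1, n_files // 4)
    outer = set(range(n_out)) | set(range(n_files - n_out, n_files))
    xs = [mesh.centroid(c)[0] for c in mesh.cells.values()]
    x_mid = 0.5 * (min(xs) + max(xs))
    export = {}
    for wall in mesh.walls():
        if wall.cell_b == OUTSIDE:
            continue
        for a, b in ((wall.cell_a, wall.cell_b), (wall.cell_b, wall.cell_a)):
            ca, cb = mesh.cells[a], mesh.cells[b]
            ax, ay = mesh.centroid(ca)
            bx, by = mesh.centroid(cb)
            axial = abs(by - ay) >= abs(bx - ax)
            if ca.role is Role.COLUMELLA_QC:
                # cap: lateral outward redistribution; outer columns vent up
                if not axial and abs(bx - x_mid) > abs(ax - x_mid):
                    export[(a, b)] = density
                elif axial and by < ay and ca.file_index in outer:
                    export[(a, b)] = density
                continue
            if ca.file_index in outer:
                if axial and by < ay:          # shootward
                    export[(a, b)] = density
                elif not axial and abs(bx - x_mid) < abs(ax - x_mid):
                    # lateral inward return closes the reflux loop
                    export[(a, b)] = density
            else:
                if axial and by > ay:          # rootward (toward the tip)
                    export[(a, b)] = density
    layout = PinLayout(scheme, density, export)
    mesh.pin = dict(export)
    return layout


def pin_repression_factor(shy2_conc, params):
    """Smooth SHY2-dependent PIN down-regulation in (0, 1]."""
    if params.pin_K is None or shy2_conc <= 0:
        return 1.0
    return 1.0 / (1.0 + (shy2_conc / params.pin_K) ** params.pin_hill)


def effective_pin(mesh, layout, params, cell_a, cell_b):
    base = layout.base(cell_a, cell_b)
    if base == 0.0:
        return 0.0
    cell = mesh.cells[cell_a]
    area = mesh.area(cell)
    shy2 = cell.chem.get("shy2", 0.0) / area if area > 0 else 0.0
    return base * pin_repression_factor(shy2, params)


def wall_flux(mesh, cell_a, cell_b, wall, params, layout=None, species="auxin"):
    """Signed net flux a -> b across one wall (AU/min); antisymmetric."""
    ca, cb = mesh.cells[cell_a], mesh.cells[cell_b]
    aa, ab = mesh.area(ca), mesh.area(cb)
    qa, qb = ca.chem.get(species, 0.0), cb.chem.get(species, 0.0)
    if qa < 0 or qb < 0:
        raise ValueError("negative chemical amount")
    conc_a, conc_b = qa / aa, qb / ab
    L = wall.length
    if species == "auxin":
        d_coef, imp = params.diffusion, params.k_import
    else:
        d_coef, imp = params.ck_diffusion, 0.0
    flux = (d_coef / params.wall_thickness + imp) * L * (conc_a - conc_b)
    if layout is not None and species == "auxin":
        pab = effective_pin(mesh, layout, params, cell_a, cell_b)
        pba = effective_pin(mesh, layout, params, cell_b, cell_a)
        flux += params.k_export * L * (pab * conc_a - pba * conc_b)
    return flux


# --------------------------------------------------------- linear operator


class ChemSystem:
    """Frozen-geometry view used to assemble transport operators.

    ``d(amounts)/dt = M q + s`` with M sparse; the a-polar part is
    constant, the PIN part is reassembled when SHY2 changes.
    """

    def __init__(self, mesh):
        self.mesh = mesh
        self.ids = sorted(mesh.cells)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self.n = len(self.ids)
        self.areas = np.array([mesh.area(cid) for cid in self.ids])
        self.walls = [w for w in mesh.walls() if w.cell_b != OUTSIDE]
        files = [mesh.cells[c].file_index for c in self.ids]
        n_files = max(files) + 1
        self.epidermal = {0, n_files - 1}
        # shootward boundary cells: carry at least one all-fixed-node edge
        self.top_cells = [
            cid for cid in self.ids
            if any(mesh.nodes[a].fixed and mesh.nodes[b].fixed
                   for a, b in mesh.boundary_edges(cid))
        ]
        # outer epidermal boundary length per cell (lateral walls only)
        self.epi_boundary = {}
        for cid in self.ids:
            cell = mesh.cells[cid]
            if cell.file_index not in self.epidermal or cell.role is Role.COLUMELLA_QC:
                continue
            length = 0.0
            for a, b in mesh.boundary_edges(cid):
                na, nb = mesh.nodes[a], mesh.nodes[b]
                if abs(nb.y - na.y) > abs(nb.x - na.x):
                    length += mesh.edge_length(a, b)
            if length > 0:
                self.epi_boundary[cid] = length

    def amounts(self, species):
        return np.array(
            [self.mesh.cells[c].chem.get(species, 0.0) for c in self.ids]
        )

    def set_amounts(self, species, q):
        for cid, val in zip(self.ids, q):
            self.mesh.cells[cid].chem[species] = float(val)

    def apolar_matrix(self, params, species):
        if species == "auxin":
            perm = params.diffusion / params.wall_thickness + params.k_import
        else:
            perm = params.ck_diffusion / params.wall_thickness
        rows, cols, vals = [], [], []
        for w in self.walls:
            i, j = self.index[w.cell_a], self.index[w.cell_b]
            g = perm * w.length
            rows += [i, i, j, j]
            cols += [i, j, j, i]
            vals += [-g / self.areas[i], g / self.areas[j],
                     -g / self.areas[j], g / self.areas[i]]
        return sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )

    def pin_matrix(self, params, layout):
        if layout is None or not layout.export:
            return sp.csr_matrix((self.n, self.n))
        rows, cols, vals = [], [], []
        for w in self.walls:
            for a, b in ((w.cell_a, w.cell_b), (w.cell_b, w.cell_a)):
                p = effective_pin(self.mesh, layout, params, a, b)
                if p == 0.0:
                    continue
                i, j = self.index[a], self.index[b]
                g = params.k_export * w.length * p / self.areas[i]
                rows += [i, j]
                cols += [i, i]
                vals += [-g, g]
        return sp.csr_matrix(
            sp.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )

    def auxin_source_and_sinks(self, params, mode):
        """Constant source vector and diagonal sink rates for auxin."""
        s = np.zeros(self.n)
        sink = np.full(self.n, params.k_deg)
        if mode in ("EXTERNAL", "MIXED") and params.boundary_flux > 0:
            targets = [
                c for c in self.top_cells
                if self.mesh.cells[c].file_index not in self.epidermal
            ] or self.top_cells
            for cid in targets:
                s[self.index[cid]] += params.boundary_flux / len(targets)
        if mode in ("EXTERNAL", "MIXED"):
            for cid, length in self.epi_boundary.items():
                i = self.index[cid]
                sink[i] += params.k_export * length / self.areas[i]
        if mode in ("PROD_AREA", "MIXED"):
            s += params.k_prod_area * self.areas
        if mode == "PROD_CELL":
            s += params.k_prod_cell
        if params.k_prod_qc > 0:
            # cap/QC auxin reservoir: tip-anchored source in every mode
            for cid in self.ids:
                if self.mesh.cells[cid].role is Role.COLUMELLA_QC:
                    s[self.index[cid]] += params.k_prod_qc
        return s, sink

    def ck_source(self, params):
        s = np.zeros(self.n)
        if params.ck_source > 0 and self.top_cells:
            for cid in self.top_cells:
                s[self.index[cid]] += params.ck_source / len(self.top_cells)
        if params.ck_prod_area > 0:
            aux = self.amounts("auxin") / self.areas
            s += (
                params.ck_prod_area * self.areas
                / (1.0 + aux / params.ck_K_aux)
            )
        return s


def _backward_euler(M, q, s, h):
    n = M.shape[0]
    A = sp.identity(n, format="csc") - h * M.tocsc()
    return spla.spsolve(A, q + h * s)


def apply_sources_and_sinks(mesh, params, mode, dt, system=None):
    """Advance auxin sources and first-order degradation only (no
    transport), one backward-Euler step; used standalone in tests and as
    part of :func:`step_chemistry`."""
    if mode not in MODES:
        raise ValueError(f"unknown source mode {mode!r}")
    system = system or ChemSystem(mesh)
    s, sink = system.auxin_source_and_sinks(params, mode)
    q = system.amounts("auxin")
    q = (q + dt * s) / (1.0 + dt * sink)
    system.set_amounts("auxin", q)
    return mesh


def step_chemistry(mesh, params, layout=None, dt=30.0, mode="MIXED",
                   species=("auxin",)):
    """Advance all active species by ``dt`` minutes in implicit
    sub-steps of at most ``params.dt_chem``.

    Auxin: wall fluxes + sources + degradation.  Cytokinin: diffusion
    with auxin-repressed production and a shootward-boundary source.
    SHY2: cell-local production (cytokinin-saturable) and degradation
    (basal + auxin-saturable), solved exactly per sub-step.  GA:
    produced in STEM/DZ cells proportionally to birth width, conserved
    elsewhere.  PIN densities are re-evaluated from SHY2 every sub-step.
    """
    if mode not in MODES:
        raise ValueError(f"unknown source mode {mode!r}")
    system = ChemSystem(mesh)
    n_sub = max(1, int(np.ceil(dt / params.dt_chem)))
    h = dt / n_sub
    apolar_aux = system.apolar_matrix(params, "auxin") if "auxin" in species else None
    apolar_ck = (
        system.apolar_matrix(params, "cytokinin")
        if "cytokinin" in species else None
    )
    pin_static = params.pin_K is None
    pin_M = system.pin_matrix(params, layout) if "auxin" in species else None
    aux_solver = ck_solver = None
    s_aux, sink_aux = system.auxin_source_and_sinks(params, mode)

    for _ in range(n_sub):
        if "auxin" in species:
            if not pin_static or aux_solver is None:
                if not pin_static:
                    pin_M = system.pin_matrix(params, layout)
                M = (apolar_aux + pin_M - sp.diags(sink_aux)).tocsc()
                aux_solver = spla.splu(sp.identity(system.n, format="csc") - h * M)
            q = system.amounts("auxin")
            q = aux_solver.solve(q + h * s_aux)
            _check_state(q, "auxin")
            system.set_amounts("auxin", q)
        if "cytokinin" in species:
            s_ck = system.ck_source(params)
            if ck_solver is None:
                M = (apolar_ck - sp.diags(np.full(system.n, params.ck_deg))).tocsc()
                ck_solver = spla.splu(sp.identity(system.n, format="csc") - h * M)
            q = ck_solver.solve(system.amounts("cytokinin") + h * s_ck)
            _check_state(q, "cytokinin")
            system.set_amounts("cytokinin", q)
        if "shy2" in species:
            _step_shy2(mesh, system, params, h)
        if "ga" in species:
            _step_ga(mesh, params, h)
    return mesh


def _check_state(q, species):
    if not np.all(np.isfinite(q)) or np.any(q < -1e-9):
        raise FloatingPointError(
            f"{species} state became invalid "
            f"(min {q.min():.3g}, max {q.max():.3g})"
        )


def _step_shy2(mesh, system, params, h):
    for cid in system.ids:
        cell = mesh.cells[cid]
        area = system.areas[system.index[cid]]
        ck = cell.chem.get("cytokinin", 0.0) / area
        aux = cell.chem.get("auxin", 0.0) / area
        prod = params.shy2_prod * area * ck / (params.shy2_K_ck + ck) if ck > 0 else 0.0
        deg = params.shy2_deg0
        if params.shy2_deg_aux > 0 and aux > 0:
            deg += params.shy2_deg_aux * aux / (params.shy2_K_aux + aux)
        s = cell.chem.get("shy2", 0.0)
        if deg > 0:
            f = np.exp(-deg * h)
            s = s * f + prod / deg * (1.0 - f)
        else:
            s = s + prod * h
        cell.chem["shy2"] = float(s)


def _step_ga(mesh, params, h):
    if params.ga_prod_per_width <= 0:
        return
    for cell in mesh.cells.values():
        if cell.role is Role.COLUMELLA_QC:
            continue
        if cell.zone in (Zone.STEM, Zone.DZ):
            cell.chem["ga"] = (
                cell.chem.get("ga", 0.0)
                + params.ga_prod_per_width * cell.initial_width * h
            )


def steady_state_amounts(mesh, params, layout=None, mode="MIXED",
                         species="auxin"):
    """Direct steady-state solve ``M q = -s`` on a static mesh.

    Requires a sink (degradation or boundary export) so the operator is
    invertible; raises otherwise.
    """
    system = ChemSystem(mesh)
    if species == "auxin":
        M = system.apolar_matrix(params, "auxin") + system.pin_matrix(params, layout)
        s, sink = system.auxin_source_and_sinks(params, mode)
    else:
        M = system.apolar_matrix(params, "cytokinin")
        s = system.ck_source(params)
        sink = np.full(system.n, params.ck_deg)
    if np.all(sink <= 0):
        raise ValueError("steady state undefined without any sink")
    A = (M - sp.diags(sink)).tocsc()
    q = spla.spsolve(A, -s)
    system.set_amounts(species, q)
    return q, system.ids


def total_amount(mesh, species):
    return sum(c.chem.get(species, 0.0) for c in mesh.cells.values())
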
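"""Tissue mechanics: generalized energy and Metropolis relaxation.

Each cell resists deviation of its polygon area ``A`` from its target
area ``A_T``; each wall segment acts as a linear spring around its rest
length ``L_T``.  Two area-term variants are provided:

* ``EQ1``  (absolute):    lambda_A * sum_i (A_i - A_T,i)**2
* ``EQ2``  (normalized):  lambda_A * sum_i ((A_i - A_T,i)/A_T,i)**2

The normalized form makes cells with equal *relative* growth deficits
contribute equally regardless of size, which keeps small meristematic
cells and large elongating cells on an equal mechanical footing.  A
second normalization, ``(A - A_T)**2 / A_T``, is available as
``EQ2_ALT`` behind the same switch.

Vertically oriented walls (those aligned with the growth axis) enter the
spring term scaled down, which lets cells elongate axially while their
width stays constrained -- the 2-D stand-in for strongly anisotropic
wall extensibility.

Relaxation uses Metropolis Monte Carlo node displacement: moves that
lower the energy are always accepted, uphill moves with Boltzmann
probability ``exp(-dH / temperature)``.  Fixed nodes are never trialled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_mesh import Mesh, Role, Zone, polygon_signed_area, _ekey

VARIANTS = ("EQ1", "EQ2", "EQ2_ALT")


@dataclass
class MechParams:
    lambda_area: float = 50.0     # area stiffness
    lambda_spring: float = 1.0    # wall spring constant (energy / µm²)
    vertical_scale: float = 0.2   # spring scale for growth-axis walls
    temperature: float = 0.1      # Boltzmann acceptance scale
    step_size: float = 1.0        # max trial displacement per axis (µm)
    sweeps_per_step: int = 8
    variant: str = "EQ2"

    def __post_init__(self):
        if self.lambda_area < 0 or self.lambda_spring < 0:
            raise ValueError("stiffness parameters must be non-negative")
        if self.temperature <= 0 or self.step_size <= 0:
            raise ValueError("temperature and step_size must be positive")
        if not 0 < self.vertical_scale <= 1:
            raise ValueError("vertical_scale must lie in (0, 1]")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown energy variant {self.variant!r}")


def area_energy(area, target, lambda_area, variant):
    d = area - target
    if variant == "EQ1":
        return lambda_area * d * d
    if target <= 0:
        raise ValueError("EQ2 variants need target_area > 0")
    if variant == "EQ2":
        r = d / target
        return lambda_area * r * r
    return lambda_area * d * d / target  # EQ2_ALT


def edge_scale(mesh, a, b, vertical_scale):
    na, nb = mesh.nodes[a], mesh.nodes[b]
    return vertical_scale if abs(nb.y - na.y) >= abs(nb.x - na.x) else 1.0


def energy(mesh, params, variant=None):
    """Total energy of the mesh under the given parameters."""
    variant = variant or params.variant
    e = 0.0
    for cell in mesh.cells.values():
        e += area_energy(mesh.area(cell), cell.target_area,
                         params.lambda_area, variant)
    for (a, b), rest in mesh.rest_length.items():
        s = edge_scale(mesh, a, b, params.vertical_scale)
        d = mesh.edge_length(a, b) - rest
        e += params.lambda_spring * s * d * d
    return e


def accept_move(d_h, temperature, rng):
    """Metropolis acceptance: downhill and ties always, uphill with
    probability exp(-dH / T)."""
    if d_h <= 0:
        return True
    return rng.random() < math.exp(-d_h / temperature)


def _local_energy(mesh, params, node_id, cells, edges, variant):
    e = 0.0
    for cid in cells:
        cell = mesh.cells[cid]
        xy = mesh.ring_xy(cell)
        e += area_energy(abs(polygon_signed_area(xy)), cell.target_area,
                         params.lambda_area, variant)
    for a, b in edges:
        s = edge_scale(mesh, a, b, params.vertical_scale)
        d = mesh.edge_length(a, b) - mesh.rest_length[_ekey(a, b)]
        e += params.lambda_spring * s * d * d
    return e


def _segments_cross(p1, p2, p3, p4):
    d1 = (p4[0] - p3[0]) * (p1[1] - p3[1]) - (p4[1] - p3[1]) * (p1[0] - p3[0])
    d2 = (p4[0] - p3[0]) * (p2[1] - p3[1]) - (p4[1] - p3[1]) * (p2[0] - p3[0])
    d3 = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    d4 = (p2[0] - p1[0]) * (p4[1] - p1[1]) - (p2[1] - p1[1]) * (p4[0] - p1[0])
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def _ring_is_simple(xy):
    """O(n²) non-adjacent segment crossing test; rings are short."""
    n = len(xy)
    for i in range(n):
        a1, a2 = xy[i], xy[(i + 1) % n]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_cross(a1, a2, xy[j], xy[(j + 1) % n]):
                return False
    return True


def _move_is_legal(mesh, cells):
    """A node move must keep every incident cell positively oriented
    and free of self-intersections (symplastic tissue cannot fold)."""
    for cid in cells:
        xy = mesh.ring_xy(mesh.cells[cid])
        if polygon_signed_area(xy) <= 0:
            return False
        if not _ring_is_simple(xy):
            return False
    return True


def _incident_edges(mesh, node_id, cells):
    edges = set()
    for cid in cells:
        ring = mesh.cells[cid].ring
        n = len(ring)
        i = ring.index(node_id)
        edges.add(_ekey(ring[i - 1], node_id))
        edges.add(_ekey(node_id, ring[(i + 1) % n]))
    return edges


def metropolis_trial(mesh, params, node_id, displacement, rng, variant=None):
    """Trial one node displacement; mutate the mesh if accepted.

    Returns True when the move was accepted.  Fixed nodes are rejected
    outright (they are never trialled by :func:`equilibrate`).
    """
    node = mesh.nodes[node_id]
    if node.fixed:
        return False
    variant = variant or params.variant
    cells = mesh.node_cells.get(node_id, ())
    edges = _incident_edges(mesh, node_id, cells)
    before = _local_energy(mesh, params, node_id, cells, edges, variant)
    old = (node.x, node.y)
    node.x += displacement[0]
    node.y += displacement[1]
    if not _move_is_legal(mesh, cells):
        node.x, node.y = old
        return False
    after = _local_energy(mesh, params, node_id, cells, edges, variant)
    if accept_move(after - before, params.temperature, rng):
        return True
    node.x, node.y = old
    return False


def active_nodes(mesh):
    """Non-fixed nodes bordering at least one still-growing cell.

    Mature and columella/QC tissue is treated as rigid: its target
    areas are frozen and differentiated walls no longer yield, so its
    interior nodes are excluded from Metropolis trials (which also
    prevents frozen cells from slowly random-walking into degenerate
    shapes).  Boundary nodes shared with growing cells stay active.
    """
    active = set()
    for cell in mesh.cells.values():
        if cell.role is Role.BODY and cell.zone is not Zone.MZ:
            active.update(cell.ring)
    return [nid for nid in active if not mesh.nodes[nid].fixed]


def equilibrate(mesh, params, rng, sweeps=None, variant=None):
    """Run full Metropolis sweeps (every active node trialled once per
    sweep, in random order); returns sweep statistics."""
    variant = variant or params.variant
    sweeps = params.sweeps_per_step if sweeps is None else sweeps
    free = sorted(active_nodes(mesh))
    e0 = energy(mesh, params, variant)
    accepted = 0
    trials = 0
    step = params.step_size
    for _ in range(sweeps):
        order = rng.permutation(len(free))
        disps = rng.uniform(-step, step, size=(len(free), 2))
        for k in order:
            trials += 1
            if metropolis_trial(mesh, params, free[k], disps[k], rng, variant):
                accepted += 1
    e1 = energy(mesh, params, variant)
    return {
        "energy_before": e0,
        "energy_after": e1,
        "acceptance": accepted / trials if trials else 0.0,
        "sweeps": sweeps,
    }


def _ring_simple_np(xy):
    """Vectorized simplicity test for one ring (all non-adjacent pairs)."""
    n = len(xy)
    if n < 4:
        return True
    a = xy
    b = np.roll(xy, -1, axis=0)
    i, j = np.triu_indices(n, k=2)
    keep = ~((i == 0) & (j == n - 1))
    i, j = i[keep], j[keep]
    p1, p2 = a[i], b[i]
    p3, p4 = a[j], b[j]
    d34 = p4 - p3
    d12 = p2 - p1
    d1 = d34[:, 0] * (p1[:, 1] - p3[:, 1]) - d34[:, 1] * (p1[:, 0] - p3[:, 0])
    d2 = d34[:, 0] * (p2[:, 1] - p3[:, 1]) - d34[:, 1] * (p2[:, 0] - p3[:, 0])
    d3 = d12[:, 0] * (p3[:, 1] - p1[:, 1]) - d12[:, 1] * (p3[:, 0] - p1[:, 0])
    d4 = d12[:, 0] * (p4[:, 1] - p1[:, 1]) - d12[:, 1] * (p4[:, 0] - p1[:, 0])
    return not np.any((d1 * d2 < 0) & (d3 * d4 < 0))


def _all_rings_valid(mesh):
    for cell in mesh.cells.values():
        xy = mesh.ring_xy(cell)
        if polygon_signed_area(xy) <= 0 or not _ring_simple_np(xy):
            return False
    return True


def growth_advection(mesh):
    """Deterministic predictor applied before Metropolis relaxation.

    Cells whose target area exceeds their actual area want to elongate
    axially; in a symplastically growing column every point is carried
    shootward/rootward by the integrated elongation of the tissue above
    it.  This translates each free node along the growth axis by the
    cumulative expected relative elongation between the fixed top row
    and the node, leaving the Monte Carlo stage only local corrections
    to resolve.  Without it, tip displacement per step would be limited
    by ``sweeps * step_size`` regardless of the growth the rules demand.
    """
    ys = np.array([n.y for n in mesh.nodes.values()])
    y_top, y_bot = float(ys.min()), float(ys.max())
    if y_bot <= y_top:
        return
    n_bins = 200
    grid = np.linspace(y_top, y_bot, n_bins + 1)
    want = np.zeros(n_bins)
    weight = np.zeros(n_bins)
    for cell in mesh.cells.values():
        a = mesh.area(cell)
        if a <= 0:
            continue
        g = max(0.0, (cell.target_area - a) / a)
        cy = mesh.ring_xy(cell)[:, 1]
        lo = np.searchsorted(grid, float(cy.min()), side="left")
        hi = np.searchsorted(grid, float(cy.max()), side="right")
        lo = max(0, min(lo, n_bins - 1))
        hi = max(lo + 1, min(hi, n_bins))
        want[lo:hi] += g
        weight[lo:hi] += 1.0
    rate = np.where(weight > 0, want / np.maximum(weight, 1), 0.0)
    dy_bin = rate * np.diff(grid)
    cum = np.concatenate([[0.0], np.cumsum(dy_bin)])
    moved = {
        nid: float(np.interp(node.y, grid, cum))
        for nid, node in mesh.nodes.items() if not node.fixed
    }
    # the y-map is monotone but not affine, so slanted walls can tangle;
    # bisect the advection factor until every ring stays simple
    for factor in (1.0, 0.5, 0.25, 0.0):
        for nid, dy in moved.items():
            mesh.nodes[nid].y += factor * dy
        if factor == 0.0 or _all_rings_valid(mesh):
            return
        for nid, dy in moved.items():
            mesh.nodes[nid].y -= factor * dy


def relax(mesh, params, rng, sweeps=None, advect=True):
    """One mechanical update: growth advection predictor + Metropolis
    sweeps, followed by plastic reset of wall rest lengths.

    Resetting ``L_T`` to the realized lengths after each step makes the
    walls yield plastically between steps, so spring energy cannot
    accumulate without bound as cells elongate.
    """
    if advect:
        growth_advection(mesh)
    stats = equilibrate(mesh, params, rng, sweeps=sweeps)
    for key in list(mesh.rest_length):
        mesh.rest_length[key] = mesh.edge_length(*key)
    return stats
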
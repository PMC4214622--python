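"""Polygonal cell-grid representation of a growing root tip.

The simulated tissue is a two-dimensional axial bisection of a root apex:
nodes (vertices) connected by edges form polygonal cells, and adjacent
cells share wall segments.  Growth is symplastic -- neighbouring cells
never slide past each other, so all topology changes go through cell
division surgery that keeps shared walls consistent on both sides.

Coordinate convention: the growth axis is ``y``, increasing rootward
(the tip sits at the largest ``y``).  The top cell row is anchored by
fixed nodes at the smallest ``y``; the three bottom rows represent the
columella/quiescent-centre (QC) complex and never grow or divide.
Axial positions are measured from the shootward face of the QC block,
positive shootward.  Units: µm, µm², minutes; chemical amounts in
arbitrary units (AU·µm², so that concentration = amount / area is AU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum

import numpy as np
import pandas as pd
from lxml import etree
from shapely.geometry import Polygon, box

OUTSIDE = -1

#: chemical species known to the serializer (cells may carry any subset)
SPECIES = ("auxin", "cytokinin", "shy2", "ga")


class MeshError(ValueError):
    """Invalid mesh state or operation."""


class MeshFormatError(MeshError):
    """Malformed serialized mesh."""


class DegenerationError(MeshError):
    """The mesh has degenerated (self-intersection or collapsed cell).

    For models that violate the uniform-strain requirement this is a
    scientific outcome, not a bug; callers may attach the trajectory
    computed so far as ``.trajectory``.
    """

    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory


class Zone(IntEnum):
    """Developmental zone; the order encodes the one-way progression."""

    STEM = 0   # in contact with the QC block, self-renewing
    DZ = 1     # division (meristematic) zone
    EZ = 2     # elongation zone
    MZ = 3     # mature zone


class Role(str, Enum):
    BODY = "BODY"
    COLUMELLA_QC = "COLUMELLA_QC"


@dataclass
class Node:
    id: int
    x: float
    y: float
    fixed: bool = False


@dataclass(frozen=True)
class Edge:
    """Read-only view of one wall segment (spring)."""

    a: int
    b: int
    length: float
    rest_length: float
    vertical: bool

    @property
    def id(self):
        return (self.a, self.b)


@dataclass
class Cell:
    id: int
    ring: list            # ordered node ids, positively oriented
    target_area: float
    chem: dict = field(default_factory=dict)   # species -> amount (AU·µm²)
    t_release: float = 0.0        # min since loss of QC contact
    t_since_division: float = 0.0
    division_count: int = 0
    zone: Zone = Zone.DZ
    file_index: int = 0
    role: Role = Role.BODY
    initial_width: float = 0.0    # µm, frozen at birth
    noise_mult: float = 0.0       # fractional timer/sizer noise for this cycle


@dataclass(frozen=True)
class CellWall:
    """Interface between two cells (or a cell and the outside)."""

    id: int
    cell_a: int
    cell_b: int               # OUTSIDE for boundary walls
    edges: tuple              # sorted node-pair tuples
    length: float
    pin_ab: float = 0.0       # PIN density on the a side (export a -> b)
    pin_ba: float = 0.0


def polygon_signed_area(xy):
    """Shoelace signed area of a closed ring given as an (n, 2) array."""
    x = xy[:, 0]
    y = xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def polygon_centroid(xy):
    x = xy[:, 0]
    y = xy[:, 1]
    xr = np.roll(x, -1)
    yr = np.roll(y, -1)
    cross = x * yr - xr * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12:
        return float(np.mean(x)), float(np.mean(y))
    cx = float(np.sum((x + xr) * cross) / (6.0 * a))
    cy = float(np.sum((y + yr) * cross) / (6.0 * a))
    return cx, cy


class Mesh:
    """Node/cell/wall collections making up the simulated tissue state."""

    def __init__(self):
        self.nodes = {}          # id -> Node
        self.cells = {}          # id -> Cell
        self.rest_length = {}    # sorted (a, b) -> target length L_T
        self.pin = {}            # (cell_id, neighbour_id | OUTSIDE) -> density
        self.time = 0.0          # min
        self._next_node = 0
        self._next_cell = 0
        self._node_cells = None  # cache: node id -> set of cell ids
        self._edge_cells = None  # cache: sorted pair -> list of cell ids

    # ---------------------------------------------------------------- caches

    def invalidate(self):
        self._node_cells = None
        self._edge_cells = None

    @property
    def node_cells(self):
        if self._node_cells is None:
            m = {nid: set() for nid in self.nodes}
            for cid, cell in self.cells.items():
                for nid in cell.ring:
                    m[nid].add(cid)
            self._node_cells = m
        return self._node_cells

    @property
    def edge_cells(self):
        if self._edge_cells is None:
            m = {}
            for cid, cell in self.cells.items():
                ring = cell.ring
                n = len(ring)
                for i in range(n):
                    key = _ekey(ring[i], ring[(i + 1) % n])
                    m.setdefault(key, []).append(cid)
            self._edge_cells = m
        return self._edge_cells

    # ------------------------------------------------------------- geometry

    def ring_xy(self, cell):
        if isinstance(cell, int):
            cell = self.cells[cell]
        return np.array([(self.nodes[i].x, self.nodes[i].y) for i in cell.ring])

    def area(self, cell):
        a = polygon_signed_area(self.ring_xy(cell))
        return abs(a)

    def centroid(self, cell):
        return polygon_centroid(self.ring_xy(cell))

    def edge_length(self, a, b):
        na, nb = self.nodes[a], self.nodes[b]
        return math.hypot(na.x - nb.x, na.y - nb.y)

    def edges(self):
        """Iterate unique :class:`Edge` views (each wall segment once)."""
        for (a, b), rest in self.rest_length.items():
            na, nb = self.nodes[a], self.nodes[b]
            dx, dy = nb.x - na.x, nb.y - na.y
            yield Edge(a, b, math.hypot(dx, dy), rest, abs(dy) >= abs(dx))

    def total_area(self):
        return sum(self.area(c) for c in self.cells.values())

    def qc_face_y(self):
        """y coordinate of the shootward face of the QC block."""
        ys = [
            self.nodes[n].y
            for c in self.cells.values()
            if c.role is Role.COLUMELLA_QC
            for n in c.ring
        ]
        if not ys:
            raise MeshError("mesh has no COLUMELLA_QC cells")
        return min(ys)

    def axial_position(self, target):
        """Axial distance from the QC face, positive shootward (µm).

        ``target`` is a cell, a cell id, or an ``(x, y)`` point; cells
        are located by their centroid.
        """
        face = self.qc_face_y()
        if isinstance(target, (Cell, int)):
            _, cy = self.centroid(target)
            return face - cy
        return face - float(target[1])

    def axial_span(self, cell):
        """(pos_min, pos_max) of a cell along the growth axis."""
        face = self.qc_face_y()
        ys = self.ring_xy(cell)[:, 1]
        return face - float(ys.max()), face - float(ys.min())

    def cell_length(self, cell):
        ys = self.ring_xy(cell)[:, 1]
        return float(ys.max() - ys.min())

    # ------------------------------------------------------------- topology

    def neighbours(self, cell_id):
        out = set()
        cell = self.cells[cell_id]
        ring = cell.ring
        n = len(ring)
        for i in range(n):
            for cid in self.edge_cells.get(_ekey(ring[i], ring[(i + 1) % n]), ()):
                if cid != cell_id:
                    out.add(cid)
        return out

    def walls(self):
        """Build :class:`CellWall` views for all interfaces.

        Interior walls join the two cells sharing the edge list; boundary
        edges of each cell are grouped into a single OUTSIDE wall.
        PIN densities are looked up from :attr:`pin`.
        """
        pairs = {}
        for key, cids in self.edge_cells.items():
            if len(cids) == 2:
                pk = tuple(sorted(cids))
            elif len(cids) == 1:
                pk = (cids[0], OUTSIDE)
            else:  # pragma: no cover - would indicate broken topology
                raise MeshError(f"edge {key} shared by {len(cids)} cells")
            pairs.setdefault(pk, []).append(key)
        out = []
        for wid, ((ca, cb), ekeys) in enumerate(sorted(pairs.items())):
            length = sum(self.edge_length(*k) for k in ekeys)
            out.append(
                CellWall(
                    wid, ca, cb, tuple(sorted(ekeys)), length,
                    pin_ab=self.pin.get((ca, cb), 0.0),
                    pin_ba=self.pin.get((cb, ca), 0.0),
                )
            )
        return out

    def boundary_edges(self, cell_id):
        """Edges of a cell not shared with any other cell."""
        cell = self.cells[cell_id]
        ring = cell.ring
        n = len(ring)
        return [
            _ekey(ring[i], ring[(i + 1) % n])
            for i in range(n)
            if len(self.edge_cells[_ekey(ring[i], ring[(i + 1) % n])]) == 1
        ]

    def qc_contact_cells(self):
        """Body cells sharing at least one wall edge with the QC block."""
        out = set()
        for cid, cell in self.cells.items():
            if cell.role is not Role.COLUMELLA_QC:
                continue
            for nb in self.neighbours(cid):
                if self.cells[nb].role is Role.BODY:
                    out.add(nb)
        return out

    def check_planarity(self):
        """Raise :class:`DegenerationError` on self-intersecting or
        collapsed cell polygons."""
        for cid, cell in self.cells.items():
            xy = self.ring_xy(cell)
            if len(xy) < 3:
                raise DegenerationError(f"cell {cid} has fewer than 3 nodes")
            poly = Polygon(xy)
            if not poly.is_valid or poly.area < 1.0:
                raise DegenerationError(
                    f"cell {cid} degenerated (area {poly.area:.3g} µm²)"
                )

    # ----------------------------------------------------------------- misc

    def new_node(self, x, y, fixed=False):
        nid = self._next_node
        self._next_node += 1
        self.nodes[nid] = Node(nid, float(x), float(y), fixed)
        return nid

    def new_cell(self, **kw):
        cid = self._next_cell
        self._next_cell += 1
        cell = Cell(id=cid, **kw)
        self.cells[cid] = cell
        return cell

    def copy(self):
        import copy as _copy

        m = Mesh()
        m.nodes = {i: replace(n) for i, n in self.nodes.items()}
        m.cells = {
            i: replace(c, ring=list(c.ring), chem=dict(c.chem))
            for i, c in self.cells.items()
        }
        m.rest_length = dict(self.rest_length)
        m.pin = dict(self.pin)
        m.time = self.time
        m._next_node = self._next_node
        m._next_cell = self._next_cell
        return m


def _ekey(a, b):
    return (a, b) if a < b else (b, a)


# ------------------------------------------------------------------ builder


def standard_column_widths(n_columns, outer=15.0, inner=7.5):
    """Column widths with the inner half of the files narrower, as in
    root anatomy (wide epidermal/cortex files flanking narrow stele files)."""
    n_out = max(1, n_columns // 4)
    widths = [outer] * n_columns
    for i in range(n_out, n_columns - n_out):
        widths[i] = inner
    return widths


def build_root_grid(n_columns, n_rows, column_widths=None, row_height=15.0):
    """Construct the rectangular starter grid.

    The top cell row is anchored with fixed nodes; the bottom three rows
    are flagged ``COLUMELLA_QC`` with frozen target areas.  Target areas
    are initialized to the actual areas, file indices to the column.
    """
    if n_columns < 2 or n_rows < 4:
        raise MeshError("grid needs at least 2 columns and 4 rows")
    if row_height <= 0:
        raise MeshError("row_height must be positive")
    if column_widths is None:
        column_widths = standard_column_widths(n_columns)
    if np.isscalar(column_widths):
        column_widths = [float(column_widths)] * n_columns
    column_widths = [float(w) for w in column_widths]
    if len(column_widths) != n_columns:
        raise MeshError("column_widths length must equal n_columns")
    if min(column_widths) <= 0:
        raise MeshError("column widths must be positive")

    mesh = Mesh()
    xs = np.concatenate([[0.0], np.cumsum(column_widths)])
    node_id = {}
    for r in range(n_rows + 1):
        for c in range(n_columns + 1):
            node_id[(r, c)] = mesh.new_node(xs[c], r * row_height, fixed=(r == 0))
    for r in range(n_rows):
        qc = r >= n_rows - 3
        for c in range(n_columns):
            ring = [
                node_id[(r, c)],
                node_id[(r, c + 1)],
                node_id[(r + 1, c + 1)],
                node_id[(r + 1, c)],
            ]
            area = column_widths[c] * row_height
            mesh.new_cell(
                ring=ring,
                target_area=area,
                file_index=c,
                role=Role.COLUMELLA_QC if qc else Role.BODY,
                zone=Zone.DZ,
                initial_width=column_widths[c],
            )
    # positive orientation
    for cell in mesh.cells.values():
        if polygon_signed_area(mesh.ring_xy(cell)) < 0:
            cell.ring.reverse()
    # rest lengths at the current geometry
    for cid, cell in mesh.cells.items():
        ring = cell.ring
        for i in range(len(ring)):
            key = _ekey(ring[i], ring[(i + 1) % len(ring)])
            mesh.rest_length[key] = mesh.edge_length(*key)
    mesh.invalidate()
    return mesh


def build_developed_grid(n_columns, column_widths=None, body_length=240.0,
                         row_height_range=(12.0, 24.0), qc_row_height=15.0,
                         rng=None):
    """Starter grid emulating an already-developed young meristem.

    Spatially regulated models are meant to start from a root that has
    been growing for a while, in which cells at the same axial position
    sit at independent phases of their division cycle.  Each file is
    subdivided into rows of independent random heights drawn from
    ``row_height_range`` (uniform over one sizer doubling by default),
    giving a brick-wall pattern: lateral walls carry the union of both
    neighbouring files' row boundaries.  Three regular columella/QC rows
    close the grid at the rootward end; the shootward nodes are fixed.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if column_widths is None:
        column_widths = standard_column_widths(n_columns)
    if np.isscalar(column_widths):
        column_widths = [float(column_widths)] * n_columns
    if len(column_widths) != n_columns:
        raise MeshError("column_widths length must equal n_columns")
    h_lo, h_hi = row_height_range
    if not 0 < h_lo <= h_hi or body_length < h_hi:
        raise MeshError("invalid row height range or body length")
    xs = np.concatenate([[0.0], np.cumsum(column_widths)])
    qc_breaks = [body_length + k * qc_row_height for k in range(4)]

    file_breaks = []
    for _ in range(n_columns):
        breaks = [0.0]
        while body_length - breaks[-1] > h_hi:
            breaks.append(breaks[-1] + float(rng.uniform(h_lo, h_hi)))
        scale = body_length / breaks[-1] if len(breaks) > 1 else 1.0
        breaks = [b * scale for b in breaks[:-1]] + [body_length]
        file_breaks.append(breaks)

    mesh = Mesh()
    wall_nodes = []  # per wall: sorted {y: node id}
    for w in range(n_columns + 1):
        ys = set(qc_breaks)
        for f in (w - 1, w):
            if 0 <= f < n_columns:
                ys.update(file_breaks[f])
        nodes = {}
        for y in sorted(ys):
            nodes[round(y, 9)] = mesh.new_node(xs[w], y, fixed=(y == 0.0))
        wall_nodes.append(nodes)

    def ring_for(f, y_top, y_bot):
        left, right = wall_nodes[f], wall_nodes[f + 1]
        kt, kb = round(y_top, 9), round(y_bot, 9)
        mid_r = [right[k] for k in sorted(right) if kt < k < kb]
        mid_l = [left[k] for k in sorted(left, reverse=True) if kt < k < kb]
        return [left[kt], right[kt]] + mid_r + [right[kb], left[kb]] + mid_l

    for f in range(n_columns):
        breaks = file_breaks[f]
        for i in range(len(breaks) - 1):
            ring = ring_for(f, breaks[i], breaks[i + 1])
            mesh.new_cell(ring=ring, target_area=1.0, file_index=f,
                          role=Role.BODY, zone=Zone.DZ,
                          initial_width=column_widths[f])
        for i in range(3):
            ring = ring_for(f, qc_breaks[i], qc_breaks[i + 1])
            mesh.new_cell(ring=ring, target_area=1.0, file_index=f,
                          role=Role.COLUMELLA_QC, zone=Zone.DZ,
                          initial_width=column_widths[f])
    for cell in mesh.cells.values():
        if polygon_signed_area(mesh.ring_xy(cell)) < 0:
            cell.ring.reverse()
        cell.target_area = mesh.area(cell)
    for cell in mesh.cells.values():
        ring = cell.ring
        for i in range(len(ring)):
            key = _ekey(ring[i], ring[(i + 1) % len(ring)])
            mesh.rest_length[key] = mesh.edge_length(*key)
    mesh.invalidate()
    return mesh


def cell_area(mesh, cell):
    """Polygon area of a cell (µm²), orientation independent."""
    if isinstance(cell, int):
        cell = mesh.cells[cell]
    if len(cell.ring) < 3:
        raise MeshError(f"cell {cell.id} is degenerate (<3 nodes)")
    return mesh.area(cell)


def axial_distance_from_qc(mesh, target):
    """Distance along the growth axis from the QC shootward face (µm)."""
    return mesh.axial_position(target)


# ----------------------------------------------------------------- division

_SNAP = 0.3  # µm: crossings closer than this to a node reuse the node


def _bisecting_height(xy, frac=0.5, tol=1e-10):
    """y level splitting the polygon so the part above (smaller y) holds
    ``frac`` of the area; solved by bisection on clipped-polygon area."""
    poly = Polygon(xy)
    y0, y1 = float(xy[:, 1].min()), float(xy[:, 1].max())
    x0, x1 = float(xy[:, 0].min()) - 1.0, float(xy[:, 0].max()) + 1.0
    target = poly.area * frac
    lo, hi = y0, y1
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        above = poly.intersection(box(x0, y0 - 1.0, x1, mid)).area
        if abs(above - target) <= tol * poly.area:
            return mid
        if above < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _insert_node_on_edge(mesh, a, b, x, y):
    """Split edge (a, b) at (x, y) in every cell that carries it, keeping
    the summed rest length unchanged."""
    m = mesh.new_node(x, y, fixed=False)
    key = _ekey(a, b)
    rest = mesh.rest_length.pop(key)
    la = mesh.edge_length(a, m)
    lb = mesh.edge_length(m, b)
    tot = la + lb
    if tot <= 0:
        raise MeshError("zero-length edge split")
    mesh.rest_length[_ekey(a, m)] = rest * la / tot
    mesh.rest_length[_ekey(m, b)] = rest * lb / tot
    for cid in list(mesh.edge_cells.get(key, ())):
        ring = mesh.cells[cid].ring
        n = len(ring)
        for i in range(n):
            j = (i + 1) % n
            if {ring[i], ring[j]} == {a, b}:
                ring.insert(j if j != 0 else n, m)
                break
    mesh.invalidate()
    return m


def divide_cell_horizontal(mesh, cell):
    """Insert a horizontal wall bisecting the cell area; return daughters.

    The wall is placed at the horizontal chord that splits the polygon
    area in half.  Chemical amounts, target area and GA-relevant state
    are inherited proportionally to daughter area; the division counter
    is incremented in both daughters.  Raises :class:`MeshError` for
    columella/QC cells.
    """
    if isinstance(cell, int):
        cell = mesh.cells[cell]
    if cell.role is Role.COLUMELLA_QC:
        raise MeshError(f"cell {cell.id} is COLUMELLA_QC and cannot divide")
    xy = mesh.ring_xy(cell)
    parent_area = abs(polygon_signed_area(xy))
    y_star = _bisecting_height(xy)

    # locate the two transversal crossings of y = y_star with the ring
    anchors = []
    ring = list(cell.ring)
    n = len(ring)
    for i in range(n):
        p = mesh.nodes[ring[i]]
        q = mesh.nodes[ring[(i + 1) % n]]
        if abs(p.y - y_star) <= _SNAP:
            anchors.append(("node", ring[i]))
            continue
        if (p.y - y_star) * (q.y - y_star) < 0 and abs(q.y - y_star) > _SNAP:
            t = (y_star - p.y) / (q.y - p.y)
            x_cross = p.x + t * (q.x - p.x)
            # snap to a nearby endpoint rather than creating a sliver
            if math.hypot(x_cross - p.x, y_star - p.y) <= _SNAP:
                anchors.append(("node", ring[i]))
            elif math.hypot(x_cross - q.x, y_star - q.y) <= _SNAP:
                anchors.append(("node", ring[(i + 1) % n]))
            else:
                anchors.append(("edge", (ring[i], ring[(i + 1) % n], x_cross)))
    # dedup node anchors
    seen = set()
    uniq = []
    for kind, payload in anchors:
        k = (kind, payload if kind == "node" else payload[:2])
        if k not in seen:
            seen.add(k)
            uniq.append((kind, payload))
    if len(uniq) < 2:
        raise DegenerationError(f"cell {cell.id}: no bisecting chord found")
    if len(uniq) > 2:
        # non-convex boundary: keep the extreme-x pair
        def anchor_x(a):
            return mesh.nodes[a[1]].x if a[0] == "node" else a[1][2]

        uniq.sort(key=anchor_x)
        uniq = [uniq[0], uniq[-1]]

    mids = []
    for kind, payload in uniq:
        if kind == "node":
            mids.append(payload)
        else:
            a, b, x = payload
            mids.append(_insert_node_on_edge(mesh, a, b, x, y_star))
    m1, m2 = mids
    if m1 == m2:
        raise DegenerationError(f"cell {cell.id}: degenerate bisecting chord")

    ring = list(cell.ring)  # may have grown by the insertions
    i1, i2 = ring.index(m1), ring.index(m2)
    if i1 > i2:
        i1, i2 = i2, i1
        m1, m2 = m2, m1
    if i2 - i1 < 2 or len(ring) - (i2 - i1) < 2:
        raise DegenerationError(
            f"cell {cell.id}: bisecting chord touches adjacent ring nodes"
        )
    ring_a = ring[i1:i2 + 1]
    ring_b = ring[i2:] + ring[:i1 + 1]
    mesh.rest_length.setdefault(_ekey(m1, m2), mesh.edge_length(m1, m2))

    del mesh.cells[cell.id]
    mesh.invalidate()

    daughters = []
    areas = []
    for r in (ring_a, ring_b):
        xyr = np.array([(mesh.nodes[i].x, mesh.nodes[i].y) for i in r])
        if polygon_signed_area(xyr) < 0:
            r = list(reversed(r))
        length = float(xyr[:, 1].max() - xyr[:, 1].min())
        area = abs(polygon_signed_area(xyr))
        d = mesh.new_cell(
            ring=list(r),
            target_area=1.0,
            file_index=cell.file_index,
            role=cell.role,
            zone=cell.zone,
            initial_width=(area / length if length > 0 else cell.initial_width),
        )
        d.t_release = cell.t_release
        d.t_since_division = 0.0
        d.division_count = cell.division_count + 1
        d.noise_mult = cell.noise_mult
        daughters.append(d)
        areas.append(area)

    total = sum(areas)
    for d, a in zip(daughters, areas):
        f = a / total
        d.target_area = cell.target_area * f
        d.chem = {sp: q * f for sp, q in cell.chem.items()}
    # exact chemical conservation despite float rounding of fractions
    for sp, q in cell.chem.items():
        daughters[0].chem[sp] = q - daughters[1].chem[sp]
    mesh.invalidate()
    return tuple(daughters)


# ------------------------------------------------------------ serialization


def write_mesh(mesh, path):
    """Serialize a mesh as an XML snapshot (nodes, edges, cells, walls)."""
    def num(x):
        return repr(float(x))

    root = etree.Element("rootmesh", time=num(mesh.time))
    nodes_el = etree.SubElement(root, "nodes")
    for n in mesh.nodes.values():
        etree.SubElement(
            nodes_el, "node", id=str(n.id), x=num(n.x), y=num(n.y),
            fixed=str(int(n.fixed)),
        )
    edges_el = etree.SubElement(root, "edges")
    for (a, b), rest in sorted(mesh.rest_length.items()):
        etree.SubElement(edges_el, "edge", a=str(a), b=str(b), rest=num(rest))
    cells_el = etree.SubElement(root, "cells")
    for c in sorted(mesh.cells.values(), key=lambda c: c.id):
        el = etree.SubElement(
            cells_el, "cell",
            id=str(c.id),
            nodes=" ".join(map(str, c.ring)),
            target_area=num(c.target_area),
            zone=c.zone.name,
            role=c.role.value,
            file_index=str(c.file_index),
            t_release=num(c.t_release),
            t_since_division=num(c.t_since_division),
            division_count=str(c.division_count),
            initial_width=num(c.initial_width),
            noise_mult=num(c.noise_mult),
        )
        for sp, q in sorted(c.chem.items()):
            etree.SubElement(el, "chem", species=sp, amount=num(q))
    walls_el = etree.SubElement(root, "walls")
    for w in mesh.walls():
        etree.SubElement(
            walls_el, "wall",
            id=str(w.id), cell_a=str(w.cell_a), cell_b=str(w.cell_b),
            nodes=" ".join(f"{a},{b}" for a, b in w.edges),
            pin_ab=num(w.pin_ab), pin_ba=num(w.pin_ba),
        )
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_mesh(path):
    """Parse an XML snapshot written by :func:`write_mesh`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise MeshFormatError(f"unparseable mesh file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "rootmesh":
        raise MeshFormatError(f"unexpected root element <{root.tag}>")
    mesh = Mesh()
    mesh.time = float(root.get("time", "0"))
    for el in root.findall("nodes/node"):
        nid = int(el.get("id"))
        mesh.nodes[nid] = Node(
            nid, float(el.get("x")), float(el.get("y")),
            bool(int(el.get("fixed", "0"))),
        )
    for el in root.findall("edges/edge"):
        a, b = int(el.get("a")), int(el.get("b"))
        for nid in (a, b):
            if nid not in mesh.nodes:
                raise MeshFormatError(f"edge ({a},{b}) references missing node {nid}")
        mesh.rest_length[_ekey(a, b)] = float(el.get("rest"))
    for el in root.findall("cells/cell"):
        cid = int(el.get("id"))
        ring = [int(s) for s in el.get("nodes").split()]
        for nid in ring:
            if nid not in mesh.nodes:
                raise MeshFormatError(f"cell {cid} references missing node {nid}")
        chem = {
            ch.get("species"): float(ch.get("amount"))
            for ch in el.findall("chem")
        }
        mesh.cells[cid] = Cell(
            id=cid,
            ring=ring,
            target_area=float(el.get("target_area")),
            chem=chem,
            t_release=float(el.get("t_release", "0")),
            t_since_division=float(el.get("t_since_division", "0")),
            division_count=int(el.get("division_count", "0")),
            zone=Zone[el.get("zone", "DZ")],
            file_index=int(el.get("file_index", "0")),
            role=Role(el.get("role", "BODY")),
            initial_width=float(el.get("initial_width", "0")),
            noise_mult=float(el.get("noise_mult", "0")),
        )
    for el in root.findall("walls/wall"):
        ca, cb = int(el.get("cell_a")), int(el.get("cell_b"))
        for val in (float(el.get("pin_ab", "0")), ):
            if val:
                mesh.pin[(ca, cb)] = val
        for val in (float(el.get("pin_ba", "0")), ):
            if val:
                mesh.pin[(cb, ca)] = val
    mesh._next_node = max(mesh.nodes, default=-1) + 1
    mesh._next_cell = max(mesh.cells, default=-1) + 1
    mesh.invalidate()
    return mesh


def snapshot_frame(mesh):
    """Tabulate per-cell state (one row per cell) for kinematic analysis.

    Axial positions are distances from the QC face, positive shootward.
    """
    face = mesh.qc_face_y()
    rows = []
    for c in sorted(mesh.cells.values(), key=lambda c: c.id):
        xy = mesh.ring_xy(c)
        area = abs(polygon_signed_area(xy))
        cx, cy = polygon_centroid(xy)
        ymin, ymax = float(xy[:, 1].min()), float(xy[:, 1].max())
        row = {
            "time": mesh.time,
            "cell_id": c.id,
            "file_index": c.file_index,
            "role": c.role.value,
            "zone": c.zone.name,
            "area": area,
            "target_area": c.target_area,
            "length": ymax - ymin,
            "width": area / (ymax - ymin) if ymax > ymin else 0.0,
            "position": face - cy,
            "pos_min": face - ymax,
            "pos_max": face - ymin,
            "division_count": c.division_count,
            "t_release": c.t_release,
        }
        for sp in SPECIES:
            if sp in c.chem:
                row[sp] = c.chem[sp]
                row[f"{sp}_conc"] = c.chem[sp] / area if area > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
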
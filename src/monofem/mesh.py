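"""Structured hexahedral box meshes with node/face selection and VTK export.

All experiment geometries (conduction rod, anisotropic cuboid, thin slab
for spiral-wave runs) are axis-aligned boxes meshed with a regular grid of
hexahedra.  Per axis the grid uses ``floor(L/h)`` elements of size ``h``
plus one smaller remainder element when ``L`` is not an integer multiple
of ``h``, so the box is always tiled exactly.

Coordinates are in mm and node indexing is 0-based everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .elements import CORNER_SIGNS, ElementFamily, get_family

__all__ = ["Mesh", "RegionSpec", "build_box_mesh", "select_nodes", "write_vtk"]

_GEOM_TOL = 1e-9

# Local faces of the reference cube in the canonical corner numbering:
# (axis, side) -> corner indices (0-based) of that face.
_FACE_CORNERS = {
    (0, -1): (0, 3, 7, 4),   # xi1 = -1
    (0, +1): (1, 2, 6, 5),   # xi1 = +1
    (1, -1): (0, 1, 5, 4),   # xi2 = -1
    (1, +1): (3, 2, 6, 7),   # xi2 = +1
    (2, -1): (0, 1, 2, 3),   # xi3 = -1
    (2, +1): (4, 5, 6, 7),   # xi3 = +1
}
FACE_NAMES = ["xmin", "xmax", "ymin", "ymax", "zmin", "zmax"]
_FACE_KEYS = [(0, -1), (0, +1), (1, -1), (1, +1), (2, -1), (2, +1)]


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned box or boundary-plane selector (closed intervals, mm)."""

    box: tuple[tuple[float, float], tuple[float, float], tuple[float, float]] | None = None
    plane: tuple[int, float] | None = None     # (axis, value)
    tol: float = _GEOM_TOL

    def __post_init__(self) -> None:
        if (self.box is None) == (self.plane is None):
            raise ValueError("RegionSpec requires exactly one of box= or plane=")
        if self.box is not None:
            for lo, hi in self.box:
                if lo > hi:
                    raise ValueError(f"box min {lo} exceeds max {hi}")
        if self.plane is not None and self.plane[0] not in (0, 1, 2):
            raise ValueError("plane axis must be 0, 1 or 2")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 3) inside the closed region."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.box is not None:
            mask = np.ones(len(pts), dtype=bool)
            for ax, (lo, hi) in enumerate(self.box):
                mask &= (pts[:, ax] >= lo - self.tol) & (pts[:, ax] <= hi + self.tol)
            return mask
        ax, val = self.plane
        return np.abs(pts[:, ax] - val) <= self.tol


@dataclass
class Mesh:
    """Hexahedral mesh: nodes, connectivity, named node/face sets.

    ``elems`` holds 8 (Q1/Q1NC) or 27 (Q2) node indices per element in the
    canonical ordering of :mod:`monofem.elements`.  ``face_sets`` map names
    to arrays of ``(element index, local face id)`` pairs with local face
    ids 0..5 = (-x, +x, -y, +y, -z, +z).
    """

    nodes: np.ndarray                 # (nn, 3) mm
    elems: np.ndarray                 # (nel, nen) int
    family_name: str
    dimensions: tuple[float, float, float]
    axis_breaks: tuple[np.ndarray, np.ndarray, np.ndarray]
    h: float
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elems.shape[0]

    @property
    def family(self) -> ElementFamily:
        return get_family(self.family_name)

    def corner_elems(self) -> np.ndarray:
        """Connectivity restricted to the 8 geometric corners of each element."""
        if self.elems.shape[1] == 8:
            return self.elems
        # Q2 lexicographic lattice: corners at offsets (a,b,c) in {0,2}^3,
        # listed in the canonical Q1 corner order.
        lex = [(0, 0, 0), (2, 0, 0), (2, 2, 0), (0, 2, 0),
               (0, 0, 2), (2, 0, 2), (2, 2, 2), (0, 2, 2)]
        idx = [a + 3 * b + 9 * c for a, b, c in lex]
        return self.elems[:, idx]

    def corner_coords(self) -> np.ndarray:
        """(nel, 8, 3) corner coordinates in canonical order."""
        return self.nodes[self.corner_elems()]

    def element_volumes(self) -> np.ndarray:
        """Exact volumes for the axis-aligned structured grid."""
        lens = [np.diff(b) for b in self.axis_breaks]
        nx, ny, nz = (len(l) for l in lens)
        vol = (lens[0][:, None, None] * lens[1][None, :, None] * lens[2][None, None, :])
        return vol.transpose(2, 1, 0).ravel()  # element index runs x fastest

    def nearest_node(self, point) -> int:
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        return int(np.argmin(d))

    def face_nodes(self, elem: int, face_id: int) -> np.ndarray:
        """Global node indices of the 4 corners of a local face."""
        corners = _FACE_CORNERS[_FACE_KEYS[face_id]]
        return self.corner_elems()[elem, list(corners)]


def _axis_breakpoints(L: float, h: float) -> np.ndarray:
    """Partition [0, L]: floor(L/h) elements of size h + one remainder."""
    if h <= 0 or L <= 0:
        raise ValueError("dimensions and element size must be positive")
    if h > L:
        # a single boundary-fitted element covers the whole (short) axis
        return np.array([0.0, L])
    n = int(np.floor(L / h + _GEOM_TOL))
    breaks = h * np.arange(n + 1)
    if L - breaks[-1] > _GEOM_TOL:
        breaks = np.append(breaks, L)
    else:
        breaks[-1] = L
    return breaks


def build_box_mesh(dimensions, h: float, family: ElementFamily | str = "Q1") -> Mesh:
    """Structured hexahedral mesh of the box ``[0,Lx]x[0,Ly]x[0,Lz]``.

    Elements have uniform size ``h`` except for one shrunken layer against
    the far boundary of each axis whose length is not a multiple of ``h``.
    Q2 meshes insert mid-edge/face/center nodes on the per-element midpoint
    lattice.  Auto-generates face sets ``xmin..zmax`` for the six outer
    faces and node sets of the same names.
    """
    if isinstance(family, str):
        family = get_family(family)
    dims = tuple(float(d) for d in dimensions)
    if len(dims) != 3:
        raise ValueError("dimensions must be (Lx, Ly, Lz)")
    breaks = tuple(_axis_breakpoints(L, h) for L in dims)
    ne = [len(b) - 1 for b in breaks]

    if family.name == "Q2":
        # Global lattice with nodes at breakpoints and element midpoints.
        coords_1d = []
        for b in breaks:
            c = np.empty(2 * (len(b) - 1) + 1)
            c[0::2] = b
            c[1::2] = 0.5 * (b[:-1] + b[1:])
            coords_1d.append(c)
        stride = 2
    else:
        coords_1d = [b.copy() for b in breaks]
        stride = 1

    npts = [len(c) for c in coords_1d]
    Z, Y, X = np.meshgrid(coords_1d[2], coords_1d[1], coords_1d[0], indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def gid(i, j, k):
        return i + npts[0] * (j + npts[1] * k)

    nel = ne[0] * ne[1] * ne[2]
    if family.name == "Q2":
        offsets = [(a, b, c) for c in range(3) for b in range(3) for a in range(3)]
    else:
        offsets = [tuple(int(s > 0) for s in row) for row in CORNER_SIGNS]
    elems = np.empty((nel, len(offsets)), dtype=np.int64)
    e = 0
    for k in range(ne[2]):
        for j in range(ne[1]):
            for i in range(ne[0]):
                base = (stride * i, stride * j, stride * k)
                elems[e] = [gid(base[0] + a, base[1] + b, base[2] + c) for a, b, c in offsets]
                e += 1

    mesh = Mesh(nodes=nodes, elems=elems, family_name=family.name,
                dimensions=dims, axis_breaks=breaks, h=float(h))

    # Outer-face sets: element grid index pinned at 0 / ne-1 per axis.
    ei = np.arange(nel)
    egrid = np.column_stack([ei % ne[0], (ei // ne[0]) % ne[1], ei // (ne[0] * ne[1])])
    for fid, (ax, side) in enumerate(_FACE_KEYS):
        sel = egrid[:, ax] == (0 if side < 0 else ne[ax] - 1)
        pairs = np.column_stack([ei[sel], np.full(sel.sum(), fid)])
        mesh.face_sets[FACE_NAMES[fid]] = pairs
        bound = 0.0 if side < 0 else dims[ax]
        mesh.node_sets[FACE_NAMES[fid]] = select_nodes(
            mesh, RegionSpec(plane=(ax, bound)), warn_empty=False)
    return mesh


def select_nodes(mesh: Mesh, region: RegionSpec, warn_empty: bool = True) -> np.ndarray:
    """Indices of all nodes inside the closed region (tolerance 1e-9 mm)."""
    mask = region.contains(mesh.nodes)
    idx = np.flatnonzero(mask)
    if idx.size == 0 and warn_empty:
        warnings.warn(f"region {region} selects no nodes", stacklevel=2)
    return idx


def write_vtk(mesh: Mesh, point_fields: dict[str, np.ndarray], path) -> None:
    """Write a VTK legacy ASCII unstructured-grid file with point scalars.

    Q1/Q1NC elements map to VTK_HEXAHEDRON (type 12).  Q2 elements are
    decomposed into 8 trilinear sub-cells on the midpoint lattice so the
    file needs only type 12 and stays readable by any VTK tool; all 27
    nodes and their point data are preserved.
    """
    for name, arr in point_fields.items():
        if len(arr) != mesh.n_nodes:
            raise ValueError(f"field {name!r} has {len(arr)} values for {mesh.n_nodes} nodes")
    if mesh.elems.shape[1] == 8:
        cells = mesh.elems
    else:
        sub = []
        for c0 in range(2):
            for b0 in range(2):
                for a0 in range(2):
                    lex = [(a0, b0, c0), (a0 + 1, b0, c0), (a0 + 1, b0 + 1, c0),
                           (a0, b0 + 1, c0), (a0, b0, c0 + 1), (a0 + 1, b0, c0 + 1),
                           (a0 + 1, b0 + 1, c0 + 1), (a0, b0 + 1, c0 + 1)]
                    sub.append([a + 3 * b + 9 * c for a, b, c in lex])
        cells = mesh.elems[:, np.asarray(sub)].reshape(-1, 8)

    lines = [
        "# vtk DataFile Version 3.0",
        "monofem unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {len(cells)} {len(cells) * 9}")
    lines += ["8 " + " ".join(str(int(i)) for i in c) for c in cells]
    lines.append(f"CELL_TYPES {len(cells)}")
    lines += ["12"] * len(cells)
    if point_fields:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, arr in point_fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.10g}" for v in arr]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
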
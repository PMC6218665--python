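"""Reference-domain element technology for hexahedral meshes.

Three element families are supported, all defined on the reference cube
``[-1, 1]^3``:

* ``Q1``   — 8-node trilinear Lagrange element, 2x2x2 Gauss quadrature.
* ``Q2``   — 27-node triquadratic Lagrange element, 3x3x3 Gauss quadrature.
* ``Q1NC`` — the Q1 element enriched with three element-internal
  incompatible (Wilson) modes ``1 - xi_c^2``; the enrichment carries no
  globally shared unknowns, so the global system stays Q1-sized once the
  internal coefficients are condensed out.

Corner numbering follows the classical counter-clockwise bottom/top
convention: nodes 1-4 on the face ``xi3 = -1`` starting at
``(-1, -1, -1)``, nodes 5-8 directly above on ``xi3 = +1``.  Q2 nodes are
ordered lexicographically over the 3x3x3 lattice ``{-1, 0, 1}^3`` with
``xi1`` varying fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuadratureRule",
    "ElementFamily",
    "MappedElement",
    "Q1",
    "Q2",
    "Q1NC",
    "FAMILIES",
    "get_family",
    "gauss_rule",
    "eval_q1_basis",
    "eval_q2_basis",
    "eval_nc_modes",
    "map_element",
    "tabulate_basis",
    "CORNER_SIGNS",
]

_XI_TOL = 1e-12

# Reference corner coordinates in canonical order (rows: nodes 1..8).
CORNER_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class QuadratureRule:
    """Tensor-product Gauss–Legendre rule on the reference cube.

    ``points`` has shape (n, 3) and ``weights`` shape (n,); the weights sum
    to 8, the volume of ``[-1, 1]^3``.
    """

    points: np.ndarray
    weights: np.ndarray

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ElementFamily:
    """Static description of an element family (DOF counts + quadrature)."""

    name: str
    nodes_per_element: int
    nc_modes: int
    quad_points_per_axis: int

    @property
    def quadrature(self) -> QuadratureRule:
        return gauss_rule(self.quad_points_per_axis)


Q1 = ElementFamily("Q1", 8, 0, 2)
Q1NC = ElementFamily("Q1NC", 8, 3, 2)
Q2 = ElementFamily("Q2", 27, 0, 3)

FAMILIES = {f.name: f for f in (Q1, Q1NC, Q2)}


def get_family(name: str) -> ElementFamily:
    try:
        return FAMILIES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown element family {name!r}; expected one of {sorted(FAMILIES)}")


def _check_xi(xi: np.ndarray) -> np.ndarray:
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (3,):
        raise ValueError(f"xi must be a 3-vector, got shape {xi.shape}")
    if np.any(np.abs(xi) > 1.0 + _XI_TOL):
        raise ValueError(f"xi={xi} outside the reference cube [-1,1]^3")
    return xi


def gauss_rule(points_per_axis: int) -> QuadratureRule:
    """Tensor-product Gauss–Legendre quadrature (2 or 3 points per axis).

    The 2-point rule integrates per-axis polynomials through degree 3
    exactly, the 3-point rule through degree 5 — the full rules used for
    every element integral (no lumping or under-integration anywhere).
    """
    if points_per_axis not in (2, 3):
        raise ValueError(f"unsupported quadrature order {points_per_axis}; expected 2 or 3")
    x1, w1 = np.polynomial.legendre.leggauss(points_per_axis)
    # xi1 varies fastest, matching the Q2 node ordering convention.
    P3, P2, P1 = np.meshgrid(x1, x1, x1, indexing="ij")
    pts = np.column_stack([P1.ravel(), P2.ravel(), P3.ravel()])
    W3, W2, W1 = np.meshgrid(w1, w1, w1, indexing="ij")
    wts = (W1 * W2 * W3).ravel()
    return QuadratureRule(points=pts, weights=wts)


def eval_q1_basis(xi) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions N_a(xi) and their reference gradients.

    Returns ``(values, grads)`` with shapes (8,) and (8, 3).
    """
    xi = _check_xi(xi)
    s = CORNER_SIGNS
    one = 1.0 + s * xi  # (8,3): factors (1 + s_c xi_c)
    vals = 0.125 * one[:, 0] * one[:, 1] * one[:, 2]
    grads = np.empty((8, 3))
    grads[:, 0] = 0.125 * s[:, 0] * one[:, 1] * one[:, 2]
    grads[:, 1] = 0.125 * s[:, 1] * one[:, 0] * one[:, 2]
    grads[:, 2] = 0.125 * s[:, 2] * one[:, 0] * one[:, 1]
    return vals, grads


def _lagrange_1d(x: float) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic Lagrange polynomials on the nodes {-1, 0, 1} and slopes."""
    vals = np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
    ders = np.array([x - 0.5, -2.0 * x, x + 0.5])
    return vals, ders


def eval_q2_basis(xi) -> tuple[np.ndarray, np.ndarray]:
    """Triquadratic (27-node) Lagrange basis on the 3x3x3 lattice.

    Node ordering is lexicographic over ``{-1, 0, 1}^3`` with xi1 fastest.
    Returns ``(values, grads)`` with shapes (27,) and (27, 3).
    """
    xi = _check_xi(xi)
    l1, d1 = _lagrange_1d(xi[0])
    l2, d2 = _lagrange_1d(xi[1])
    l3, d3 = _lagrange_1d(xi[2])
    vals = np.empty(27)
    grads = np.empty((27, 3))
    n = 0
    for c in range(3):
        for b in range(3):
            for a in range(3):
                vals[n] = l1[a] * l2[b] * l3[c]
                grads[n, 0] = d1[a] * l2[b] * l3[c]
                grads[n, 1] = l1[a] * d2[b] * l3[c]
                grads[n, 2] = l1[a] * l2[b] * d3[c]
                n += 1
    return vals, grads


def eval_nc_modes(xi) -> tuple[np.ndarray, np.ndarray]:
    """Incompatible (Wilson) bubble modes ``M_c = 1 - xi_c^2``.

    The modes vanish on the faces ``xi_c = +-1``, so the enrichment lives
    strictly inside the element and inter-element continuity is violated
    only in element interiors.  Returns shapes (3,) and (3, 3).
    """
    xi = _check_xi(xi)
    vals = 1.0 - xi * xi
    grads = np.diag(-2.0 * xi)
    return vals, grads


def tabulate_basis(family: ElementFamily, rule: QuadratureRule | None = None):
    """Evaluate the family's basis (and nc modes, if any) at quadrature points.

    Returns ``(N, dN, W, dW)`` with shapes (nq, nen), (nq, nen, 3),
    (nq, nnc), (nq, nnc, 3); ``W``/``dW`` are empty for Q1/Q2.
    """
    if rule is None:
        rule = family.quadrature
    nq = rule.n_points
    nen = family.nodes_per_element
    evalf = eval_q2_basis if family.name == "Q2" else eval_q1_basis
    N = np.empty((nq, nen))
    dN = np.empty((nq, nen, 3))
    W = np.empty((nq, family.nc_modes))
    dW = np.empty((nq, family.nc_modes, 3))
    for q, xi in enumerate(rule.points):
        N[q], dN[q] = evalf(xi)
        if family.nc_modes:
            W[q], dW[q] = eval_nc_modes(xi)
    return N, dN, W, dW


@dataclass
class MappedElement:
    """Isoparametric data of one element at its quadrature points.

    Physical gradients are obtained as ``J^{-T} grad_ref``; ``detJ * w_q``
    is the physical integration measure (mm^3).
    """

    node_coords: np.ndarray          # (8, 3) corner coordinates, mm
    rule: QuadratureRule
    phys_points: np.ndarray = field(init=False)   # (nq, 3)
    jac: np.ndarray = field(init=False)           # (nq, 3, 3)
    det_jac: np.ndarray = field(init=False)       # (nq,)
    inv_jac: np.ndarray = field(init=False)       # (nq, 3, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.node_coords, dtype=float)
        if coords.shape != (8, 3):
            raise ValueError("map_element expects the 8 corner nodes")
        nq = self.rule.n_points
        self.phys_points = np.empty((nq, 3))
        self.jac = np.empty((nq, 3, 3))
        for q, xi in enumerate(self.rule.points):
            N, dN = eval_q1_basis(xi)
            self.phys_points[q] = N @ coords
            # J[i, j] = d x_i / d xi_j
            self.jac[q] = coords.T @ dN
        self.det_jac = np.linalg.det(self.jac)
        if np.any(self.det_jac <= 0):
            raise ValueError("non-positive Jacobian determinant: inverted or degenerate element")
        self.inv_jac = np.linalg.inv(self.jac)

    def physical_gradients(self, ref_grads: np.ndarray) -> np.ndarray:
        """Push reference gradients (nq, n, 3) to physical space."""
        return np.einsum("qji,qnj->qni", self.inv_jac, ref_grads)


def map_element(node_coords, rule: QuadratureRule) -> MappedElement:
    """Isoparametric map of a hexahedron given its 8 corner coordinates."""
    return MappedElement(node_coords=np.asarray(node_coords, dtype=float), rule=rule)
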
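"""Heaviside-enriched hexahedral elements with moment-fitting quadrature.

The voxel grid maps one-to-one to eight-node hexahedral elements on a
structured mesh.  The level set phi, interpolated to the nodes, classifies
each element as solid (all nodal phi >= 0), void (all < 0) or cut (mixed
signs); H(0) = 1, i.e. the zero level belongs to the solid phase.  Solid
elements are integrated with the standard 2x2x2 Gauss rule.  Cut elements
keep a fixed set of Gauss-Legendre points but receive moment-fitted weights

    w_i = int_Qe H(phi(xi)) l_i(xi) dQe,

with l_i the Lagrange polynomials through the Gauss points, evaluated by
subdividing the element into n_c equal sub-cells, assigning the Heaviside
value from phi at each sub-cell center, and reusing the per-sub-cell
Lagrange integrals (which depend only on the sub-cell position, not on the
element).  Defaults p_q = 2 (27 points) and n_c = 10^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ELEM_VOID",
    "ELEM_SOLID",
    "ELEM_CUT",
    "StructuredHexMesh",
    "QuadratureRule",
    "ElementContribution",
    "nodal_phi_from_voxel",
    "gather_nodal_phi",
    "classify_elements",
    "gauss_rule",
    "lagrange_basis_values",
    "momentfit_tables",
    "moment_fit_weights",
    "moment_fit_weights_batch",
    "element_B_stack",
    "integrate_element",
    "integrate_elements_batch",
]

ELEM_VOID = 0
ELEM_SOLID = 1
ELEM_CUT = 2

# local node offsets of the hex element, fixed ordering used package-wide
NODE_OFFSETS = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0],
                         [0, 0, 1], [1, 0, 1], [0, 1, 1], [1, 1, 1]])
# node coordinates in the isoparametric cube [-1, 1]^3
NODE_XI = 2.0 * NODE_OFFSETS - 1.0


@dataclass
class StructuredHexMesh:
    """Axis-aligned structured hex mesh with one element per voxel."""

    dims: tuple[int, int, int]       # elements per axis
    spacing_mm: tuple[float, float, float]

    @property
    def n_elements(self) -> int:
        ex, ey, ez = self.dims
        return ex * ey * ez

    @property
    def node_dims(self) -> tuple[int, int, int]:
        ex, ey, ez = self.dims
        return (ex + 1, ey + 1, ez + 1)

    @property
    def det_jacobian(self) -> float:
        hx, hy, hz = self.spacing_mm
        if hx <= 0 or hy <= 0 or hz <= 0:
            raise ValueError("singular Jacobian: element spacing must be positive")
        return hx * hy * hz / 8.0

    @property
    def volume(self) -> float:
        hx, hy, hz = self.spacing_mm
        return self.n_elements * hx * hy * hz


@dataclass
class QuadratureRule:
    """Integration points (isoparametric) and weights for one element."""

    points: np.ndarray    # (n_i, 3)
    weights: np.ndarray   # (n_i,)
    order: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("quadrature weights must be finite")


@dataclass
class ElementContribution:
    """Stiffness, unit-strain load columns and hygric load of one element."""

    K: np.ndarray   # (24, 24)
    F: np.ndarray   # (24, 6)
    f: np.ndarray   # (24,)


# --------------------------------------------------------------------------
# nodal level set and element classification
# --------------------------------------------------------------------------

def nodal_phi_from_voxel(phi_vox: np.ndarray, periodic: bool = True) -> np.ndarray:
    """Interpolate voxel-center phi to mesh nodes (8-neighbor average).

    Nodes are voxel corners; each node value is the mean of the up to eight
    adjacent voxel values, wrapping across the domain when periodic.
    """
    mode = "wrap" if periodic else "edge"
    p = np.pad(phi_vox, 1, mode=mode)
    out = np.zeros(tuple(s + 1 for s in phi_vox.shape))
    for di, dj, dk in NODE_OFFSETS:
        out += p[di:di + phi_vox.shape[0] + 1,
                 dj:dj + phi_vox.shape[1] + 1,
                 dk:dk + phi_vox.shape[2] + 1]
    return out / 8.0


def gather_nodal_phi(phi_nodal: np.ndarray) -> np.ndarray:
    """Per-element nodal phi values, shape (n_elem, 8) in mesh element order."""
    ex, ey, ez = (s - 1 for s in phi_nodal.shape)
    out = np.empty((ex * ey * ez, 8))
    for a, (di, dj, dk) in enumerate(NODE_OFFSETS):
        out[:, a] = phi_nodal[di:di + ex, dj:dj + ey, dk:dk + ez].ravel()
    return out


def classify_elements(phi_elem_nodal: np.ndarray) -> np.ndarray:
    """Element classes from nodal phi signs: solid / void / cut.

    ``phi_elem_nodal`` has shape (n_elem, 8).  All nodal phi >= 0 gives
    solid (the zero level counts as solid, H(0) = 1); all < 0 gives void;
    mixed signs give cut.
    """
    solid = np.all(phi_elem_nodal >= 0, axis=1)
    void = np.all(phi_elem_nodal < 0, axis=1)
    out = np.full(phi_elem_nodal.shape[0], ELEM_CUT, dtype=np.uint8)
    out[solid] = ELEM_SOLID
    out[void] = ELEM_VOID
    return out


# --------------------------------------------------------------------------
# quadrature and moment fitting
# --------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _gauss_1d(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def gauss_rule(n_per_axis: int) -> QuadratureRule:
    """Tensor-product Gauss-Legendre rule on [-1, 1]^3."""
    g, w = _gauss_1d(n_per_axis)
    pts = np.array([(g[a], g[b], g[c])
                    for a in range(n_per_axis)
                    for b in range(n_per_axis)
                    for c in range(n_per_axis)])
    wts = np.array([w[a] * w[b] * w[c]
                    for a in range(n_per_axis)
                    for b in range(n_per_axis)
                    for c in range(n_per_axis)])
    return QuadratureRule(points=pts, weights=wts, order=n_per_axis - 1)


def lagrange_basis_values(xi: np.ndarray, p_q: int) -> np.ndarray:
    """Evaluate the (p_q+1)^3 tensor Lagrange polynomials at points xi.

    The Lagrange nodes are the Gauss-Legendre points, so l_j(xi_i^GL) =
    delta_ji.  Returns shape (len(xi), (p_q+1)^3) with the same point
    ordering as :func:`gauss_rule`.
    """
    g, _ = _gauss_1d(p_q + 1)
    xi = np.atleast_2d(xi)

    def l1d(t: np.ndarray) -> np.ndarray:
        # (npts, p_q+1): 1D Lagrange basis through nodes g
        out = np.ones((len(t), len(g)))
        for a in range(len(g)):
            for k in range(len(g)):
                if k != a:
                    out[:, a] *= (t - g[k]) / (g[a] - g[k])
        return out

    lx, ly, lz = l1d(xi[:, 0]), l1d(xi[:, 1]), l1d(xi[:, 2])
    return np.einsum("pa,pb,pc->pabc", lx, ly, lz).reshape(len(xi), -1)


@lru_cache(maxsize=8)
def momentfit_tables(p_q: int, n_c: int) -> tuple[np.ndarray, np.ndarray]:
    """Precomputed sub-cell tables for moment fitting.

    Returns ``(T, Phi)`` where ``T`` (n_i, n_c) holds the integral of each
    Lagrange basis over each sub-cell (2-point Gauss per axis, exact for the
    quadratic basis) and ``Phi`` (n_c, 8) the trilinear shape functions at
    the sub-cell centers, for evaluating phi there from nodal values.
    Sub-cells are ordered lexicographically like the quadrature points.
    """
    s = round(n_c ** (1.0 / 3.0))
    if s**3 != n_c:
        raise ValueError("n_c must be a perfect cube")
    if p_q < 1:
        raise ValueError("quadrature order p_q must be >= 1")
    n1 = p_q + 1
    g, _ = _gauss_1d(n1)
    edges = np.linspace(-1.0, 1.0, s + 1)
    half = 1.0 / s  # sub-interval half-length
    gp2, gw2 = _gauss_1d(p_q)  # p_q-point rule: exact for degree 2p_q-1 >= p_q

    # 1D Lagrange integrals over each sub-interval: t1d[a, c]
    t1d = np.zeros((n1, s))
    for c in range(s):
        mid = 0.5 * (edges[c] + edges[c + 1])
        t = mid + half * gp2
        l = np.ones((len(t), n1))
        for a in range(n1):
            for k in range(n1):
                if k != a:
                    l[:, a] *= (t - g[k]) / (g[a] - g[k])
        t1d[:, c] = half * (gw2[:, None] * l).sum(axis=0)

    T = np.einsum("as,bt,cu->abcstu", t1d, t1d, t1d).reshape(n1**3, s**3)

    centers1d = 0.5 * (edges[:-1] + edges[1:])
    cx, cy, cz = np.meshgrid(centers1d, centers1d, centers1d, indexing="ij")
    pts = np.stack([cx.ravel(), cy.ravel(), cz.ravel()], axis=1)
    Phi = np.empty((n_c, 8))
    for a, xi_a in enumerate(NODE_XI):
        Phi[:, a] = np.prod((1.0 + pts * xi_a) / 2.0, axis=1)
    return T, Phi


def moment_fit_weights_batch(phi_elem_nodal: np.ndarray, p_q: int = 2,
                             n_c: int = 1000) -> np.ndarray:
    """Moment-fitted weights for a batch of cut elements.

    ``phi_elem_nodal`` has shape (n, 8); returns (n, (p_q+1)^3) weights at
    the Gauss-Legendre points of order p_q.  phi inside the element is the
    trilinear interpolation of the nodal values; each sub-cell's Heaviside
    value comes from phi at its center (H(0) = 1).
    """
    T, Phi = momentfit_tables(p_q, n_c)
    H = (phi_elem_nodal @ Phi.T) >= 0.0          # (n, n_c)
    return H.astype(np.float64) @ T.T            # (n, n_i)


def moment_fit_weights(phi_nodal: np.ndarray, p_q: int = 2,
                       n_c: int = 1000) -> QuadratureRule:
    """Quadrature rule for one element given its 8 nodal phi values.

    Solid elements get the standard Gauss rule of the requested order, void
    elements a zero-weight rule, and cut elements moment-fitted weights.
    """
    if p_q < 1:
        raise ValueError("quadrature order p_q must be >= 1")
    phi_nodal = np.asarray(phi_nodal, dtype=float).reshape(1, 8)
    cls = classify_elements(phi_nodal)[0]
    rule = gauss_rule(p_q + 1)
    if cls == ELEM_SOLID:
        return rule
    if cls == ELEM_VOID:
        return QuadratureRule(points=rule.points,
                              weights=np.zeros_like(rule.weights), order=p_q)
    w = moment_fit_weights_batch(phi_nodal, p_q, n_c)[0]
    return QuadratureRule(points=rule.points, weights=w, order=p_q)


# --------------------------------------------------------------------------
# element integrals
# --------------------------------------------------------------------------

def shape_gradients(points: np.ndarray) -> np.ndarray:
    """d N_a / d xi at the given isoparametric points, shape (npts, 8, 3)."""
    pts = np.atleast_2d(points)
    out = np.empty((len(pts), 8, 3))
    for a, xi_a in enumerate(NODE_XI):
        fac = (1.0 + pts * xi_a) / 2.0          # (npts, 3)
        for d in range(3):
            others = [e for e in range(3) if e != d]
            out[:, a, d] = (xi_a[d] / 2.0) * fac[:, others[0]] * fac[:, others[1]]
    return out


def element_B_stack(points: np.ndarray,
                    spacing_mm: tuple[float, float, float]) -> np.ndarray:
    """Strain-displacement matrices B (6 x 24) at each point, eng. shear."""
    dN = shape_gradients(points)                 # (npts, 8, 3), d/d xi
    scale = np.array([2.0 / s for s in spacing_mm])
    dN = dN * scale[None, None, :]               # d/d x (physical)
    npts = dN.shape[0]
    B = np.zeros((npts, 6, 24))
    for a in range(8):
        gx, gy, gz = dN[:, a, 0], dN[:, a, 1], dN[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 1] = gz
        B[:, 3, c + 2] = gy
        B[:, 4, c + 0] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 0] = gy
        B[:, 5, c + 1] = gx
    return B


def integrate_elements_batch(C: np.ndarray, beta: np.ndarray,
                             weights: np.ndarray, B: np.ndarray,
                             det_j: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """K, F, f for a batch of elements sharing quadrature point locations.

    ``C`` (n, 6, 6), ``beta`` (n, 6), ``weights`` (n, npts) or (npts,) for a
    shared rule, ``B`` (npts, 6, 24).  Returns K (n, 24, 24), F (n, 24, 6),
    f (n, 24).
    """
    C = np.asarray(C)
    n = C.shape[0]
    w = np.asarray(weights, dtype=float)
    if w.ndim == 1:
        w = np.broadcast_to(w, (n, w.shape[0]))
    BtC = np.einsum("iak,nab->nikb", B, C)              # (n, npts, 24, 6)
    K = np.einsum("ni,nikb,ibl->nkl", w, BtC, B) * det_j
    F = np.einsum("ni,nikb->nkb", w, BtC) * det_j       # (n, 24, 6)
    f = np.einsum("nkb,nb->nk", F, beta)                # beta constant per element
    return K, F, f


def integrate_element(C: np.ndarray, beta: np.ndarray, quad: QuadratureRule,
                      spacing_mm: tuple[float, float, float]) -> ElementContribution:
    """Stiffness and load contributions of a single element.

    K = sum_i w_i B^T C B det J, F columns are unit-macroscopic-strain loads
    B^T C e_j, and f is the hygric load B^T C beta, with det J = hx hy hz / 8
    for the axis-aligned voxel element.  Void elements (all-zero weights)
    return zero contributions.
    """
    if min(spacing_mm) <= 0:
        raise ValueError("singular Jacobian: element spacing must be positive")
    beta = np.asarray(beta, dtype=float)
    if beta.shape == (3,):
        beta = np.concatenate([beta, np.zeros(3)])
    B = element_B_stack(quad.points, spacing_mm)
    det_j = spacing_mm[0] * spacing_mm[1] * spacing_mm[2] / 8.0
    K, F, f = integrate_elements_batch(C[None], beta[None], quad.weights, B, det_j)
    return ElementContribution(K=K[0], F=F[0], f=f[0])
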
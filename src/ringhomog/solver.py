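"""Assembly and iterative solution of the periodic cell problems.

Six mechanical influence-function columns (one per independent macroscopic
strain component, Voigt order) and one hygric column are obtained from

    K n_j = -F_j   (j = 1..6),      K b = f,

on the periodic structured hex mesh.  Opposite-face nodes share degrees of
freedom (left/right, top/down, front/back), nodes surrounded exclusively by
void elements are deactivated, and the remaining translation nullspace is
handled by projecting residual and iterates onto the zero-mean subspace
inside a preconditioned conjugate-gradient loop.  The preconditioner is the
assembled sum of element-wise spectral pseudo-inverses,

    S = sum_e P_e^T (K^e_+)^(-1) P_e,

with eigenvalues at or below lambda_th = eps * max_i(lambda_i) zeroed
(default eps = 1e-13), which controls the ill-conditioning caused by cut
elements with small solid slivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .xfem import ELEM_VOID, NODE_OFFSETS

__all__ = [
    "PeriodicDofMap",
    "build_periodic_dof_map",
    "assemble_system",
    "assemble_matrix",
    "build_preconditioner",
    "TwoLevelPreconditioner",
    "CellProblemSolution",
    "solve_cell_problems",
    "pcg",
]


@dataclass
class PeriodicDofMap:
    """Reduced periodic DOF numbering on a structured hex mesh.

    Nodes on opposite faces are identified by wrapping the node index
    modulo the element count per axis, which chains edge and corner nodes
    to a single master automatically.  ``element_dofs`` holds, per element,
    the 24 reduced DOF indices of its 8 nodes (x, y, z interleaved).
    """

    dims: tuple[int, int, int]            # elements per axis
    active_nodes: np.ndarray              # bool over unique nodes (ex*ey*ez,)
    node_dof: np.ndarray                  # (n_unique,) first-dof index or -1
    element_dofs: np.ndarray              # (n_elem, 24) int32
    n_dof: int

    @property
    def n_unique_nodes(self) -> int:
        ex, ey, ez = self.dims
        return ex * ey * ez

    @property
    def n_active_nodes(self) -> int:
        return int(np.count_nonzero(self.active_nodes))


def _unique_node_ids(dims: tuple[int, int, int]) -> np.ndarray:
    """(ex+1, ey+1, ez+1) array of unique (wrapped) node ids."""
    ex, ey, ez = dims
    i = np.arange(ex + 1) % ex
    j = np.arange(ey + 1) % ey
    k = np.arange(ez + 1) % ez
    return (i[:, None, None] * ey + j[None, :, None]) * ez + k[None, None, :]


def build_periodic_dof_map(dims: tuple[int, int, int],
                           element_class: np.ndarray) -> PeriodicDofMap:
    """Reduced periodic numbering; nodes touching only void elements drop out.

    ``element_class`` is flat (n_elem,) in C order over the element grid.
    """
    ex, ey, ez = dims
    uid = _unique_node_ids(dims)
    n_unique = ex * ey * ez

    active = np.zeros(n_unique, dtype=bool)
    cls = np.asarray(element_class).reshape(ex, ey, ez)
    nonvoid = cls != ELEM_VOID
    for di, dj, dk in NODE_OFFSETS:
        ids = uid[di:di + ex, dj:dj + ey, dk:dk + ez]
        sel = ids[nonvoid]
        active[sel] = True

    node_dof = np.full(n_unique, -1, dtype=np.int64)
    node_dof[active] = 3 * np.arange(int(active.sum()))
    n_dof = 3 * int(active.sum())

    elem_dofs = np.full((ex * ey * ez, 24), -1, dtype=np.int64)
    for a, (di, dj, dk) in enumerate(NODE_OFFSETS):
        ids = uid[di:di + ex, dj:dj + ey, dk:dk + ez].ravel()
        base = node_dof[ids]
        for d in range(3):
            elem_dofs[:, 3 * a + d] = np.where(base >= 0, base + d, -1)

    return PeriodicDofMap(dims=dims, active_nodes=active, node_dof=node_dof,
                          element_dofs=elem_dofs, n_dof=n_dof)


def _scatter_add(mat_entries: np.ndarray, dofs: np.ndarray,
                 n_dof: int) -> sp.csr_matrix:
    """Assemble (n, 24, 24) element matrices into a CSR matrix."""
    n = mat_entries.shape[0]
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    vals = mat_entries.reshape(n, -1).ravel()
    keep = (rows >= 0) & (cols >= 0)
    A = sp.coo_matrix((vals[keep], (rows[keep], cols[keep])),
                      shape=(n_dof, n_dof))
    return A.tocsr()


def assemble_matrix(K_elems: np.ndarray, element_ids: np.ndarray,
                    dof_map: PeriodicDofMap, chunk: int = 8192) -> sp.csr_matrix:
    """Scatter-add element stiffness matrices into the reduced numbering."""
    n_dof = dof_map.n_dof
    K = sp.csr_matrix((n_dof, n_dof))
    for start in range(0, len(element_ids), chunk):
        sl = slice(start, start + chunk)
        if not np.all(np.isfinite(K_elems[sl])):
            bad = int(element_ids[sl][~np.isfinite(K_elems[sl]).all(axis=(1, 2))][0])
            raise FloatingPointError(f"non-finite stiffness in element {bad}")
        K = K + _scatter_add(K_elems[sl], dof_map.element_dofs[element_ids[sl]],
                             n_dof)
    return K


def assemble_system(K_elems: np.ndarray, F_elems: np.ndarray,
                    f_elems: np.ndarray, element_ids: np.ndarray,
                    dof_map: PeriodicDofMap,
                    ) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """Assemble K (sparse), the 6 mechanical load columns F, and the hygric f.

    ``element_ids`` selects which global elements the contribution arrays
    belong to (allows assembling class batches separately).
    """
    if not (np.all(np.isfinite(F_elems)) and np.all(np.isfinite(f_elems))):
        raise FloatingPointError("non-finite load contribution")
    K = assemble_matrix(K_elems, element_ids, dof_map)
    F = np.zeros((dof_map.n_dof, 6))
    f = np.zeros(dof_map.n_dof)
    dofs = dof_map.element_dofs[element_ids]
    valid = dofs >= 0
    for j in range(6):
        np.add.at(F[:, j], dofs[valid], F_elems[..., j][valid])
    np.add.at(f, dofs[valid], f_elems[valid])
    return K, F, f


def build_preconditioner(K_elems: np.ndarray, element_ids: np.ndarray,
                         dof_map: PeriodicDofMap, eps: float = 1e-13,
                         assembled_diag: np.ndarray | None = None,
                         chunk: int = 4096,
                         sym_tol: float = 1e-8) -> sp.csr_matrix:
    """Element-sum preconditioner from spectral pseudo-inverses.

    Each symmetric element matrix is decomposed as K^e = V diag(lambda) V^T;
    eigenvalues at or below lambda_th = eps * max(lambda) are dropped from
    the inverse, which removes rigid modes and round-off-negative sliver
    modes.  The pseudo-inverses are assembled like stiffness matrices.

    When ``assembled_diag`` (the diagonal of the assembled K) is supplied,
    each element inverse is weighted by the element's share of the assembled
    diagonal stiffness at every DOF (a partition of unity over elements).
    Without the weighting, a plain sum of inverses is dominated at shared
    nodes by the softest adjacent element, which under strong stiffness
    contrast makes the preconditioned spectrum worse than the original.
    """
    n_dof = dof_map.n_dof
    S = sp.csr_matrix((n_dof, n_dof))
    if assembled_diag is not None:
        dK = np.where(assembled_diag > 0, assembled_diag, 1.0)
    for start in range(0, len(element_ids), chunk):
        sl = slice(start, start + chunk)
        Ke = K_elems[sl]
        asym = np.abs(Ke - np.swapaxes(Ke, 1, 2)).max(axis=(1, 2))
        scale = np.abs(Ke).max(axis=(1, 2)) + 1e-300
        if np.any(asym / scale > sym_tol):
            raise ValueError("asymmetric element stiffness beyond tolerance")
        lam, V = np.linalg.eigh(0.5 * (Ke + np.swapaxes(Ke, 1, 2)))
        lam_th = eps * lam.max(axis=1, keepdims=True)
        inv = np.where(lam > lam_th, 1.0 / np.where(lam > lam_th, lam, 1.0), 0.0)
        Kinv = np.einsum("nik,nk,njk->nij", V, inv, V)
        dofs = dof_map.element_dofs[element_ids[sl]]
        if assembled_diag is not None:
            de = np.einsum("nii->ni", Ke)
            w = np.where(dofs >= 0, de / dK[np.maximum(dofs, 0)], 0.0)
            Kinv = w[:, :, None] * Kinv * w[:, None, :]
        S = S + _scatter_add(Kinv, dofs, n_dof)
    return S


class TwoLevelPreconditioner:
    """Element-sum preconditioner augmented with a coarse correction.

    The element-wise spectral pseudo-inverses control the high-frequency
    and cut-element sliver modes, but they annihilate every per-element
    rigid mode, so the assembled sum transfers no energy along smooth,
    nearly-rigid deformation patterns and plain PCG stagnates on meshes of
    more than a few thousand elements.  A standard additive coarse-grid
    correction restores those components: active nodes are grouped into
    cubic aggregates, the coarse space W holds one rigid translation per
    aggregate and component, and the correction solves the Galerkin coarse
    operator W^T K W directly,

        z = S r + W (W^T K W)^{-1} W^T r.
    """

    def __init__(self, S: sp.spmatrix, K: sp.spmatrix,
                 dof_map: PeriodicDofMap, aggregate: int = 4):
        self.S = S
        ex, ey, ez = dof_map.dims
        act = np.flatnonzero(dof_map.active_nodes)
        ii = act // (ey * ez)
        jj = (act // ez) % ey
        kk = act % ez
        nax, nay = -(-ex // aggregate), -(-ey // aggregate)
        naz = -(-ez // aggregate)
        agg = (ii // aggregate) * nay * naz + (jj // aggregate) * naz \
            + (kk // aggregate)
        uniq, agg_idx = np.unique(agg, return_inverse=True)
        n_dof = dof_map.n_dof
        rows = np.arange(n_dof)
        cols = np.repeat(agg_idx * 3, 3) + np.tile([0, 1, 2], len(act))
        W = sp.coo_matrix((np.ones(n_dof), (rows, cols)),
                          shape=(n_dof, 3 * len(uniq))).tocsr()
        Kc = (W.T @ K @ W).tocsc()
        # tiny shift guards the singular translation block of the coarse op
        shift = 1e-12 * abs(Kc.diagonal()).max()
        self._lu = splu(Kc + shift * sp.eye(Kc.shape[0], format="csc"))
        self.W = W

    def __matmul__(self, r: np.ndarray) -> np.ndarray:
        return self.S @ r + self.W @ self._lu.solve(self.W.T @ r)


# --------------------------------------------------------------------------
# preconditioned conjugate gradients with translation projection
# --------------------------------------------------------------------------

def _project_translations(x: np.ndarray) -> np.ndarray:
    """Remove the per-component mean (rigid translation) in place."""
    v = x.reshape(-1, 3)
    v -= v.mean(axis=0, keepdims=True)
    return x


def pcg(K: sp.spmatrix, b: np.ndarray, S: sp.spmatrix | None = None,
        tol: float = 1e-8, max_iter: int | None = None,
        project=_project_translations) -> tuple[np.ndarray, dict]:
    """Left-preconditioned CG on the zero-mean (translation-free) subspace.

    Returns (x, diagnostics).  ``S`` is applied as a sparse operator;
    ``project`` removes the nullspace component from residuals and iterates
    each iteration so K stays SPD on the working subspace.
    """
    n = K.shape[0]
    if max_iter is None:
        max_iter = max(200, int(10 * np.sqrt(n)))
    b = project(b.astype(np.float64).copy())
    nb = np.linalg.norm(b)
    x = np.zeros(n)
    if nb == 0:
        return x, {"iterations": 0, "converged": True, "relres": 0.0,
                   "residual_history": [0.0]}
    r = b.copy()
    z = S @ r if S is not None else r.copy()
    project(z)
    p = z.copy()
    rz = r @ z
    history = [1.0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Kp = K @ p
        project(Kp)
        denom = p @ Kp
        if denom <= 0:
            break  # lost positive definiteness numerically; return best iterate
        alpha = rz / denom
        x += alpha * p
        r -= alpha * Kp
        project(r)
        relres = np.linalg.norm(r) / nb
        history.append(float(relres))
        if relres <= tol:
            converged = True
            break
        z = S @ r if S is not None else r.copy()
        project(z)
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    project(x)
    return x, {"iterations": it, "converged": converged,
               "relres": history[-1], "residual_history": history}


@dataclass
class CellProblemSolution:
    """Nodal influence functions on the reduced periodic DOFs.

    ``N`` (n_dof, 6): mechanical fluctuation fields per unit macroscopic
    strain (Voigt order); ``b`` (n_dof,): hygric fluctuation field.
    """

    N: np.ndarray
    b: np.ndarray
    dof_map: PeriodicDofMap
    diagnostics: list = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(d["converged"] for d in self.diagnostics)

    def element_values(self, element_ids: np.ndarray | None = None) -> np.ndarray:
        """Per-element nodal values, shape (n_elem, 24, 7) (6 mech + hygric)."""
        dofs = self.dof_map.element_dofs
        if element_ids is not None:
            dofs = dofs[element_ids]
        fields = np.concatenate([self.N, self.b[:, None]], axis=1)  # (ndof, 7)
        out = np.zeros(dofs.shape + (7,))
        valid = dofs >= 0
        out[valid] = fields[dofs[valid]]
        return out


def solve_cell_problems(K: sp.spmatrix, F: np.ndarray, f: np.ndarray,
                        S: sp.spmatrix | None, dof_map: PeriodicDofMap,
                        tol: float = 1e-8, max_iter: int | None = None,
                        node_volume: np.ndarray | None = None,
                        ) -> CellProblemSolution:
    """Solve the 6 mechanical and 1 hygric cell problems with PCG.

    Each fluctuation field is post-shifted to a zero volume average using
    the nodal tributary volumes (uniform over active nodes when not given).
    """
    N = np.zeros((dof_map.n_dof, 6))
    diags = []
    for j in range(6):
        N[:, j], d = pcg(K, -F[:, j], S, tol=tol, max_iter=max_iter)
        d["rhs"] = f"mech_{j}"
        diags.append(d)
    b, d = pcg(K, f, S, tol=tol, max_iter=max_iter)
    d["rhs"] = "hygric"
    diags.append(d)

    # tributary-volume-weighted zero mean (uniqueness constraint)
    if node_volume is None:
        w = np.ones(dof_map.n_active_nodes)
    else:
        w = np.asarray(node_volume, dtype=float)
    w = w / w.sum()
    for j in range(6):
        v = N[:, j].reshape(-1, 3)
        v -= (w[:, None] * v).sum(axis=0, keepdims=True)
    vb = b.reshape(-1, 3)
    vb -= (w[:, None] * vb).sum(axis=0, keepdims=True)

    return CellProblemSolution(N=N, b=b, dof_map=dof_map, diagnostics=diags)


def solve_dense(K: sp.spmatrix, rhs: np.ndarray) -> np.ndarray:
    """Direct least-squares solve (dense) for small oracle meshes.

    Returns the minimum-norm solution, which lies in the zero-mean subspace
    up to the rigid-translation component removed afterwards.
    """
    Kd = K.toarray()
    x, *_ = np.linalg.lstsq(Kd, rhs, rcond=None)
    if x.ndim == 1:
        _project_translations(x)
    else:
        for j in range(x.shape[1]):
            _project_translations(x[:, j])
    return x
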
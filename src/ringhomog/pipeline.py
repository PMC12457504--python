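"""End-to-end orchestration: level set -> materials -> solve -> homogenize.

``solve_homogenization`` is the core entry point used by the command-line
interface, the acceptance script and the tests: given a signed-distance
field on the (already periodized) voxel grid plus cell-type labels, it
builds the orientation and material fields, classifies and integrates the
elements, assembles the periodic system and its element-sum preconditioner,
solves the seven cell problems and returns the effective properties along
with every intermediate needed for field reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import (AXIAL_CELL_WALL, RAY_CELL_WALL, CellWallParams,
                        MaterialField, MoistureScaling, build_material_field,
                        compute_orientation)
from .homogenization import (EffectiveProperties, LocalFields, homogenize,
                             reconstruct_fields)
from .segmentation import LevelSetField
from .solver import (CellProblemSolution, PeriodicDofMap,
                     TwoLevelPreconditioner, assemble_system,
                     build_periodic_dof_map, build_preconditioner,
                     solve_cell_problems)
from .xfem import (ELEM_CUT, ELEM_SOLID, ELEM_VOID, NODE_OFFSETS,
                   StructuredHexMesh, classify_elements, element_B_stack,
                   gather_nodal_phi, gauss_rule, integrate_elements_batch,
                   moment_fit_weights_batch, nodal_phi_from_voxel)

__all__ = ["HomogenizationResult", "solve_homogenization"]


@dataclass
class HomogenizationResult:
    """Everything produced by one cell-problem solve."""

    mesh: StructuredHexMesh
    element_class: np.ndarray           # flat, effective classes
    cut_weights: np.ndarray             # (n_cut, n_i) moment-fitted
    materials: MaterialField
    dof_map: PeriodicDofMap
    solution: CellProblemSolution
    effective: EffectiveProperties
    p_q: int

    def local_fields(self, delta_m: float, mode: str) -> LocalFields:
        """Strain/stress under a moisture step (free or constrained)."""
        return reconstruct_fields(self.solution, self.materials, self.mesh,
                                  self.element_class, self.cut_weights,
                                  delta_m, mode,
                                  beta_bar=self.effective.beta_bar,
                                  p_q=self.p_q)


def _node_tributary_volume(dof_map: PeriodicDofMap,
                           element_class: np.ndarray,
                           voxel_volume: float) -> np.ndarray:
    """Per active node: 1/8 of the volume of adjacent non-void elements."""
    ex, ey, ez = dof_map.dims
    counts = np.zeros(dof_map.n_unique_nodes)
    nonvoid = (np.asarray(element_class).reshape(ex, ey, ez) != ELEM_VOID)
    i = np.arange(ex + 1) % ex
    j = np.arange(ey + 1) % ey
    k = np.arange(ez + 1) % ez
    uid = (i[:, None, None] * ey + j[None, :, None]) * ez + k[None, None, :]
    for di, dj, dk in NODE_OFFSETS:
        ids = uid[di:di + ex, dj:dj + ey, dk:dk + ez][nonvoid]
        np.add.at(counts, ids, voxel_volume / 8.0)
    return counts[dof_map.active_nodes]


def solve_homogenization(phi: LevelSetField,
                         cell_type: np.ndarray,
                         spacing_um: float,
                         boundary_layer: np.ndarray | None = None,
                         moisture: float = 12.0,
                         scaling: MoistureScaling | None = None,
                         axial: CellWallParams = AXIAL_CELL_WALL,
                         ray: CellWallParams = RAY_CELL_WALL,
                         p_q: int = 2,
                         n_c: int = 1000,
                         tol: float = 1e-8,
                         max_iter: int | None = None,
                         precond_eps: float = 1e-13,
                         use_preconditioner: bool = True,
                         coarse_aggregate: int = 4,
                         ) -> HomogenizationResult:
    """Solve the periodic cell problems for one meso-structure.

    ``phi`` lives on the voxel grid (one element per voxel) of an already
    periodized domain; ``cell_type`` supplies per-voxel axial/ray/void
    labels.  Lengths are converted to mm internally so stresses come out in
    MPa (N/mm^2).
    """
    dims = phi.phi.shape
    h_mm = spacing_um / 1000.0
    mesh = StructuredHexMesh(dims=dims, spacing_mm=(h_mm, h_mm, h_mm))

    orientation = compute_orientation(phi, cell_type)
    materials = build_material_field(orientation, moisture=moisture,
                                     scaling=scaling, axial=axial, ray=ray,
                                     boundary_layer=boundary_layer)

    phi_nodal = nodal_phi_from_voxel(phi.phi, periodic=True)
    phi_elem = gather_nodal_phi(phi_nodal)
    cls = classify_elements(phi_elem)

    cut_ids = np.flatnonzero(cls == ELEM_CUT)
    cut_weights = moment_fit_weights_batch(phi_elem[cut_ids], p_q=p_q, n_c=n_c) \
        if cut_ids.size else np.zeros((0, (p_q + 1) ** 3))
    # cut elements whose sub-cell Heaviside field is identically zero carry
    # no stiffness: demote to void so their nodes can be deactivated
    empty = ~np.any(cut_weights != 0.0, axis=1)
    if np.any(empty):
        cls[cut_ids[empty]] = ELEM_VOID
        cut_ids = cut_ids[~empty]
        cut_weights = cut_weights[~empty]
    # elements labelled void by the material field but solid by phi would
    # contribute zero stiffness rows; demote them as well
    zeroC = ~np.any(materials.C.reshape(len(cls), -1) != 0.0, axis=1)
    cls[zeroC & (cls != ELEM_VOID)] = ELEM_VOID
    keep = cls[cut_ids] == ELEM_CUT
    cut_ids, cut_weights = cut_ids[keep], cut_weights[keep]

    dof_map = build_periodic_dof_map(dims, cls)
    det_j = mesh.det_jacobian

    import scipy.sparse as sp
    K = sp.csr_matrix((dof_map.n_dof, dof_map.n_dof))
    S = sp.csr_matrix((dof_map.n_dof, dof_map.n_dof)) if use_preconditioner else None
    F = np.zeros((dof_map.n_dof, 6))
    fh = np.zeros(dof_map.n_dof)

    batches = []
    solid_ids = np.flatnonzero(cls == ELEM_SOLID)
    if solid_ids.size:
        rule = gauss_rule(2)
        batches.append((solid_ids, rule.weights,
                        element_B_stack(rule.points, mesh.spacing_mm)))
    if cut_ids.size:
        rule = gauss_rule(p_q + 1)
        batches.append((cut_ids, cut_weights,
                        element_B_stack(rule.points, mesh.spacing_mm)))

    chunk = 4096
    for ids, weights, B in batches:
        w_all = np.asarray(weights, dtype=float)
        for s in range(0, ids.size, chunk):
            sel = ids[s:s + chunk]
            w = w_all if w_all.ndim == 1 else w_all[s:s + chunk]
            Ke, Fe, fe = integrate_elements_batch(materials.C[sel],
                                                  materials.beta[sel],
                                                  w, B, det_j)
            Kc, Fc, fc = assemble_system(Ke, Fe, fe, sel, dof_map)
            K = K + Kc
            F += Fc
            fh += fc

    if use_preconditioner:
        # second pass: element pseudo-inverses weighted by each element's
        # share of the assembled diagonal stiffness
        diag_K = np.asarray(K.diagonal())
        for ids, weights, B in batches:
            w_all = np.asarray(weights, dtype=float)
            for s in range(0, ids.size, chunk):
                sel = ids[s:s + chunk]
                w = w_all if w_all.ndim == 1 else w_all[s:s + chunk]
                Ke, _, _ = integrate_elements_batch(materials.C[sel],
                                                    materials.beta[sel],
                                                    w, B, det_j)
                S = S + build_preconditioner(Ke, sel, dof_map,
                                             eps=precond_eps,
                                             assembled_diag=diag_K)
        S = TwoLevelPreconditioner(S, K, dof_map, aggregate=coarse_aggregate)
    node_vol = _node_tributary_volume(dof_map, cls, det_j * 8.0)
    solution = solve_cell_problems(K, F, fh, S, dof_map, tol=tol,
                                   max_iter=max_iter, node_volume=node_vol)
    effective = homogenize(solution, materials, mesh, cls, cut_weights, p_q=p_q)
    return HomogenizationResult(mesh=mesh, element_class=cls,
                                cut_weights=cut_weights, materials=materials,
                                dof_map=dof_map, solution=solution,
                                effective=effective, p_q=p_q)
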
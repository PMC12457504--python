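"""Effective hygro-elastic tensors and local field reconstruction.

From the converged cell-problem solutions the effective stiffness and
hygro-expansion follow as the quadrature-discretized unit-cell averages

    C_bar = (1/|Q|) sum_e sum_i w_i detJ  C(x_i) : (grad N1(x_i) + I_S),
    beta_bar = C_bar^{-1} (1/|Q|) sum_e sum_i w_i detJ  C(x_i) : (beta - grad b1),

with |Q| the total cell volume including voids, standard Gauss weights on
solid elements and moment-fitted weights on cut elements.  Engineering
constants (E_R, E_T, E_L, Poisson's ratios, shear moduli) are read off the
inverse of C_bar under the orthotropic parameterization; the residual of
the entries that orthotropy sets to zero is reported rather than forced
away.  Local strain/stress fields under a moisture step are reconstructed
per element in a free-expansion mode (zero average stress) or a
constrained-expansion mode (zero average strain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialField
from .solver import CellProblemSolution
from .xfem import (ELEM_CUT, ELEM_SOLID, StructuredHexMesh, element_B_stack,
                   gauss_rule)

__all__ = [
    "EffectiveProperties",
    "homogenize",
    "extract_orthotropic_constants",
    "LocalFields",
    "reconstruct_fields",
]

_CHUNK = 4096


@dataclass
class EffectiveProperties:
    """Homogenized stiffness (MPa), expansion (eng. Voigt) and constants."""

    C_bar: np.ndarray        # (6, 6) MPa
    beta_bar: np.ndarray     # (6,) %/% in engineering Voigt form
    constants: dict          # engineering constants, MPa and dimensionless
    orthotropy_residual: float

    @property
    def beta_R(self) -> float:
        return float(self.beta_bar[0])

    @property
    def beta_T(self) -> float:
        return float(self.beta_bar[1])

    @property
    def beta_L(self) -> float:
        return float(self.beta_bar[2])


def _class_batches(element_class: np.ndarray, cut_weights: np.ndarray,
                   mesh: StructuredHexMesh, p_q: int):
    """Yield (element_ids, weights, B-stack) per element class."""
    cls = np.asarray(element_class).ravel()
    h = mesh.spacing_mm
    solid_ids = np.flatnonzero(cls == ELEM_SOLID)
    if solid_ids.size:
        rule = gauss_rule(2)
        yield solid_ids, rule.weights, element_B_stack(rule.points, h)
    cut_ids = np.flatnonzero(cls == ELEM_CUT)
    if cut_ids.size:
        rule = gauss_rule(p_q + 1)
        yield cut_ids, cut_weights, element_B_stack(rule.points, h)


def homogenize(solution: CellProblemSolution, materials: MaterialField,
               mesh: StructuredHexMesh, element_class: np.ndarray,
               cut_weights: np.ndarray, p_q: int = 2) -> EffectiveProperties:
    """Unit-cell averages of the influence-function gradients.

    ``cut_weights`` holds the moment-fitted weights of the cut elements in
    the order produced by ``np.flatnonzero(element_class == ELEM_CUT)``.
    Raises if the resulting stiffness is not symmetric positive definite
    (the spectrum is included in the message).
    """
    det_j = mesh.det_jacobian
    vol = mesh.volume
    C_bar = np.zeros((6, 6))
    y_hyg = np.zeros(6)

    for ids, weights, B in _class_batches(element_class, cut_weights, mesh, p_q):
        w_all = np.asarray(weights, dtype=float)
        for s in range(0, ids.size, _CHUNK):
            sel = ids[s:s + _CHUNK]
            w = w_all if w_all.ndim == 1 else w_all[s:s + _CHUNK]
            C = materials.C[sel]
            beta = materials.beta[sel]
            vals = solution.element_values(sel)          # (n, 24, 7)
            # strain of each fluctuation column at each quadrature point
            E = np.einsum("ibk,nkj->nibj", B, vals)      # (n, npts, 6, 7)
            if w_all.ndim == 1:
                wsum = np.full(len(sel), w.sum())
                CE = np.einsum("i,nab,nibj->naj", w, C, E)
            else:
                wsum = w.sum(axis=1)
                CE = np.einsum("ni,nab,nibj->naj", w, C, E)
            C_bar += det_j * (CE[:, :, :6].sum(axis=0)
                              + np.einsum("n,nab->ab", wsum, C))
            y_hyg += det_j * (np.einsum("n,nab,nb->a", wsum, C, beta)
                              - CE[:, :, 6].sum(axis=0))

    C_bar /= vol
    y_hyg /= vol
    C_bar_sym = 0.5 * (C_bar + C_bar.T)
    eig = np.linalg.eigvalsh(C_bar_sym)
    if eig.min() <= 0:
        raise ValueError("effective stiffness is not positive definite; "
                         f"spectrum: {np.array2string(eig, precision=4)}")
    beta_bar = np.linalg.solve(C_bar, y_hyg)
    constants, residual = extract_orthotropic_constants(C_bar)
    return EffectiveProperties(C_bar=C_bar, beta_bar=beta_bar,
                               constants=constants,
                               orthotropy_residual=residual)


def extract_orthotropic_constants(C_bar: np.ndarray) -> tuple[dict, float]:
    """Engineering constants from the inverse of the effective stiffness.

    Returns ``(constants, residual)``: moduli in the units of ``C_bar``
    (MPa in the pipeline), and the relative norm of the compliance entries
    that exact orthotropy would set to zero (normal-shear and shear-shear
    couplings).  Constants are read from the orthotropic pattern even when
    the residual is nonzero.
    """
    D = np.linalg.inv(C_bar)
    E_R, E_T, E_L = 1.0 / D[0, 0], 1.0 / D[1, 1], 1.0 / D[2, 2]
    Dsym = 0.5 * (D + D.T)
    constants = {
        "E_R": E_R, "E_T": E_T, "E_L": E_L,
        "nu_RT": -Dsym[0, 1] * E_R,
        "nu_RL": -Dsym[0, 2] * E_R,
        "nu_TL": -Dsym[1, 2] * E_T,
        "G_LT": 1.0 / D[3, 3],
        "G_LR": 1.0 / D[4, 4],
        "G_RT": 1.0 / D[5, 5],
    }
    # ratios implied by compliance symmetry
    constants["nu_TR"] = constants["nu_RT"] * E_T / E_R
    constants["nu_LR"] = constants["nu_RL"] * E_L / E_R
    constants["nu_LT"] = constants["nu_TL"] * E_L / E_T
    off = np.concatenate([D[:3, 3:].ravel(),
                          D[3:, 3:][~np.eye(3, dtype=bool)].ravel()])
    residual = float(np.linalg.norm(off) / np.linalg.norm(D))
    return constants, residual


@dataclass
class LocalFields:
    """Element-center strain/stress on solid and cut elements.

    Strains are engineering Voigt in percent elongation (the natural unit
    when hygro-expansion coefficients are % strain per % moisture content
    and the moisture step is in %); stresses are in MPa (= N/mm^2), i.e.
    the percent strains are converted to absolute strain inside the
    constitutive law.  The quadrature-consistent unit-cell averages
    (normalized by the total cell volume, voids included) are stored
    alongside.
    """

    element_ids: np.ndarray
    strain: np.ndarray       # (n, 6)
    stress: np.ndarray       # (n, 6)
    mode: str
    delta_m: float
    avg_strain: np.ndarray   # (6,)
    avg_stress: np.ndarray   # (6,)


def reconstruct_fields(solution: CellProblemSolution, materials: MaterialField,
                       mesh: StructuredHexMesh, element_class: np.ndarray,
                       cut_weights: np.ndarray, delta_m: float,
                       mode: str, beta_bar: np.ndarray | None = None,
                       p_q: int = 2) -> LocalFields:
    """Meso-scale strain and stress under a macroscopic moisture step.

    Constrained expansion (zero average deformation): eps = grad b1 dm.
    Free expansion (zero average stress): eps = (beta_bar + grad N1 :
    beta_bar + grad b1) dm, requiring the effective expansion vector.
    Stress follows the local law sigma = C : (eps - beta dm), with the
    percent strains converted to absolute strain (factor 1/100) so that
    stresses come out in MPa.  Values are evaluated at element centers;
    averages use the element quadrature.
    """
    if mode not in ("free", "constrained"):
        raise ValueError(f"unknown loading mode {mode!r}")
    if mode == "free":
        if beta_bar is None:
            raise ValueError("free expansion requires beta_bar")
        beta_bar = np.asarray(beta_bar, dtype=float)

    det_j = mesh.det_jacobian
    vol = mesh.volume
    B0 = element_B_stack(np.zeros((1, 3)), mesh.spacing_mm)  # center
    ids_all, strains, stresses = [], [], []
    avg_e = np.zeros(6)
    avg_s = np.zeros(6)

    for ids, weights, B in _class_batches(element_class, cut_weights, mesh, p_q):
        w_all = np.asarray(weights, dtype=float)
        for s in range(0, ids.size, _CHUNK):
            sel = ids[s:s + _CHUNK]
            w = w_all if w_all.ndim == 1 else w_all[s:s + _CHUNK]
            C = materials.C[sel]
            beta = materials.beta[sel]
            vals = solution.element_values(sel)             # (n, 24, 7)
            if mode == "constrained":
                coef = vals[:, :, 6]                        # b1 column
                base = np.zeros(6)
            else:
                coef = vals[:, :, :6] @ beta_bar + vals[:, :, 6]
                base = beta_bar
            # element centers; percent strain -> absolute inside the law
            e_c = delta_m * (base[None, :]
                             + np.einsum("bk,nk->nb", B0[0], coef))
            s_c = 0.01 * np.einsum("nab,nb->na", C, e_c - delta_m * beta)
            ids_all.append(sel)
            strains.append(e_c)
            stresses.append(s_c)
            # quadrature averages
            Eq = delta_m * (base[None, None, :]
                            + np.einsum("ibk,nk->nib", B, coef))
            Sq = 0.01 * np.einsum("nab,nib->nia", C,
                                  Eq - delta_m * beta[:, None, :])
            if w_all.ndim == 1:
                avg_e += det_j * np.einsum("i,nib->b", w, Eq)
                avg_s += det_j * np.einsum("i,nia->a", w, Sq)
            else:
                avg_e += det_j * np.einsum("ni,nib->b", w, Eq)
                avg_s += det_j * np.einsum("ni,nia->a", w, Sq)

    return LocalFields(element_ids=np.concatenate(ids_all) if ids_all else
                       np.empty(0, dtype=int),
                       strain=np.concatenate(strains) if strains else
                       np.empty((0, 6)),
                       stress=np.concatenate(stresses) if stresses else
                       np.empty((0, 6)),
                       mode=mode, delta_m=delta_m,
                       avg_strain=avg_e / vol, avg_stress=avg_s / vol)
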
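"""Moisture-dependent orthotropic cell-wall materials in rotated frames.

Cell walls are homogenized orthotropic solids described by nine elastic
constants (E1, E2, E3, nu12, nu13, nu23, G12, G13, G23) and three
hygro-expansion coefficients (beta1, beta2, beta3, % strain per % moisture
content) in a local (1, 2, 3) frame whose 3-axis runs along the cell:
longitudinal (global z) for axial cells, radial (global x) for ray cells.
The in-plane orientation angle alpha of the local 1-axis is recovered from
the spatial gradient of the signed-distance level set,

    alpha = arctan(-phi_,x / phi_,y)        (axial cells, x-y slice)

evaluated by central differences at the element center, and the local
stiffness/expansion tensors are rotated to the global meso frame.

Voigt convention used throughout: component order (11, 22, 33, 23, 13, 12)
with engineering shear strains (gamma = 2 eps); stiffness in MPa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .phantom import CELL_AXIAL, CELL_RAY, CELL_VOID
from .segmentation import LevelSetField

__all__ = [
    "CellWallParams",
    "AXIAL_CELL_WALL",
    "RAY_CELL_WALL",
    "MoistureScaling",
    "build_cell_wall_material",
    "OrientationField",
    "compute_orientation",
    "rotation_matrix",
    "bond_stress_matrix",
    "rotate_material",
    "MaterialField",
    "build_material_field",
]


@dataclass(frozen=True)
class CellWallParams:
    """Orthotropic hygro-elastic constants of one cell-wall type.

    Moduli in GPa, Poisson's ratios dimensionless, hygro-expansion in
    % strain per % moisture content, referenced to ``reference_moisture``
    (% moisture content).
    """

    E1: float
    E2: float
    E3: float
    nu23: float
    nu13: float
    nu12: float
    G23: float
    G13: float
    G12: float
    beta1: float
    beta2: float
    beta3: float
    cell_type: str = "axial"
    reference_moisture: float = 12.0

    def __post_init__(self) -> None:
        if min(self.E1, self.E2, self.E3, self.G12, self.G13, self.G23) <= 0:
            raise ValueError("elastic moduli must be positive")


# Reference cell-wall properties at 12% moisture content (GPa, -, %/%),
# from a nano-to-meso multi-scale model with a 20 degree S2 microfibril angle.
AXIAL_CELL_WALL = CellWallParams(E1=5.8, E2=3.7, E3=18.3,
                                 nu23=0.02, nu13=0.19, nu12=0.24,
                                 G23=1.2, G13=4.4, G12=1.0,
                                 beta1=0.16, beta2=0.40, beta3=0.01,
                                 cell_type="axial")
RAY_CELL_WALL = CellWallParams(E1=4.9, E2=3.5, E3=13.0,
                               nu23=0.01, nu13=0.30, nu12=0.21,
                               G23=1.1, G13=5.6, G12=1.0,
                               beta1=0.17, beta2=0.43, beta3=0.00,
                               cell_type="ray")

_SCALABLE = ("E1", "E2", "E3", "nu23", "nu13", "nu12",
             "G23", "G13", "G12", "beta1", "beta2", "beta3")


@dataclass
class MoistureScaling:
    """Tabulated per-parameter multipliers versus moisture content.

    ``tables`` maps a parameter name to ``(m_grid_percent, multiplier)``
    arrays.  On construction each table is renormalized so the multiplier is
    exactly 1 at the reference moisture; parameters without a table are left
    unscaled.  Interpolation is linear and must stay inside the table hull.
    """

    tables: dict = field(default_factory=dict)
    reference_moisture: float = 12.0

    def __post_init__(self) -> None:
        norm = {}
        for name, (m, s) in self.tables.items():
            m = np.asarray(m, dtype=float)
            s = np.asarray(s, dtype=float)
            if np.any(s <= 0):
                raise ValueError(f"multipliers for {name} must be positive")
            ref = np.interp(self.reference_moisture, m, s)
            if not (m.min() <= self.reference_moisture <= m.max()):
                raise ValueError(f"table for {name} must bracket the "
                                 "reference moisture")
            norm[name] = (m, s / ref)
        self.tables = norm

    def factor(self, name: str, m: float) -> float:
        if name not in self.tables:
            return 1.0
        grid, s = self.tables[name]
        if not (grid.min() <= m <= grid.max()):
            raise ValueError(f"moisture {m}% outside the table hull for {name}")
        return float(np.interp(m, grid, s))

    def apply(self, p: CellWallParams, m: float) -> CellWallParams:
        scaled = {name: getattr(p, name) * self.factor(name, m)
                  for name in _SCALABLE}
        return replace(p, **scaled)


def orthotropic_compliance(p: CellWallParams) -> np.ndarray:
    """6x6 compliance (1/GPa) in Voigt order (11,22,33,23,13,12), eng. shear."""
    D = np.zeros((6, 6))
    D[0, 0] = 1.0 / p.E1
    D[1, 1] = 1.0 / p.E2
    D[2, 2] = 1.0 / p.E3
    D[0, 1] = D[1, 0] = -p.nu12 / p.E1
    D[0, 2] = D[2, 0] = -p.nu13 / p.E1
    D[1, 2] = D[2, 1] = -p.nu23 / p.E2
    D[3, 3] = 1.0 / p.G23
    D[4, 4] = 1.0 / p.G13
    D[5, 5] = 1.0 / p.G12
    return D


def build_cell_wall_material(p: CellWallParams, m: float | None = None,
                             scaling: MoistureScaling | None = None,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Local-frame stiffness (6x6, MPa) and hygro-expansion (3-vector).

    Assembles the orthotropic compliance, optionally scales the parameters
    to moisture content ``m`` via the tabulated multipliers, and inverts to
    stiffness.  Raises if the scaled parameter set is not positive definite,
    naming the offending eigenvalue.
    """
    if m is not None and scaling is not None:
        p = scaling.apply(p, m)
    D = orthotropic_compliance(p)
    eig = np.linalg.eigvalsh(D)
    if np.min(eig) <= 0:
        raise ValueError("cell-wall stiffness not positive definite: "
                         f"compliance eigenvalue {np.min(eig):.3e} <= 0")
    C = np.linalg.inv(D) * 1e3  # GPa -> MPa
    beta = np.array([p.beta1, p.beta2, p.beta3])
    return C, beta


# --------------------------------------------------------------------------
# orientation field from the level-set gradient
# --------------------------------------------------------------------------

@dataclass
class OrientationField:
    """Per-element in-plane angle (radians) about the cell extrusion axis."""

    alpha: np.ndarray       # (-pi/2, pi/2], one value per element
    cell_type: np.ndarray   # uint8 CELL_* codes per element
    valid: np.ndarray       # False where the gradient was degenerate


def _wrap_half_pi(a: np.ndarray) -> np.ndarray:
    """Reduce a director angle to (-pi/2, pi/2]."""
    a = np.mod(a + np.pi / 2, np.pi) - np.pi / 2
    return np.where(a == -np.pi / 2, np.pi / 2, a)


def compute_orientation(phi: LevelSetField, cell_type: np.ndarray,
                        eps_grad: float | None = None) -> OrientationField:
    """Material orientation angles from central differences of phi.

    Axial elements use the x-y slice gradient (3-axis along z); ray elements
    use the y-z slice gradient (3-axis along x).  Elements where the
    in-plane gradient magnitude falls below ``eps_grad`` (default 1e-6 x
    spacing) are marked invalid and filled with the most common angle among
    their valid 26-neighbors, falling back to alpha = 0 with a warning.
    One element per voxel: the element center is the voxel center at which
    phi lives.
    """
    f = phi.phi
    h = phi.spacing
    if eps_grad is None:
        eps_grad = 1e-6 * h
    gx, gy, gz = np.gradient(f, h)

    cell_type = np.asarray(cell_type, dtype=np.uint8)
    alpha = np.zeros(f.shape)
    valid = np.zeros(f.shape, dtype=bool)

    ax = cell_type == CELL_AXIAL
    norm_ax = np.hypot(gx, gy)
    alpha_ax = _wrap_half_pi(np.arctan2(-gx, gy))
    valid[ax] = norm_ax[ax] >= eps_grad
    alpha[ax] = alpha_ax[ax]

    ry = cell_type == CELL_RAY
    norm_ry = np.hypot(gy, gz)
    alpha_ry = _wrap_half_pi(np.arctan2(-gy, gz))
    valid[ry] = norm_ry[ry] >= eps_grad
    alpha[ry] = alpha_ry[ry]

    # fill invalid solid elements from the mode of their valid 26-neighbors
    solid = cell_type != CELL_VOID
    bad = solid & ~valid
    if np.any(bad):
        _fill_by_neighbor_mode(alpha, valid, bad)
        still_bad = solid & ~valid
        if np.any(still_bad):
            warnings.warn(f"{int(np.count_nonzero(still_bad))} elements have a "
                          "degenerate level-set gradient and no valid neighbor; "
                          "their orientation defaults to alpha = 0",
                          RuntimeWarning, stacklevel=2)
            alpha[still_bad] = 0.0
    alpha[~solid] = 0.0
    return OrientationField(alpha=alpha, cell_type=cell_type, valid=valid)


def _fill_by_neighbor_mode(alpha: np.ndarray, valid: np.ndarray,
                           bad: np.ndarray) -> int:
    """In-place: set invalid entries to the mode of valid 26-neighbor angles."""
    idx = np.argwhere(bad)
    shape = alpha.shape
    n_filled = 0
    new_vals = {}
    for i, j, k in idx:
        sl = (slice(max(i - 1, 0), min(i + 2, shape[0])),
              slice(max(j - 1, 0), min(j + 2, shape[1])),
              slice(max(k - 1, 0), min(k + 2, shape[2])))
        vals = alpha[sl][valid[sl]]
        if vals.size:
            # mode on a 1-degree grid; directors near +-pi/2 are identified
            q = np.round(np.degrees(vals)).astype(int)
            q[q == -90] = 90
            counts = np.bincount(q - q.min())
            new_vals[(i, j, k)] = np.radians(q.min() + np.argmax(counts))
            n_filled += 1
    for (i, j, k), v in new_vals.items():
        alpha[i, j, k] = v
        valid[i, j, k] = True
    return n_filled


# --------------------------------------------------------------------------
# coordinate transformation (Bond matrices)
# --------------------------------------------------------------------------

def rotation_matrix(alpha: np.ndarray, cell_type_code: int) -> np.ndarray:
    """3x3 rotation(s) taking the local (1,2,3) frame to global (x,y,z).

    Columns are the local axes expressed in global coordinates.  Axial cells:
    3-axis along z, 1-axis at angle alpha from x in the x-y plane.  Ray
    cells: 3-axis along x, 1-axis at angle alpha from y in the y-z plane.
    Broadcasts over alpha; returns shape alpha.shape + (3, 3).
    """
    alpha = np.asarray(alpha, dtype=float)
    c, s = np.cos(alpha), np.sin(alpha)
    R = np.zeros(alpha.shape + (3, 3))
    if cell_type_code == CELL_AXIAL:
        R[..., 0, 0] = c
        R[..., 1, 0] = s
        R[..., 0, 1] = -s
        R[..., 1, 1] = c
        R[..., 2, 2] = 1.0
    elif cell_type_code == CELL_RAY:
        R[..., 1, 0] = c
        R[..., 2, 0] = s
        R[..., 1, 1] = -s
        R[..., 2, 1] = c
        R[..., 0, 2] = 1.0
    else:
        raise ValueError(f"no material frame for cell-type code {cell_type_code}")
    return R


def bond_stress_matrix(R: np.ndarray) -> np.ndarray:
    """6x6 Bond transformation for stress-like Voigt vectors.

    For C in the engineering-shear Voigt convention (order 11,22,33,23,13,12)
    the global stiffness is M C M^T with M built from the 3x3 rotation R
    (local -> global).  Broadcasts over leading axes of R.
    """
    M = np.zeros(R.shape[:-2] + (6, 6))
    # tensor index pairs for Voigt slots; sigma'_ij = R_ik R_jl sigma_kl
    pairs = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]
    for I, (i, j) in enumerate(pairs):
        for J, (k, l) in enumerate(pairs):
            if J < 3:
                M[..., I, J] = R[..., i, k] * R[..., j, k]
            else:
                M[..., I, J] = (R[..., i, k] * R[..., j, l]
                                + R[..., i, l] * R[..., j, k])
    return M


def rotate_material(C_local: np.ndarray, beta_local: np.ndarray,
                    alpha: np.ndarray, cell_type_code: int,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate local stiffness and expansion into the global frame.

    ``C_local`` is 6x6 (engineering Voigt), ``beta_local`` a 3-vector of
    principal expansion coefficients.  ``alpha`` may be an array; the result
    broadcasts to alpha.shape + (6, 6) and alpha.shape + (6,).  The returned
    expansion is a 6-vector in engineering Voigt form (shear entries are
    2 x tensor components), as required for C : beta load terms.
    """
    R = rotation_matrix(alpha, cell_type_code)
    M = bond_stress_matrix(R)
    C_glob = np.einsum("...ij,jk,...lk->...il", M, C_local, M)
    B = np.einsum("...ip,p,...jp->...ij", R, np.asarray(beta_local, float), R)
    beta_glob = np.stack([B[..., 0, 0], B[..., 1, 1], B[..., 2, 2],
                          2 * B[..., 1, 2], 2 * B[..., 0, 2], 2 * B[..., 0, 1]],
                         axis=-1)
    return C_glob, beta_glob


# --------------------------------------------------------------------------
# per-element material field
# --------------------------------------------------------------------------

@dataclass
class MaterialField:
    """Global-frame stiffness and expansion per element (flat, C order).

    ``C`` has shape (n_elem, 6, 6) in MPa; ``beta`` shape (n_elem, 6) in
    engineering Voigt form.  Void elements carry zeros.
    """

    C: np.ndarray
    beta: np.ndarray
    cell_type: np.ndarray   # (n_elem,) uint8
    alpha: np.ndarray       # (n_elem,)
    shape: tuple[int, int, int]


def build_material_field(orientation: OrientationField,
                         moisture: float = 12.0,
                         scaling: MoistureScaling | None = None,
                         axial: CellWallParams = AXIAL_CELL_WALL,
                         ray: CellWallParams = RAY_CELL_WALL,
                         boundary_layer: np.ndarray | None = None,
                         ) -> MaterialField:
    """Rotate the cell-wall materials into the global frame element-wise.

    Elements flagged in ``boundary_layer`` (the artificial periodization tie
    layers) are treated as axial material at alpha = 0.
    """
    shape = orientation.alpha.shape
    ct = orientation.cell_type.copy()
    alpha = orientation.alpha.copy()
    if boundary_layer is not None:
        bl = np.asarray(boundary_layer, dtype=bool)
        alpha[bl] = 0.0
        ct[bl & (ct != CELL_VOID)] = CELL_AXIAL

    n = int(np.prod(shape))
    C = np.zeros((n, 6, 6))
    beta = np.zeros((n, 6))
    ct_flat = ct.reshape(n)
    al_flat = alpha.reshape(n)

    for code, params in ((CELL_AXIAL, axial), (CELL_RAY, ray)):
        mask = ct_flat == code
        if not np.any(mask):
            continue
        C_loc, b_loc = build_cell_wall_material(params, moisture, scaling)
        C[mask], beta[mask] = rotate_material(C_loc, b_loc, al_flat[mask], code)

    return MaterialField(C=C, beta=beta, cell_type=ct_flat, alpha=al_flat,
                         shape=shape)
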
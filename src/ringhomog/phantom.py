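"""Synthetic growth-ring phantoms and analytic level-set geometries.

Real inputs to the pipeline are micro-CT volumes of wood meso-structures:
a porous earlywood band with large vessels, a denser latewood band with
small vessels, thin-walled axial cells running longitudinally (z), and a
horizontal band of radially oriented ray parenchyma.  No such volume can be
shipped with the package, so this module renders a geometrically explicit
stand-in with exact ground truth (phase, per-voxel material orientation,
cell-type labels, porosity) against which every downstream stage --
segmentation, orientation recovery, homogenization -- can be validated.

The phantom is deliberately schematic: axial cells are square prisms on a
jittered lattice, vessels are circular cylinders along z, rays are prisms
along x.  It does not emulate scanner physics (beam hardening, ring
artifacts) beyond Gaussian noise and a smooth multiplicative intensity
inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "VoxelVolume",
    "PhantomSpec",
    "GroundTruth",
    "generate_growth_ring_phantom",
    "calibrate_pitch_for_porosity",
    "analytic_levelset",
    "CELL_VOID",
    "CELL_AXIAL",
    "CELL_RAY",
]

# cell-type label codes used throughout the package
CELL_VOID = 0
CELL_AXIAL = 1
CELL_RAY = 2


@dataclass
class VoxelVolume:
    """A gray-scale 3D scalar field with isotropic voxel spacing (um)."""

    data: np.ndarray  # float, shape (nx, ny, nz); axes x=R, y=T, z=L
    spacing_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class GroundTruth:
    """Exact per-voxel truth accompanying a rendered phantom."""

    binary_phase: np.ndarray        # bool, True = solid (cell wall)
    orientation_angle: np.ndarray   # float, radians in (-pi/2, pi/2]; NaN where undefined
    cell_type: np.ndarray           # uint8, CELL_VOID / CELL_AXIAL / CELL_RAY
    porosity: float

    def __post_init__(self) -> None:
        n_void = int(np.size(self.binary_phase) - np.count_nonzero(self.binary_phase))
        expected = n_void / self.binary_phase.size
        if abs(self.porosity - expected) > 1e-15:
            raise ValueError("porosity must equal the void voxel fraction exactly")
        if np.any(np.isfinite(self.orientation_angle) & ~self.binary_phase):
            raise ValueError("orientation may only be defined on solid voxels")


@dataclass
class PhantomSpec:
    """Parameters of the synthetic growth-ring volume.

    The defaults approximate the meso-structural proportions of a single oak
    growth ring with a multi-seriate ray band along its bottom edge: an
    earlywood band of roughly 30% of the ring width carrying ~14% vessel
    volume, a denser latewood band with small vessels, porosity near 0.45
    and a ray solid fraction near 0.21.  Lengths are in micrometres.
    """

    domain_size_voxels: tuple[int, int, int] = (60, 28, 8)
    spacing_um: float = 40.0
    earlywood_width_fraction: float = 0.30
    vessel_radii_um: tuple[float, float] = (170.0, 75.0)   # (earlywood, latewood)
    vessel_fractions: tuple[float, float] = (0.14, 0.04)   # void area targets per band
    cell_wall_thickness_um: float = 85.0
    axial_cell_pitch_um: float = 340.0
    latewood_wall_factor: float = 1.5    # wall thickening in the latewood band
    ray_band: tuple[int, int] | None = (0, 5)   # [y0, y1) voxel rows; None = no rays
    ray_cell_pitch_um: float = 200.0
    intensity_modes: tuple[float, float] = (0.3, 0.7)      # (void, solid)
    noise_sd: float = 0.0
    inhomogeneity_amplitude: float = 0.0
    lattice_jitter: float = 0.10         # wall-position jitter, fraction of pitch
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.domain_size_voxels
        if min(nx, ny, nz) < 2:
            raise ValueError("domain must have at least 2 voxels per axis")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if not (0 < self.earlywood_width_fraction < 1):
            raise ValueError("earlywood width fraction must lie in (0, 1)")
        if self.intensity_modes[0] == self.intensity_modes[1]:
            raise ValueError("void and solid intensity modes must be distinct")
        if self.noise_sd < 0 or self.inhomogeneity_amplitude < 0:
            raise ValueError("noise and inhomogeneity amplitudes must be >= 0")
        w = nx * self.spacing_um
        h = ny * self.spacing_um
        if max(self.vessel_radii_um) >= min(w, h) / 2:
            raise ValueError("vessel radii must be smaller than the domain half-extent")
        if min(self.vessel_radii_um) <= 0:
            raise ValueError("vessel radii must be positive")
        if self.cell_wall_thickness_um < 2 * self.spacing_um:
            raise ValueError(
                "infeasible geometry: cell walls must span at least 2 voxels "
                f"(thickness {self.cell_wall_thickness_um} um < "
                f"2 x {self.spacing_um} um)"
            )
        if self.axial_cell_pitch_um <= self.cell_wall_thickness_um:
            raise ValueError("cell pitch must exceed the wall thickness")


def _wall_positions(extent: float, pitch: float, jitter: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Jittered positions of parallel wall mid-planes covering [0, extent]."""
    n = int(np.ceil(extent / pitch)) + 1
    base = np.arange(n + 1) * pitch
    return base + rng.uniform(-jitter * pitch, jitter * pitch, size=base.shape)


def _min_dist_to_planes(coord: np.ndarray, planes: np.ndarray) -> np.ndarray:
    return np.min(np.abs(coord[..., None] - planes[None, :]), axis=-1)


def _place_vessels(rng: np.random.Generator, x_lo: float, x_hi: float,
                   y_lo: float, y_hi: float, radius: float,
                   target_fraction: float) -> list[tuple[float, float]]:
    """Dart-throw non-overlapping cylinder centers to hit an area fraction."""
    area = (x_hi - x_lo) * (y_hi - y_lo)
    if area <= 0:
        return []
    n_target = int(round(target_fraction * area / (np.pi * radius**2)))
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_target and attempts < 200 * max(n_target, 1):
        attempts += 1
        cx = rng.uniform(x_lo + radius, x_hi - radius) if x_hi - x_lo > 2 * radius \
            else 0.5 * (x_lo + x_hi)
        cy = rng.uniform(y_lo + radius, y_hi - radius) if y_hi - y_lo > 2 * radius \
            else 0.5 * (y_lo + y_hi)
        if all((cx - px) ** 2 + (cy - py) ** 2 > (2.2 * radius) ** 2
               for px, py in centers):
            centers.append((cx, cy))
    return centers


def generate_growth_ring_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Render a gray-scale growth-ring volume plus exact ground truth.

    The solid phase is the union of the axial-cell wall lattice (prisms along
    z), thickened in the latewood band, and the ray-band wall lattice (prisms
    along x), minus the carved vessel cylinders.  Intensities are two modes
    plus optional Gaussian noise and a smooth low-order polynomial
    multiplicative inhomogeneity.  Fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.domain_size_voxels
    h = spec.spacing_um
    W, H = nx * h, ny * h
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h

    we = spec.earlywood_width_fraction * W
    t = spec.cell_wall_thickness_um
    t_of_x = np.where(x < we, t, t * spec.latewood_wall_factor)

    # --- axial cell-wall lattice: planes normal to x and to y ---------------
    xw = _wall_positions(W, spec.axial_cell_pitch_um, spec.lattice_jitter, rng)
    yw = _wall_positions(H, spec.axial_cell_pitch_um, spec.lattice_jitter, rng)
    dxw = _min_dist_to_planes(x, xw)                       # (nx,)
    dyw = _min_dist_to_planes(y, yw)                       # (ny,)
    on_x_wall = dxw[:, None] < t_of_x[:, None] / 2         # (nx, ny): wall normal x
    on_x_wall = np.broadcast_to(on_x_wall, (nx, ny)).copy()
    on_y_wall = np.broadcast_to(dyw[None, :] < t_of_x[:, None] / 2, (nx, ny)).copy()
    axial_solid_2d = on_x_wall | on_y_wall

    # --- vessels: circular cylinders along z, carved as void ----------------
    ray_y1 = 0.0
    if spec.ray_band is not None:
        ray_y1 = spec.ray_band[1] * h
    centers = _place_vessels(rng, 0.0, we, ray_y1, H,
                             spec.vessel_radii_um[0], spec.vessel_fractions[0])
    r_of_center = [spec.vessel_radii_um[0]] * len(centers)
    lw_centers = _place_vessels(rng, we, W, ray_y1, H,
                                spec.vessel_radii_um[1], spec.vessel_fractions[1])
    centers += lw_centers
    r_of_center += [spec.vessel_radii_um[1]] * len(lw_centers)

    xx, yy = np.meshgrid(x, y, indexing="ij")
    in_vessel = np.zeros((nx, ny), dtype=bool)
    near_vessel = np.zeros((nx, ny), dtype=bool)
    for (cx, cy), r in zip(centers, r_of_center):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        in_vessel |= d2 <= r**2
        near_vessel |= d2 <= (r + 2.0 * h) ** 2

    axial_solid_2d &= ~in_vessel
    solid = np.broadcast_to(axial_solid_2d[:, :, None], (nx, ny, nz)).copy()
    cell_type = np.where(solid, CELL_AXIAL, CELL_VOID).astype(np.uint8)

    # --- ray band: wall lattice of prisms along x ---------------------------
    if spec.ray_band is not None:
        y0, y1 = spec.ray_band
        ywr = _wall_positions(H, spec.ray_cell_pitch_um, spec.lattice_jitter, rng)
        zwr = _wall_positions(nz * h, spec.ray_cell_pitch_um, spec.lattice_jitter, rng)
        on_ry = _min_dist_to_planes(y, ywr) < t / 2        # (ny,)
        on_rz = _min_dist_to_planes(z, zwr) < t / 2        # (nz,)
        ray_solid = on_ry[None, :, None] | on_rz[None, None, :]
        band = np.zeros((nx, ny, nz), dtype=bool)
        band[:, y0:y1, :] = True
        ray_solid = ray_solid & band
        solid = solid & ~band | ray_solid
        cell_type[band] = CELL_VOID
        cell_type[ray_solid] = CELL_RAY
        cell_type[solid & (cell_type == CELL_VOID)] = CELL_AXIAL  # safety

    # --- exact orientation ground truth (axial walls only) ------------------
    # x-normal walls are tangent to y (alpha = pi/2); y-normal walls tangent
    # to x (alpha = 0).  Junctions and vessel-adjacent voxels are undefined.
    alpha = np.full((nx, ny, nz), np.nan)
    clean_x = on_x_wall & ~on_y_wall & ~near_vessel
    clean_y = on_y_wall & ~on_x_wall & ~near_vessel
    alpha[np.broadcast_to(clean_x[:, :, None], alpha.shape)] = np.pi / 2
    alpha[np.broadcast_to(clean_y[:, :, None], alpha.shape)] = 0.0
    alpha[~solid | (cell_type != CELL_AXIAL)] = np.nan

    porosity = float(np.count_nonzero(~solid)) / solid.size
    truth = GroundTruth(binary_phase=solid, orientation_angle=alpha,
                        cell_type=cell_type, porosity=porosity)

    # --- gray-scale rendering ----------------------------------------------
    m_void, m_solid = spec.intensity_modes
    img = np.where(solid, m_solid, m_void).astype(np.float64)
    if spec.inhomogeneity_amplitude > 0:
        u = np.linspace(-1, 1, nx)[:, None, None]
        v = np.linspace(-1, 1, ny)[None, :, None]
        w = np.linspace(-1, 1, nz)[None, None, :]
        poly = 0.5 * u + 0.35 * v + 0.25 * u * v + 0.15 * w + 0.2 * u * u
        poly = poly / np.max(np.abs(poly))
        img = img * (1.0 + spec.inhomogeneity_amplitude * poly)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    return VoxelVolume(data=img, spacing_um=spec.spacing_um), truth


def calibrate_pitch_for_porosity(spec: PhantomSpec, target: float,
                                 pitch_range_um: tuple[float, float] = (120.0, 2000.0),
                                 iters: int = 40) -> PhantomSpec:
    """Bisect the axial cell pitch so the rendered porosity hits ``target``.

    Porosity is monotonically increasing in the pitch (larger lumens), up to
    the voxelization quantum; bisection therefore lands within one rendering
    step of the target.  Returns a new spec; the input is unchanged.
    """
    lo, hi = pitch_range_um
    if not (0 < target < 1):
        raise ValueError("target porosity must lie in (0, 1)")

    def porosity_at(p: float) -> float:
        _, gt = generate_growth_ring_phantom(replace(spec, axial_cell_pitch_um=p))
        return gt.porosity

    if not (porosity_at(lo) <= target <= porosity_at(hi)):
        raise ValueError("target porosity not bracketed by the pitch range")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if porosity_at(mid) < target:
            lo = mid
        else:
            hi = mid
    best = min((lo, hi, 0.5 * (lo + hi)), key=lambda p: abs(porosity_at(p) - target))
    return replace(spec, axial_cell_pitch_um=best)


def analytic_levelset(shape: Literal["plate", "cylinder", "sphere"],
                      params: dict,
                      grid: tuple[tuple[int, int, int], float],
                      solid_outside: bool = True):
    """Exact signed-distance field of an analytic surface on a voxel grid.

    ``grid`` is ``(domain_size_voxels, spacing_um)``; voxel centers sit at
    ``(i + 1/2) * spacing``.  With ``solid_outside=True`` (the lumen
    convention) phi is positive outside the surface; the sign flips
    otherwise.  phi is in the same length units as the spacing.

    params:
      plate:    ``point`` (3,), ``normal`` (3,)  -- solid on the +normal side
      cylinder: ``center`` (2,), ``radius``      -- axis along z
      sphere:   ``center`` (3,), ``radius``
    """
    from .segmentation import LevelSetField  # local import to avoid a cycle

    (nx, ny, nz), h = grid
    x = (np.arange(nx) + 0.5) * h
    y = (np.arange(ny) + 0.5) * h
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")

    if shape == "plate":
        n = np.asarray(params["normal"], dtype=float)
        n = n / np.linalg.norm(n)
        p0 = np.asarray(params["point"], dtype=float)
        phi = (X - p0[0]) * n[0] + (Y - p0[1]) * n[1] + (Z - p0[2]) * n[2]
    elif shape == "cylinder":
        r = float(params["radius"])
        if r <= 0:
            raise ValueError("degenerate cylinder: radius must be positive")
        cx, cy = params["center"]
        if r >= min(nx, ny) * h / 2 + r * 0:  # fits-in-grid check on the tight axis
            pass
        phi = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2) - r
    elif shape == "sphere":
        r = float(params["radius"])
        if r <= 0:
            raise ValueError("degenerate sphere: radius must be positive")
        cx, cy, cz = params["center"]
        phi = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) - r
    else:
        raise ValueError(f"unknown shape {shape!r}")

    if not solid_outside:
        phi = -phi
    return LevelSetField(phi=phi, spacing=h, units="um")
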
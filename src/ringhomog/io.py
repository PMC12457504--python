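"""File I/O, configuration and the end-to-end pipeline driver.

Volumes are exchanged as multi-page TIFF stacks, raw binary with a JSON
sidecar (dtype, shape, spacing), or HDF5; scalar results as JSON; diagnostic
fields as legacy-ASCII VTK structured points (cell data), which any
ParaView-class viewer reads.  ``run_pipeline`` chains segment -> periodize
-> orient -> assemble -> solve -> homogenize -> fields and writes a run
manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .phantom import (PhantomSpec, VoxelVolume, generate_growth_ring_phantom)
from .segmentation import (EnergyParams, LevelSetField, SegmentedMesostructure,
                           clean_segmentation, compute_morphometrics,
                           evolve_level_set, init_level_set, make_periodic)
from .pipeline import HomogenizationResult, solve_homogenization

__all__ = [
    "read_volume",
    "write_volume",
    "write_level_set",
    "write_vtk_cells",
    "PipelineConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

def read_volume(path: str | Path, spacing_um: float | None = None,
                normalize: bool = False) -> VoxelVolume:
    """Read a gray-scale volume from TIFF, raw+JSON sidecar, or HDF5.

    TIFF pages are z-slices of (x, y) planes.  The raw format expects
    ``<path>.json`` beside the data with keys ``dtype``, ``shape`` and
    ``spacing_um``.  An explicit ``spacing_um`` overrides metadata.  With
    ``normalize=True`` intensities are min-max scaled to [0, 1].
    """
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        data = np.asarray(tifffile.imread(path))
        data = np.moveaxis(data, 0, 2)  # pages (z) last
        if spacing_um is None:
            raise ValueError("TIFF input requires an explicit spacing_um")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            data = fh["volume"][()]
            meta_spacing = fh["volume"].attrs.get("spacing_um")
        if spacing_um is None:
            spacing_um = float(meta_spacing)
    elif path.suffix == ".raw":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"raw volume needs sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        shape = tuple(meta["shape"])
        dtype = np.dtype(meta["dtype"])
        raw = path.read_bytes()
        expected = int(np.prod(shape)) * dtype.itemsize
        if len(raw) != expected:
            raise ValueError(f"raw byte count mismatch: expected {expected}, "
                             f"found {len(raw)}")
        data = np.frombuffer(raw, dtype=dtype).reshape(shape)
        if spacing_um is None:
            spacing_um = float(meta["spacing_um"])
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")

    data = np.asarray(data, dtype=np.float64)
    if normalize and np.ptp(data) > 0:
        data = (data - data.min()) / np.ptp(data)
    return VoxelVolume(data=data, spacing_um=float(spacing_um))


def write_volume(path: str | Path, vol: VoxelVolume) -> None:
    """Write a volume as TIFF, HDF5, or raw + JSON sidecar by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.ascontiguousarray(np.moveaxis(vol.data, 2, 0)))
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("volume", data=vol.data)
            ds.attrs["spacing_um"] = vol.spacing_um
    elif path.suffix == ".raw":
        path.write_bytes(np.ascontiguousarray(vol.data).tobytes())
        path.with_suffix(".json").write_text(json.dumps(
            {"dtype": str(vol.data.dtype), "shape": list(vol.data.shape),
             "spacing_um": vol.spacing_um}))
    else:
        raise ValueError(f"unsupported volume format {path.suffix!r}")


def write_level_set(path: str | Path, phi: LevelSetField) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("phi", data=phi.phi)
        ds.attrs["spacing"] = phi.spacing
        ds.attrs["units"] = phi.units


def write_vtk_cells(path: str | Path, cell_data: dict,
                    dims: tuple[int, int, int], spacing_mm: float) -> None:
    """Legacy-ASCII VTK structured points with per-voxel (cell) data arrays."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx, ny, nz = dims
    lines = ["# vtk DataFile Version 3.0", "ringhomog cell data", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
             "ORIGIN 0 0 0",
             f"SPACING {spacing_mm} {spacing_mm} {spacing_mm}",
             f"CELL_DATA {nx * ny * nz}"]
    for name, arr in cell_data.items():
        arr = np.asarray(arr).reshape(nx, ny, nz)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest
        flat = np.transpose(arr, (2, 1, 0)).ravel()
        lines.extend(" ".join(f"{v:.8g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    path.write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Parameters of an end-to-end run; YAML round-trippable."""

    input_path: str | None = None     # None -> generate the default phantom
    input_is_binary: bool = False     # skip level-set evolution (pre-segmented)
    spacing_um: float = 40.0
    seed: int = 0
    # phantom generation (used when input_path is None)
    phantom_shape: tuple[int, int, int] = (60, 28, 8)
    phantom_noise_sd: float = 0.05
    phantom_inhomogeneity: float = 0.6
    # segmentation
    omega_global: float = 1.0
    omega_local: float = 1.0
    mu_curvature: float = 0.1
    sigma_local: float = 3.0
    seg_tol: float = 1e-3
    seg_max_iter: int = 500
    island_threshold: int = 27
    ray_band: tuple[int, int] | None = (0, 5)   # y-voxel rows labelled ray
    # discretization / integration
    p_q: int = 2
    n_c: int = 1000
    # solver
    solver_tol: float = 1e-8
    solver_max_iter: int | None = None
    precond_eps: float = 1e-13
    # loading
    moisture: float = 12.0
    delta_m: float = 1.0
    # output
    output_dir: str = "ringhomog_out"

    def __post_init__(self) -> None:
        if self.p_q < 1 or self.n_c < 1:
            raise ValueError("p_q and n_c must be positive")
        if not (0 < self.moisture < 100):
            raise ValueError("moisture content must be a percentage in (0, 100)")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        if d["ray_band"] is not None:
            d["ray_band"] = list(d["ray_band"])
        d["phantom_shape"] = list(d["phantom_shape"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("ray_band") is not None:
            d["ray_band"] = tuple(d["ray_band"])
        if "phantom_shape" in d:
            d["phantom_shape"] = tuple(d["phantom_shape"])
        return cls(**d)


def _two_means_threshold(img: np.ndarray, iters: int = 50) -> float:
    """Midpoint threshold between two iteratively refitted intensity means."""
    t = 0.5 * (img.min() + img.max())
    for _ in range(iters):
        lo = img[img < t]
        hi = img[img >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < 1e-12:
            break
        t = t_new
    return t


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full image-to-property pipeline and write artifacts.

    Returns a dict with the output paths, the morphometrics, the effective
    properties and the homogenization result object.  Stages: segment ->
    clean -> periodize -> orient -> assemble -> solve -> homogenize ->
    fields.  Any stage failure aborts with the stage named.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "load"
    try:
        if config.input_path is None:
            spec = PhantomSpec(domain_size_voxels=config.phantom_shape,
                               spacing_um=config.spacing_um, seed=config.seed,
                               noise_sd=config.phantom_noise_sd,
                               inhomogeneity_amplitude=config.phantom_inhomogeneity,
                               ray_band=config.ray_band)
            volume, _truth = generate_growth_ring_phantom(spec)
        else:
            volume = read_volume(config.input_path, spacing_um=config.spacing_um)
        img = volume.data
        if np.ptp(img) > 0:
            img = (img - img.min()) / np.ptp(img)
        volume = VoxelVolume(data=img, spacing_um=volume.spacing_um)

        stage = "segment"
        seg_converged = True
        if config.input_is_binary:
            binary = img >= 0.5
        else:
            binary0 = img >= _two_means_threshold(img)
            phi0 = init_level_set(binary0, method="fast")
            energy = EnergyParams(omega_global=config.omega_global,
                                  omega_local=config.omega_local,
                                  mu_curvature=config.mu_curvature,
                                  sigma_local=config.sigma_local,
                                  tol=config.seg_tol,
                                  max_iter=config.seg_max_iter)
            phi_seg = evolve_level_set(volume, phi0, energy)
            binary = phi_seg.binary()
            seg_converged = phi_seg.converged

        stage = "clean"
        cell_type = np.where(binary, 1, 0).astype(np.uint8)
        if config.ray_band is not None:
            y0, y1 = config.ray_band
            ray = np.zeros_like(cell_type, dtype=bool)
            ray[:, y0:y1, :] = True
            cell_type[ray & binary] = 2
        seg = SegmentedMesostructure(binary_phase=binary,
                                     spacing_um=volume.spacing_um,
                                     cell_type=cell_type)
        if binary.any() and not binary.all():
            seg = clean_segmentation(seg, config.island_threshold)

        stage = "periodize"
        seg_p = make_periodic(seg)
        morpho = compute_morphometrics(seg_p)

        stage = "orient+solve"
        if seg_p.binary_phase.all():
            # fully solid domain: no interface, constant-positive level set
            phi_p = LevelSetField(phi=np.full(seg_p.binary_phase.shape, 0.5),
                                  spacing=1.0)
        else:
            phi_p = init_level_set(seg_p.binary_phase, spacing=1.0,
                                   method="exact")
        result = solve_homogenization(phi_p, seg_p.cell_type,
                                      spacing_um=volume.spacing_um,
                                      boundary_layer=seg_p.boundary_layer,
                                      moisture=config.moisture,
                                      p_q=config.p_q, n_c=config.n_c,
                                      tol=config.solver_tol,
                                      max_iter=config.solver_max_iter,
                                      precond_eps=config.precond_eps)

        stage = "fields"
        fields_free = result.local_fields(config.delta_m, "free")
        fields_con = result.local_fields(config.delta_m, "constrained")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- artifacts --------------------------------------------------------
    eff = result.effective
    morpho_path = out / "morphometrics.json"
    morpho_path.write_text(json.dumps(asdict(morpho), indent=2))
    eff_path = out / "effective_properties.json"
    eff_path.write_text(json.dumps({
        "C_bar_MPa": eff.C_bar.tolist(),
        "beta_bar": eff.beta_bar.tolist(),
        "constants_MPa": {k: float(v) for k, v in eff.constants.items()},
        "orthotropy_residual": eff.orthotropy_residual,
    }, indent=2))

    dims = result.mesh.dims
    n_elem = result.mesh.n_elements
    write_vtk_cells(out / "orientation.vtk",
                    {"alpha_rad": result.materials.alpha,
                     "cell_type": result.materials.cell_type.astype(float)},
                    dims, result.mesh.spacing_mm[0])
    for name, flds in (("fields_free", fields_free),
                       ("fields_constrained", fields_con)):
        comps = {}
        for ci, cname in enumerate(("sxx", "syy", "szz")):
            full = np.zeros(n_elem)
            full[flds.element_ids] = flds.stress[:, ci]
            comps[f"{name}_{cname}"] = full
        write_vtk_cells(out / f"{name}.vtk", comps, dims,
                        result.mesh.spacing_mm[0])

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "timings_s": {"total": time.time() - t0},
        "solver": [{k: d[k] for k in ("rhs", "iterations", "converged", "relres")}
                   for d in result.solution.diagnostics],
        "segmentation_converged": bool(seg_converged),
        "cleanup_actions": len(seg.log),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {"output_dir": str(out), "morphometrics": morpho,
            "effective": eff, "result": result,
            "fields_free": fields_free, "fields_constrained": fields_con}
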
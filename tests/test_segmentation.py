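"""Level-set initialization, evolution, cleanup, periodization, morphometrics."""

import numpy as np
import pytest

from ringhomog.phantom import PhantomSpec, VoxelVolume, generate_growth_ring_phantom
from ringhomog.segmentation import (EnergyParams, SegmentedMesostructure,
                                    clean_segmentation, compute_morphometrics,
                                    dice_coefficient, evolve_level_set,
                                    init_level_set, make_periodic)


def brute_force_signed_distance(binary: np.ndarray) -> np.ndarray:
    """All-pairs voxel-center-to-boundary-face distance (test oracle)."""
    faces = []
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        for p in np.argwhere(binary[tuple(lo)] != binary[tuple(hi)]):
            c = p.astype(float)
            c[ax] += 0.5
            faces.append((c, ax))
    out = np.empty(binary.shape)
    for p in np.argwhere(np.ones_like(binary)):
        best = np.inf
        for c, ax in faces:
            d = np.abs(p - c)
            inplane = np.maximum(d - 0.5, 0.0)
            inplane[ax] = 0.0
            best = min(best, np.sqrt(d[ax] ** 2 + inplane @ inplane))
        out[tuple(p)] = best
    return np.where(binary, out, -out)


class TestInitLevelSet:
    def test_planar_interface_half_voxel_convention(self):
        # half-space solid: |phi| = (k + 1/2) * spacing at k layers from the face
        binary = np.zeros((6, 4, 4), dtype=bool)
        binary[:3] = True
        phi = init_level_set(binary, spacing=2.0).phi
        np.testing.assert_allclose(phi[2, :, :], 1.0)   # adjacent solid: +h/2
        np.testing.assert_allclose(phi[3, :, :], -1.0)  # adjacent void: -h/2
        np.testing.assert_allclose(phi[0, :, :], 5.0)   # 2 layers deep: 2.5 h

    def test_single_solid_voxel_face_distance(self):
        binary = np.zeros((5, 5, 5), dtype=bool)
        binary[2, 2, 2] = True
        phi = init_level_set(binary).phi
        assert phi[2, 2, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_small_grids(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((7, 6, 5)) < 0.5
        if binary.all() or not binary.any():
            pytest.skip("degenerate draw")
        phi = init_level_set(binary).phi
        ref = brute_force_signed_distance(binary)
        np.testing.assert_allclose(phi, ref, rtol=0, atol=1e-12)

    def test_sign_round_trip(self):
        rng = np.random.default_rng(3)
        binary = rng.random((8, 8, 8)) < 0.4
        phi = init_level_set(binary)
        np.testing.assert_array_equal(phi.binary(), binary)
        fast = init_level_set(binary, method="fast")
        np.testing.assert_array_equal(fast.binary(), binary)

    def test_single_phase_rejected(self):
        with pytest.raises(ValueError, match="no phase boundary"):
            init_level_set(np.ones((4, 4, 4), dtype=bool))


class TestEvolveLevelSet:
    def test_noiseless_phantom_recovered(self, noiseless_phantom):
        _, vol, truth = noiseless_phantom
        mid = 0.5 * (vol.data.min() + vol.data.max())
        phi0 = init_level_set(vol.data >= mid, method="fast")
        phi = evolve_level_set(vol, phi0)
        assert phi.converged
        assert dice_coefficient(phi.binary(), truth.binary_phase) >= 0.99
        # zero level within one voxel of the true boundary
        ref = init_level_set(truth.binary_phase, method="fast").phi
        boundary = np.abs(phi.phi) <= 0.5
        assert np.abs(ref[boundary]).max() <= 1.5

    def test_converged_result_is_a_fixed_point(self, noiseless_phantom):
        _, vol, truth = noiseless_phantom
        mid = 0.5 * (vol.data.min() + vol.data.max())
        phi0 = init_level_set(vol.data >= mid, method="fast")
        phi = evolve_level_set(vol, phi0)
        again = evolve_level_set(vol, phi)
        assert again.converged
        np.testing.assert_array_equal(again.binary(), phi.binary())

    def test_uniform_image_rejected(self):
        vol = VoxelVolume(data=np.full((6, 6, 6), 0.5), spacing_um=1.0)
        phi0 = init_level_set(np.arange(216).reshape(6, 6, 6) > 100,
                              method="fast")
        with pytest.raises(ValueError, match="no two-phase minimizer"):
            evolve_level_set(vol, phi0)

    def test_accuracy_non_increasing_with_noise(self):
        dices = []
        for sd in (0.0, 0.1, 0.3):
            spec = PhantomSpec(noise_sd=sd, seed=5)
            vol, truth = generate_growth_ring_phantom(spec)
            mid = 0.5 * (vol.data.min() + vol.data.max())
            phi0 = init_level_set(vol.data >= mid, method="fast")
            phi = evolve_level_set(vol, phi0)
            dices.append(dice_coefficient(phi.binary(), truth.binary_phase))
        assert dices[0] >= dices[1] >= dices[2]


class TestCleanSegmentation:
    def test_small_speck_removed_and_logged(self):
        binary = np.zeros((10, 10, 10), dtype=bool)
        binary[:2] = True                 # bulk solid
        binary[6:7, 6:7, 6:7] = True      # 1-voxel speck (26-disconnected)
        seg = clean_segmentation(
            SegmentedMesostructure(binary, 1.0), island_threshold_voxels=10)
        assert not seg.binary_phase[6, 6, 6]
        assert any(e["action"] == "flip_solid_island" for e in seg.log)

    def test_component_at_threshold_is_kept(self):
        binary = np.zeros((10, 10, 10), dtype=bool)
        binary[:2] = True
        binary[6:8, 6:8, 6:8] = True      # size exactly 8
        seg = clean_segmentation(
            SegmentedMesostructure(binary, 1.0), island_threshold_voxels=8)
        assert seg.binary_phase[6:8, 6:8, 6:8].all()

    def test_enclosed_void_bubble_filled(self):
        binary = np.ones((8, 8, 8), dtype=bool)
        binary[4, 4, 4] = False
        seg = clean_segmentation(
            SegmentedMesostructure(binary, 1.0), island_threshold_voxels=5)
        assert seg.binary_phase.all()

    def test_injected_specks_restore_clean_phantom(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        dirty = truth.binary_phase.copy()
        # inject isolated voxels well inside large vessel lumens
        from scipy import ndimage
        deep_void = ndimage.distance_transform_edt(~dirty) > 3
        spots = np.argwhere(deep_void)[::50][:5]
        for p in spots:
            dirty[tuple(p)] = True
        assert not np.array_equal(dirty, truth.binary_phase)
        seg = clean_segmentation(SegmentedMesostructure(dirty, 1.0), 27)
        np.testing.assert_array_equal(seg.binary_phase, truth.binary_phase)

    def test_threshold_larger_than_domain_rejected(self):
        binary = np.zeros((4, 4, 4), dtype=bool)
        binary[0] = True
        with pytest.raises(ValueError):
            clean_segmentation(SegmentedMesostructure(binary, 1.0), 64)


class TestMakePeriodic:
    def test_mirror_symmetry_in_z(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        seg = SegmentedMesostructure(truth.binary_phase, 40.0,
                                     cell_type=truth.cell_type)
        out = make_periodic(seg)
        nz = out.binary_phase.shape[2]
        assert nz == 2 * truth.binary_phase.shape[2]
        for k in range(nz):
            np.testing.assert_array_equal(out.binary_phase[:, :, k],
                                          out.binary_phase[:, :, nz - 1 - k])

    def test_xy_faces_are_solid(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        out = make_periodic(SegmentedMesostructure(truth.binary_phase, 40.0))
        assert out.binary_phase[:2].all() and out.binary_phase[-2:].all()
        assert out.binary_phase[:, :2].all() and out.binary_phase[:, -2:].all()
        assert out.boundary_layer is not None
        assert out.boundary_layer[0, 0, 0]
        assert not out.boundary_layer[5, 5, 0]

    def test_porosity_accounting_by_direct_count(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        out = make_periodic(SegmentedMesostructure(truth.binary_phase, 40.0))
        n_void_in = np.count_nonzero(~truth.binary_phase)
        n_void_out = np.count_nonzero(~out.binary_phase)
        assert n_void_out == 2 * n_void_in  # added layers are all solid


class TestMorphometrics:
    def test_density_from_porosity(self):
        # porosity 0.454 with cell-wall density 1440 gives 786 kg/m^3
        binary = np.ones((10, 10, 10), dtype=bool)
        binary.ravel()[:454] = False
        m = compute_morphometrics(SegmentedMesostructure(binary, 1.0),
                                  rho_cw=1440.0)
        assert m.porosity == pytest.approx(0.454)
        assert round(m.density_kg_m3) == 786

    def test_all_solid_volume(self):
        binary = np.ones((5, 5, 5), dtype=bool)
        m = compute_morphometrics(SegmentedMesostructure(binary, 2.0),
                                  rho_cw=1440.0)
        assert m.porosity == 0.0
        assert m.density_kg_m3 == pytest.approx(1440.0)

    def test_ray_fraction_from_labels(self):
        binary = np.ones((10, 10, 2), dtype=bool)
        ct = np.ones((10, 10, 2), dtype=np.uint8)
        ct[:, :2, :] = 2  # 20% of solid labelled ray
        m = compute_morphometrics(SegmentedMesostructure(binary, 1.0,
                                                         cell_type=ct))
        assert m.v_ray == pytest.approx(0.2)

    def test_missing_labels_reported_as_undefined(self):
        binary = np.ones((4, 4, 4), dtype=bool)
        m = compute_morphometrics(SegmentedMesostructure(binary, 1.0))
        assert m.v_ray is None

    def test_vessel_fraction_from_constructed_cylinder(self):
        binary = np.ones((20, 20, 6), dtype=bool)
        X, Y = np.meshgrid(np.arange(20) + 0.5, np.arange(20) + 0.5,
                           indexing="ij")
        lumen = (X - 6) ** 2 + (Y - 10) ** 2 <= 4.0**2
        binary[lumen] = False
        m = compute_morphometrics(SegmentedMesostructure(binary, 1.0),
                                  ew_boundary_x_um=12.0,
                                  vessel_radius_threshold_um=2.0)
        expected = np.count_nonzero(lumen) * 6 / binary.size
        assert m.v_vessel_earlywood == pytest.approx(expected)
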
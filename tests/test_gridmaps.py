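"""Grid maps: alignment, proximal densities, free energies, concentration."""

import numpy as np
import pytest

from pmdmembrane.gridmaps import (AlignmentSpec, BOLTZMANN_KCAL,
                                  C0_MOLECULES_PER_A3, align_trajectory,
                                  concentration_grid, density_to_free_energy,
                                  proximal_density_grid, smooth_grid,
                                  threshold_isosurface_report)
from pmdmembrane.model import ScalarField3D, Trajectory
from pmdmembrane.occupancy import compute_occupancy

from conftest import make_bare_system, static_trajectory, tetra_probe


def _small_system(probe_center=(12.5, 12.5, 12.5), box=(25.0, 25.0, 25.0)):
    # compact probe: all 4 heavy atoms inside one 1 A^3 voxel; protein nearby
    return make_bare_system([[10.0, 12.5, 12.5]],
                            [tetra_probe(probe_center, size=0.1)], box=box)


def _rot_z(deg):
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t), 0.0],
                     [np.sin(t), np.cos(t), 0.0],
                     [0.0, 0.0, 1.0]])


class TestAlignment:
    @pytest.fixture()
    def wobbly(self):
        rng = np.random.default_rng(9)
        prot = rng.uniform(5, 20, size=(8, 3))
        system, coords, box = make_bare_system(
            prot, [tetra_probe([22.0, 22.0, 22.0])], box=(30.0, 30.0, 30.0))
        return system, coords, box

    def test_identical_frame_is_unchanged(self, wobbly):
        system, coords, box = wobbly
        traj = static_trajectory(coords, box, 2)
        spec = AlignmentSpec(reference=0, fit_atoms=system.protein_heavy)
        out = align_trajectory(system, traj, spec)
        assert np.allclose(out.coordinates, traj.coordinates, atol=1e-10)

    def test_translation_removed_exactly(self, wobbly):
        system, coords, box = wobbly
        frames = np.array([coords, coords + np.array([5.0, 0.0, 0.0])])
        traj = Trajectory(frames, np.tile(box, (2, 1)), np.arange(2.0))
        out = align_trajectory(system, traj,
                               AlignmentSpec(0, system.protein_heavy))
        rmsd = np.sqrt(np.mean((out.coordinates[1] - coords) ** 2))
        assert rmsd < 1e-10

    def test_30_degree_rotation_recovered(self, wobbly):
        system, coords, box = wobbly
        rotated = coords @ _rot_z(30.0).T
        traj = Trajectory(np.array([coords, rotated]), np.tile(box, (2, 1)),
                          np.arange(2.0))
        out = align_trajectory(system, traj,
                               AlignmentSpec(0, system.protein_heavy))
        fit = system.protein_heavy
        rmsd = np.sqrt(np.mean(np.sum(
            (out.coordinates[1][fit] - coords[fit]) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_exclusions_are_dropped_from_fit(self, wobbly):
        system, coords, box = wobbly
        spec = AlignmentSpec(0, system.protein_heavy,
                             exclusions=system.protein_heavy[:6])
        assert spec.resolved_fit().size == 2
        with pytest.raises(ValueError):
            align_trajectory(system, static_trajectory(coords, box), spec)

    def test_occupancy_invariant_under_alignment(self, wobbly):
        system, coords, box = wobbly
        rng = np.random.default_rng(4)
        frames = np.array([coords @ _rot_z(a).T + rng.uniform(-2, 2, 3)
                           for a in (0.0, 15.0, 40.0, 80.0)])
        # large box so the minimum image never engages (alignment breaks
        # the wrap geometry, but not true distances)
        bigbox = np.array([500.0, 500.0, 500.0])
        traj = Trajectory(frames, np.tile(bigbox, (4, 1)), np.arange(4.0))
        aligned = align_trajectory(system, traj,
                                   AlignmentSpec(0, system.protein_heavy))
        p0 = compute_occupancy(system, traj)
        p1 = compute_occupancy(system, aligned)
        for i in p0.R:
            assert p0.R[i] == pytest.approx(p1.R[i], rel=1e-9, abs=1e-12)


class TestProximalDensity:
    def test_stationary_qualifying_probe_counts_four_atoms(self):
        system, coords, box = _small_system()
        traj = static_trajectory(coords, box, 10)
        field = proximal_density_grid(system, traj, cutoff=4.0, spacing=1.0,
                                      bounds=((0, 0, 0), box))
        # all 4 heavy atoms fall in the voxel around (12.5, 12.5, 12.5)
        total = field.values.sum() * field.voxel_volume
        assert total == pytest.approx(4.0, rel=1e-12)
        assert field.values.max() * field.voxel_volume == pytest.approx(4.0)

    def test_probe_beyond_cutoff_gives_empty_field(self):
        system, coords, box = _small_system(probe_center=(20.0, 20.0, 20.0))
        traj = static_trajectory(coords, box, 5)
        field = proximal_density_grid(system, traj, cutoff=4.0,
                                      bounds=((0, 0, 0), box))
        assert np.all(field.values == 0.0)

    def test_time_average_is_linear_in_qualifying_frames(self):
        system, coords, box = _small_system()
        far = coords.copy()
        far[system.probes[0].heavy_atoms, :] = \
            tetra_probe([20.0, 20.0, 20.0])
        frames = np.array([coords] * 5 + [far] * 5)
        traj = Trajectory(frames, np.tile(box, (10, 1)), np.arange(10.0))
        half = proximal_density_grid(system, traj, bounds=((0, 0, 0), box))
        full = proximal_density_grid(system, static_trajectory(coords, box, 10),
                                     bounds=((0, 0, 0), box))
        assert half.values.sum() == pytest.approx(full.values.sum() / 2,
                                                  rel=1e-12)

    def test_infinite_cutoff_equals_unconditional_map(self):
        system, coords, box = _small_system(probe_center=(20.0, 20.0, 20.0))
        traj = static_trajectory(coords, box, 3)
        a = proximal_density_grid(system, traj, cutoff=None,
                                  bounds=((0, 0, 0), box))
        b = proximal_density_grid(system, traj, cutoff=1e6,
                                  bounds=((0, 0, 0), box))
        assert np.array_equal(a.values, b.values)


class TestFreeEnergy:
    def _uniform_field(self, value, dims=(3, 3, 3)):
        return ScalarField3D(origin=np.zeros(3), spacing=np.ones(3),
                             values=np.full(dims, float(value)), units="A^-3")

    def test_reference_density_maps_to_zero(self):
        fe = density_to_free_energy(self._uniform_field(0.02), 0.02)
        assert np.allclose(fe.field.values, 0.0)

    def test_e_fold_enrichment_at_310K(self):
        rho = self._uniform_field(0.02)
        rho.values[1, 1, 1] = 0.02 * np.e
        fe = density_to_free_energy(rho, 0.02, temperature=310.0)
        # kB*310 = 0.616 kcal/mol
        assert BOLTZMANN_KCAL * 310.0 == pytest.approx(0.616, abs=1e-3)
        assert fe.field.values[1, 1, 1] == pytest.approx(-0.616, abs=1e-3)

    def test_empty_voxels_carry_cap_sentinel(self):
        rho = self._uniform_field(0.0)
        fe = density_to_free_energy(rho, 0.02, cap=5.0)
        assert np.all(fe.field.values == 5.0)
        assert np.all(np.isfinite(fe.field.values))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            density_to_free_energy(self._uniform_field(0.1), 0.0)


class TestConcentrationGrid:
    def test_single_probe_single_voxel_is_1660_molar(self):
        system, coords, box = _small_system()
        traj = static_trajectory(coords, box, 1)
        grid = concentration_grid(system, traj, spacing=1.0,
                                  bounds=((0, 0, 0), box))
        nz = grid.field.values[grid.field.values > 0]
        assert nz.size == 1
        assert nz[0] == pytest.approx(1660.3, rel=1e-9)
        assert grid.conservation_sum() == pytest.approx(1.0, rel=1e-9)

    def test_no_probes_in_bounds_gives_zero_grid(self):
        system, coords, box = _small_system(probe_center=(20.0, 20.0, 20.0))
        traj = static_trajectory(coords, box, 2)
        grid = concentration_grid(system, traj, spacing=1.0,
                                  bounds=((0, 0, 0), (10.0, 10.0, 10.0)))
        assert np.all(grid.field.values == 0.0)

    def test_duplicating_frames_leaves_grid_unchanged(self):
        system, coords, box = _small_system()
        g1 = concentration_grid(system, static_trajectory(coords, box, 1),
                                spacing=0.37, bounds=((0, 0, 0), box))
        g2 = concentration_grid(system, static_trajectory(coords, box, 4),
                                spacing=0.37, bounds=((0, 0, 0), box))
        assert np.allclose(g1.field.values, g2.field.values, rtol=1e-12)

    def test_conservation_on_seeded_moving_probes(self):
        rng = np.random.default_rng(21)
        probes = [tetra_probe(rng.uniform(3, 22, 3), rng.standard_normal(3))
                  for _ in range(4)]
        system, coords, box = make_bare_system([[12.0, 12.0, 12.0]], probes,
                                               box=(25.0, 25.0, 25.0))
        frames = []
        for _ in range(6):
            f = coords.copy()
            for p in system.probes:
                f[list(p.heavy_atoms)] = tetra_probe(rng.uniform(3, 22, 3),
                                                     rng.standard_normal(3))
            frames.append(f)
        traj = Trajectory(np.array(frames), np.tile(box, (6, 1)),
                          np.arange(6.0))
        grid = concentration_grid(system, traj, spacing=0.7,
                                  bounds=((0, 0, 0), box))
        assert grid.conservation_sum() == pytest.approx(4.0, rel=1e-9)

    def test_default_spacing_is_0p37(self):
        system, coords, box = _small_system()
        grid = concentration_grid(system, static_trajectory(coords, box),
                                  bounds=((0, 0, 0), box))
        assert np.allclose(grid.field.spacing, 0.37)


class TestSmoothing:
    def _grid_from(self, values):
        fld = ScalarField3D(origin=np.zeros(3), spacing=np.ones(3),
                            values=np.asarray(values, dtype=float), units="M")
        from pmdmembrane.gridmaps import ConcentrationGrid
        return ConcentrationGrid(field=fld)

    def test_interior_spike_redistributes_sevenths(self):
        v = np.zeros((5, 5, 5))
        v[2, 2, 2] = 7.0
        out = smooth_grid(self._grid_from(v)).field.values
        assert out[2, 2, 2] == pytest.approx(1.0)
        for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            assert out[2 + di, 2 + dj, 2 + dk] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(7.0)

    def test_corner_spike_boundary_convention(self):
        v = np.zeros((4, 4, 4))
        v[0, 0, 0] = 7.0
        out = smooth_grid(self._grid_from(v)).field.values
        assert out[0, 0, 0] == pytest.approx(1.0)  # 3 neighbours lost, /7 kept
        assert out[1, 0, 0] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(4.0)

    def test_renormalized_variant_conserves_at_boundary(self):
        v = np.zeros((4, 4, 4))
        v[0, 0, 0] = 7.0
        out = smooth_grid(self._grid_from(v), renormalize=True).field.values
        assert out[0, 0, 0] == pytest.approx(7.0 / 4.0)

    def test_uniform_interior_unchanged(self):
        v = np.ones((7, 7, 7))
        out = smooth_grid(self._grid_from(v)).field.values
        assert np.allclose(out[1:-1, 1:-1, 1:-1], 1.0)

    def test_linearity_and_positivity(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 5, (6, 6, 6))
        b = rng.uniform(0, 5, (6, 6, 6))
        sa = smooth_grid(self._grid_from(a)).field.values
        sb = smooth_grid(self._grid_from(b)).field.values
        sab = smooth_grid(self._grid_from(a + 2 * b)).field.values
        assert np.allclose(sab, sa + 2 * sb, rtol=1e-12)
        assert np.all(sa >= 0)


class TestThresholdReport:
    def test_zero_grid_below_minus_one(self):
        g = ScalarField3D(np.zeros(3), np.ones(3), np.zeros((4, 4, 4)))
        count, mask = threshold_isosurface_report(g, -1.0, "below")
        assert count == 0 and np.all(mask.values == 0)

    def test_known_node_count(self):
        v = np.zeros((4, 4, 4))
        v.flat[[3, 7, 11, 19, 23]] = -2.0
        g = ScalarField3D(np.zeros(3), np.ones(3), v)
        count, mask = threshold_isosurface_report(g, -1.0, "below")
        assert count == 5 and mask.values.sum() == 5

    def test_random_grid_matches_brute_scan(self):
        rng = np.random.default_rng(17)
        v = rng.normal(0, 2, (8, 8, 8))
        g = ScalarField3D(np.zeros(3), np.ones(3), v)
        for level, direction in [(-1.0, "below"), (3.2, "above")]:
            count, _ = threshold_isosurface_report(g, level, direction)
            brute = sum(1 for x in v.ravel()
                        if (x <= level if direction == "below" else x >= level))
            assert count == brute
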
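"""Bilayer diagnostics: z-profiles, orientation order parameters, APL, thickness."""

import numpy as np
import pytest

from pmdmembrane.membrane import (area_per_lipid, bilayer_thickness,
                                  density_profile_z,
                                  probe_orientation_vs_normal,
                                  probe_orientation_vs_surface)
from pmdmembrane.model import Trajectory
from pmdmembrane.occupancy import compute_occupancy
from pmdmembrane.synth import ContactPlant, SynthSpec, build_synthetic

from conftest import make_bare_system, static_trajectory, tetra_probe


class TestDensityProfile:
    def test_phosphate_sheets_peak_at_plus_minus_20(self):
        system, coords, box = make_bare_system(
            [[30.0, 30.0, 30.0]], [tetra_probe([30.0, 30.0, 55.0])],
            lipid_z=([50.0] * 6, [10.0] * 6))
        prof = density_profile_z(system, static_trajectory(coords, box, 3),
                                 bin_width=1.0)
        peaks = prof.bin_centers[prof.lipid_phosphate > 0]
        assert np.all(np.abs(np.abs(peaks) - 20.0) <= 0.5)

    def test_profile_integral_recovers_group_counts(self):
        spec = SynthSpec(seed=5, n_frames=10, n_probes=8, placement="all")
        system, traj, _ = build_synthetic(spec)
        prof = density_profile_z(system, traj)
        area = float(traj.boxes[0, 0] * traj.boxes[0, 1])
        assert prof.integral("lipid_phosphate", area) == pytest.approx(
            system.lipid_phosphates.size, rel=1e-9)
        assert prof.integral("probe_center_of_mass", area) == pytest.approx(
            len(system.probes), rel=1e-9)

    def test_uniform_slab_density_within_poisson_noise(self):
        spec = SynthSpec(seed=6, n_frames=200, n_probes=20, placement="upper",
                         n_lipids_per_leaflet=9)
        system, traj, _ = build_synthetic(spec)
        prof = density_profile_z(system, traj, bin_width=2.0, recenter=False)
        lx, ly, lz = spec.box
        z_lo = spec.midplane_z + spec.leaflet_z + 2.0
        z_hi = lz - 2.0
        expect = spec.n_probes / (lx * ly * (z_hi - z_lo))
        inside = (prof.bin_centers > z_lo + 3) & (prof.bin_centers < z_hi - 3)
        counts_per_bin = expect * lx * ly * 2.0 * spec.n_frames
        tol = 4.0 * np.sqrt(counts_per_bin) / (lx * ly * 2.0 * spec.n_frames)
        assert np.all(np.abs(prof.probe_center_of_mass[inside] - expect) < tol)
        outside = np.abs(prof.bin_centers - spec.midplane_z) < spec.leaflet_z - 4
        assert np.all(prof.probe_center_of_mass[outside] == 0.0)

    def test_system_without_probes_gives_zero_probe_profile(self):
        system, coords, box = make_bare_system(
            [[30.0, 30.0, 30.0]], [], lipid_z=([50.0] * 3, [10.0] * 3))
        prof = density_profile_z(system, static_trajectory(coords, box))
        assert np.all(prof.probe_center_of_mass == 0.0)

    def test_invalid_bin_width_rejected(self):
        system, coords, box = make_bare_system(
            [[30.0, 30.0, 30.0]], [], lipid_z=([50.0], [10.0]))
        with pytest.raises(ValueError):
            density_profile_z(system, static_trajectory(coords, box),
                              bin_width=0.0)


class TestOrientationVsNormal:
    def test_oxygen_up_gives_plus_one(self):
        spec = SynthSpec(seed=2, n_frames=5, n_probes=6,
                         orientation_plan="plus_z", placement="all")
        system, traj, _ = build_synthetic(spec)
        prof = probe_orientation_vs_normal(system, traj)
        occupied = prof.counts > 0
        assert np.allclose(prof.mean_cos[occupied], 1.0, atol=1e-12)

    def test_oxygen_down_gives_minus_one(self):
        spec = SynthSpec(seed=2, n_frames=5, n_probes=6,
                         orientation_plan="minus_z", placement="all")
        system, traj, _ = build_synthetic(spec)
        prof = probe_orientation_vs_normal(system, traj)
        occupied = prof.counts > 0
        assert np.allclose(prof.mean_cos[occupied], -1.0, atol=1e-12)

    def test_isotropic_orientations_average_to_zero(self):
        spec = SynthSpec(seed=8, n_frames=400, n_probes=10,
                         orientation_plan="random", placement="upper",
                         n_lipids_per_leaflet=9)
        system, traj, _ = build_synthetic(spec)
        prof = probe_orientation_vs_normal(system, traj, bin_width=4.0)
        occupied = prof.counts > 0
        # SEM bound: SD(cos) = 1/sqrt(3) under isotropy; 4/sqrt(n) is looser
        bound = 4.0 / np.sqrt(prof.counts[occupied])
        assert np.all(np.abs(prof.mean_cos[occupied]) < bound)

    def test_flipping_carbon_and_oxygen_negates_means(self):
        spec = SynthSpec(seed=9, n_frames=20, n_probes=5, placement="all")
        system, traj, _ = build_synthetic(spec)
        prof = probe_orientation_vs_normal(system, traj)
        flipped = [type(p)(p.heavy_atoms, p.hydroxyl_oxygen, p.central_carbon)
                   for p in system.probes]
        system.probes = flipped
        prof2 = probe_orientation_vs_normal(system, traj)
        occ = prof.counts > 0
        assert np.allclose(prof2.mean_cos[occ], -prof.mean_cos[occ],
                           atol=1e-12, equal_nan=True)

    def test_empty_bins_are_nan_not_zero(self):
        spec = SynthSpec(seed=3, n_frames=3, n_probes=2, placement="distal")
        system, traj, _ = build_synthetic(spec)
        prof = probe_orientation_vs_normal(system, traj)
        assert np.all(np.isnan(prof.mean_cos[prof.counts == 0]))


def _surface_fixture(orientation, n_frames=20):
    plant = ContactPlant(atom=0, probe=0, distance=2.0,
                         frames=tuple(range(n_frames)),
                         orientation=orientation)
    spec = SynthSpec(seed=4, n_protein_atoms=4, protein_spacing=30.0,
                     n_probes=4, n_lipids_per_leaflet=16,
                     box=(120.0, 120.0, 150.0), midplane_z=50.0,
                     n_frames=n_frames, contact_schedule=(plant,))
    system, traj, gt = build_synthetic(spec)
    prof = compute_occupancy(system, traj)
    orient = probe_orientation_vs_surface(system, traj, prof, threshold=0.24)
    return system, gt, orient


class TestOrientationVsSurface:
    def test_radial_out_gives_plus_one(self):
        system, gt, orient = _surface_fixture("radial_out")
        gi = int(system.protein_heavy[0])
        assert orient.mean_cos[gi] == pytest.approx(1.0, abs=1e-9)

    def test_radial_in_gives_minus_one(self):
        system, gt, orient = _surface_fixture("radial_in")
        gi = int(system.protein_heavy[0])
        assert orient.mean_cos[gi] == pytest.approx(-1.0, abs=1e-9)

    def test_fixed_45_degrees_gives_sqrt_half(self):
        system, gt, orient = _surface_fixture(("fixed_angle", 45.0))
        gi = int(system.protein_heavy[0])
        assert orient.mean_cos[gi] == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_atoms_below_threshold_are_absent(self):
        system, gt, orient = _surface_fixture("radial_out")
        # only the planted bead has occupancy; the others sit below 0.24
        assert set(orient.mean_cos) == {int(system.protein_heavy[0])}

    def test_no_atoms_above_threshold_warns_and_returns_empty(self):
        spec = SynthSpec(seed=5, n_frames=3, n_probes=2)
        system, traj, _ = build_synthetic(spec)
        prof = compute_occupancy(system, traj)
        orient = probe_orientation_vs_surface(system, traj, prof,
                                              threshold=0.24)
        assert orient.mean_cos == {}


class TestBilayerMetrics:
    def test_area_per_lipid_exact_arithmetic(self):
        spec = SynthSpec(seed=1, n_frames=4, box=(80.0, 80.0, 90.0),
                         n_lipids_per_leaflet=128)
        system, traj, _ = build_synthetic(spec)
        m = area_per_lipid(system, traj, leaflet="upper")
        assert m.mean == pytest.approx(50.0, rel=1e-12)
        assert m.sd == 0.0

    def test_large_bilayer_lattice_value(self):
        # 208 lipids per leaflet in a 112.4 x 112.4 A^2 box
        spec = SynthSpec(seed=1, n_frames=2, box=(112.4, 112.4, 90.0),
                         n_lipids_per_leaflet=208)
        system, traj, _ = build_synthetic(spec)
        m = area_per_lipid(system, traj)
        assert m.mean == pytest.approx(112.4 * 112.4 / 208, rel=1e-12)
        assert m.mean == pytest.approx(60.74, abs=0.01)

    def test_fluctuating_box_sd_matches_recompute(self):
        spec = SynthSpec(seed=7, n_frames=6, n_lipids_per_leaflet=36)
        system, traj, _ = build_synthetic(spec)
        rng = np.random.default_rng(13)
        boxes = traj.boxes.copy()
        boxes[:, 0] *= rng.uniform(0.95, 1.05, traj.n_frames)
        traj = Trajectory(traj.coordinates, boxes, traj.times)
        m = area_per_lipid(system, traj, leaflet="upper")
        series = boxes[:, 0] * boxes[:, 1] / 36
        assert m.mean == pytest.approx(series.mean(), rel=1e-12)
        assert m.sd == pytest.approx(series.std(ddof=1), rel=1e-12)

    def test_empty_leaflet_rejected(self):
        system, coords, box = make_bare_system(
            [[30.0, 30.0, 30.0]], [tetra_probe([30, 30, 55])],
            lipid_z=([50.0] * 4, []))
        with pytest.raises(ValueError):
            area_per_lipid(system, static_trajectory(coords, box), "lower")

    def test_thickness_of_flat_sheets_is_exact(self):
        system, coords, box = make_bare_system(
            [[30.0, 30.0, 30.0]], [tetra_probe([30, 30, 55])],
            lipid_z=([50.0] * 5, [10.0] * 5))
        m = bilayer_thickness(system, static_trajectory(coords, box, 3))
        assert m.mean == pytest.approx(40.0, rel=1e-12)
        assert m.sd == 0.0

    def test_thickness_with_phosphate_jitter(self):
        # 100 phosphates per leaflet, sigma = 1 A: leaflet-mean SEM = 0.1,
        # so the per-frame thickness scatters ~0.14 around 38
        spec = SynthSpec(seed=10, n_frames=50, n_lipids_per_leaflet=100,
                         box=(80.0, 80.0, 90.0), phosphate_jitter=1.0)
        system, traj, _ = build_synthetic(spec)
        m = bilayer_thickness(system, traj)
        assert m.mean == pytest.approx(2 * spec.leaflet_z, abs=0.3)
        assert 0.0 < m.sd < 0.5

    def test_single_frame_sd_is_zero(self):
        spec = SynthSpec(seed=1, n_frames=1)
        system, traj, _ = build_synthetic(spec)
        assert bilayer_thickness(system, traj).sd == 0.0

    def test_metrics_invariant_under_z_translation(self):
        spec = SynthSpec(seed=2, n_frames=3)
        system, traj, _ = build_synthetic(spec)
        shifted = Trajectory(traj.coordinates + np.array([0.0, 0.0, 7.5]),
                             traj.boxes, traj.times)
        assert bilayer_thickness(system, traj).mean == pytest.approx(
            bilayer_thickness(system, shifted).mean, rel=1e-12)
        assert area_per_lipid(system, traj).mean == pytest.approx(
            area_per_lipid(system, shifted).mean, rel=1e-12)
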
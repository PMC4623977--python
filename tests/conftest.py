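"""Shared fixtures: small seeded synthetic systems with known structure."""

import numpy as np
import pytest

from pmdmembrane.model import (AtomRecord, ProbeTopology, SystemModel,
                               Trajectory)
from pmdmembrane.synth import ContactPlant, SynthSpec, build_synthetic


def make_bare_system(protein_xyz, probe_xyz_list, box=(60.0, 60.0, 60.0),
                     lipid_z=None):
    """Hand-built SystemModel + single-frame coordinate template.

    ``probe_xyz_list``: list of (4, 3) arrays (C1, C2, C3, O2 order; C2 is
    the central carbon, O2 the hydroxyl oxygen).  ``lipid_z``: optional
    (upper_z_array, lower_z_array) of phosphate sheet heights; each lipid
    is a single phosphate bead.
    """
    atoms, coords = [], []

    def add(name, resname, resid, element, mass):
        atoms.append(AtomRecord(index=len(atoms), name=name,
                                residue_name=resname, residue_id=resid,
                                segment="X", element=element, mass=mass))

    protein_idx = []
    for i, p in enumerate(np.atleast_2d(protein_xyz)):
        add("CA", "PRO", 1, "C", 12.011)
        coords.append(np.asarray(p, dtype=float))
        protein_idx.append(len(atoms) - 1)

    phosphate_idx, upper, lower = [], set(), set()
    resid = 1
    if lipid_z is not None:
        for which, zs in zip(("u", "l"), lipid_z):
            for z in np.atleast_1d(zs):
                resid += 1
                add("P", "LIP", resid, "P", 30.974)
                coords.append(np.array([30.0, 30.0, float(z)]))
                phosphate_idx.append(len(atoms) - 1)
                (upper if which == "u" else lower).add(resid)

    probes = []
    for px in probe_xyz_list:
        resid += 1
        start = len(atoms)
        for name, el, m in (("C1", "C", 12.011), ("C2", "C", 12.011),
                            ("C3", "C", 12.011), ("O2", "O", 15.999)):
            add(name, "IPA", resid, el, m)
        for row in np.asarray(px, dtype=float):
            coords.append(row)
        probes.append(ProbeTopology(tuple(range(start, start + 4)),
                                    central_carbon=start + 1,
                                    hydroxyl_oxygen=start + 3))

    system = SystemModel(
        atoms=atoms,
        protein_heavy=np.array(protein_idx, dtype=int),
        probes=probes,
        lipid_phosphates=np.array(phosphate_idx, dtype=int),
        leaflet_upper=frozenset(upper),
        leaflet_lower=frozenset(lower),
    )
    system.validate()
    return system, np.array(coords), np.asarray(box, dtype=float)


def static_trajectory(coords, box, n_frames=1):
    """Trajectory repeating one coordinate frame."""
    return Trajectory(np.repeat(coords[None], n_frames, axis=0),
                      np.tile(box, (n_frames, 1)),
                      np.arange(n_frames, dtype=float))


def tetra_probe(center, u=(0.0, 0.0, 1.0), size=1.0):
    """(4, 3) probe coordinates with C2 at center and O2 along u.

    ``size`` scales the internal bond lengths (a small value packs all
    four heavy atoms into a sub-Å blob for single-voxel tests).
    """
    u = np.asarray(u, dtype=float)
    u = u / np.linalg.norm(u)
    e = np.array([1.0, 0.0, 0.0])
    if abs(u @ e) > 0.9:
        e = np.array([0.0, 1.0, 0.0])
    v = e - (e @ u) * u
    v /= np.linalg.norm(v)
    c = np.asarray(center, dtype=float)
    return np.array([c + size * (0.505 * u + 1.438 * v),   # C1
                     c,                                    # C2 (central)
                     c + size * (0.505 * u - 1.438 * v),   # C3
                     c + size * 1.43 * u])                 # O2


def isolated_recovery_spec(seed=11, n_frames=2000,
                           probabilities=(1.0, 0.5, 0.1)):
    """Fixture where planted beads are isolated beyond the switching range.

    Protein beads 30 Å apart in a large box, probes otherwise across the
    bilayer, so each planted bead's occupancy is exactly
    scale * p / N_probes up to < 1e-10 background.
    """
    plants = tuple(
        ContactPlant(atom=i, probe=i, distance=0.0, probability=p)
        for i, p in enumerate(probabilities)
    )
    return SynthSpec(seed=seed, n_protein_atoms=4, protein_spacing=30.0,
                     n_probes=10, n_lipids_per_leaflet=16,
                     box=(120.0, 120.0, 150.0), midplane_z=50.0,
                     leaflet_z=19.0, n_frames=n_frames,
                     contact_schedule=plants)


@pytest.fixture(scope="session")
def recovery_run():
    """2,000-frame isolated-plant run shared by the heavier tests."""
    spec = isolated_recovery_spec()
    system, traj, gt = build_synthetic(spec)
    return spec, system, traj, gt
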
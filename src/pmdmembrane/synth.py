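"""Seeded synthetic system/trajectory generator with analytically known structure.

Every estimator in the toolkit is validated against fixtures produced
here: a two-leaflet slab of 3-bead pseudo-lipids (phosphate marker +
two CTL2-labelled tail beads) on leaflet lattices, a rigid pseudo-protein
bead blob resting on the upper leaflet surface, and rigid 4-heavy-atom
probe molecules with a designated central carbon and hydroxyl oxygen.

Probes follow a *contact schedule*: a plant pins a probe's nearest heavy
atom at a chosen distance from a chosen protein atom in a chosen (or
Bernoulli-drawn) set of frames, with a controlled orientation relative to
the outward radial direction.  In all other frames probes are placed
uniformly in the solvent; by default in the solvent region *distal* to
the protein (across the bilayer, ≥ ~35 Å away), where the occupancy
kernel is < 1e-14, so the planted statistics are exact.  The resulting
:class:`GroundTruth` carries closed-form expectations for occupancy,
orientation order parameters, area per lipid and thickness.

Water is bookkept, not instantiated: analyses never touch water positions,
and the recorded count honours the 20:1 water-to-probe composition default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .io import _ELEMENT_MASSES, _element_from_name, default_type_table, make_universe
from .model import AtomRecord, ProbeTopology, SystemModel, Trajectory
from .occupancy import OccupancyParams, switching_weight

logger = logging.getLogger(__name__)

__all__ = ["ContactPlant", "SynthSpec", "GroundTruth", "build_synthetic",
           "make_paired_runs"]

# rigid probe internal geometry, relative to the central carbon, in the
# orientation frame (u = C->O direction, v/w completing the basis); the
# non-central atoms sit in the forward hemisphere so that for a radially
# planted probe the central carbon is always the atom nearest the protein
_PROBE_OFFSETS = {
    "O2": (1.43, 0.0),     # (along u, along v) — O on the orientation axis
    "C1": (0.505, 1.438),
    "C3": (0.505, -1.438),
}
_PROBE_ATOM_ORDER = ("C1", "C2", "C3", "O2")


@dataclass(frozen=True)
class ContactPlant:
    """Pin one probe near one protein atom in selected frames.

    ``atom`` is the 0-based ordinal of the protein bead (not a global atom
    index).  Exactly one of ``frames`` (explicit frame indices) or
    ``probability`` (per-frame Bernoulli contact probability) must be
    given.  ``orientation``: ``"radial_out"`` (hydroxyl O away from the
    protein centre), ``"radial_in"``, or ``("fixed_angle", degrees)``.
    """

    atom: int
    probe: int
    distance: float = 0.0
    frames: tuple[int, ...] | None = None
    probability: float | None = None
    orientation: object = "radial_out"

    def __post_init__(self) -> None:
        if (self.frames is None) == (self.probability is None):
            raise ValueError("specify exactly one of frames or probability")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError("contact probability must be in [0, 1]")
        if self.distance < 0:
            raise ValueError("planted distance must be >= 0")


@dataclass
class SynthSpec:
    """Study conditions of a synthetic run (all lengths in Å)."""

    seed: int = 0
    n_protein_atoms: int = 12
    n_probes: int = 10
    n_lipids_per_leaflet: int = 36
    box: tuple[float, float, float] = (60.0, 60.0, 90.0)
    n_frames: int = 100
    leaflet_z: float = 19.0          # phosphate offset from the midplane
    midplane_z: float = 30.0
    contact_schedule: tuple[ContactPlant, ...] = ()
    protein_spacing: float = 3.0      # protein bead lattice constant
    orientation_plan: str = "random"  # free probes: random | plus_z | minus_z
    placement: str = "distal"         # distal | upper | all
    exclusion_radius: float = 12.0    # protein stand-off for upper/all placement
    phosphate_jitter: float = 0.0     # per-frame Gaussian z jitter of phosphates
    water_per_probe: int = 20
    probe_fraction_label: str = "5%"
    dt_ps: float = 10.0

    def __post_init__(self) -> None:
        if min(self.n_protein_atoms, self.n_probes, self.n_frames) < 1:
            raise ValueError("need at least one protein atom, probe and frame")
        if self.n_lipids_per_leaflet < 0:
            raise ValueError("lipid count must be >= 0")
        if self.placement not in ("distal", "upper", "all"):
            raise ValueError("placement must be distal, upper or all")
        if not 0 < self.leaflet_z < self.midplane_z:
            raise ValueError("need 0 < leaflet_z < midplane_z")


@dataclass
class GroundTruth:
    """Closed-form expectations planted into a synthetic fixture.

    ``expected_R`` uses the planted contact *probabilities*;
    ``realized_R`` uses the contact frequencies actually drawn, so an
    estimator replaying the trajectory should match it to numerical
    precision.  Both are keyed by global atom index over all protein
    beads.  The free-probe background contribution is below 1e-12 in
    occupancy units by construction (distal placement) and is not
    included.
    """

    expected_R: dict[int, float]
    realized_R: dict[int, float]
    planted_probability: dict[int, float]
    expected_cos_surface: dict[int, float]
    protein_atoms: np.ndarray
    water_count: int
    probe_count: int
    expected_apl: float
    expected_thickness: float
    probe_fraction_label: str
    params: OccupancyParams


def _orientation_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.array([1.0, 0.0, 0.0])
    if abs(u @ e) > 0.9:
        e = np.array([0.0, 1.0, 0.0])
    v = e - (e @ u) * u
    v /= np.linalg.norm(v)
    return v, np.cross(u, v)


def _probe_coords(center_c: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """(4, 3) heavy-atom coordinates in _PROBE_ATOM_ORDER given orientation."""
    pos = {"C2": center_c}
    for name, (du, dv) in _PROBE_OFFSETS.items():
        pos[name] = center_c + du * u + dv * v
    return np.array([pos[n] for n in _PROBE_ATOM_ORDER])


def _build_atoms(spec: SynthSpec):
    """Static atom table + reference coordinates + selection bookkeeping."""
    table = default_type_table()
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name, resname, resid, seg):
        elem = _element_from_name(name)
        atoms.append(AtomRecord(
            index=len(atoms), name=name, residue_name=resname, residue_id=resid,
            segment=seg, type_label=table.get(resname, {}).get(name, ""),
            element=elem, mass=_ELEMENT_MASSES.get(elem, 12.011),
        ))

    lx, ly, lz = spec.box
    resid = 0
    phosphate_idx, tail_idx = [], []
    upper_res, lower_res = set(), set()

    n_lip = spec.n_lipids_per_leaflet
    if n_lip:
        nx = int(np.ceil(np.sqrt(n_lip)))
        for sign, res_set in ((1, upper_res), (-1, lower_res)):
            placed = 0
            for gx in range(nx):
                for gy in range(nx):
                    if placed >= n_lip:
                        break
                    resid += 1
                    res_set.add(resid)
                    x = (gx + 0.5) * lx / nx
                    y = (gy + 0.5) * ly / nx
                    zp = spec.midplane_z + sign * spec.leaflet_z
                    for name, dz in (("P", 0.0), ("C1", -5.0 * sign), ("C2", -10.0 * sign)):
                        add(name, "LIP", resid, "M")
                        coords.append(np.array([x, y, zp + dz]))
                        (phosphate_idx if name == "P" else tail_idx).append(
                            len(atoms) - 1)
                    placed += 1

    # rigid protein blob: cubic bead lattice on the upper leaflet surface
    resid += 1
    protein_res = resid
    m = int(np.ceil(spec.n_protein_atoms ** (1.0 / 3.0)))
    z_surface = spec.midplane_z + spec.leaflet_z + 6.0
    base = np.array([lx / 2.0, ly / 2.0, z_surface])
    protein_idx = []
    count = 0
    for gx in range(m):
        for gy in range(m):
            for gz in range(m):
                if count >= spec.n_protein_atoms:
                    break
                add("CA", "PRO", protein_res, "P")
                coords.append(base + spec.protein_spacing
                              * (np.array([gx, gy, gz]) - (m - 1) / 2.0))
                protein_idx.append(len(atoms) - 1)
                count += 1

    probes: list[ProbeTopology] = []
    probe_atom_start = []
    for _ in range(spec.n_probes):
        resid += 1
        start = len(atoms)
        for name in _PROBE_ATOM_ORDER:
            add(name, "IPA", resid, "S")
            coords.append(np.zeros(3))  # filled per frame
        probe_atom_start.append(start)
        idx = tuple(range(start, start + 4))
        probes.append(ProbeTopology(
            heavy_atoms=idx,
            central_carbon=start + _PROBE_ATOM_ORDER.index("C2"),
            hydroxyl_oxygen=start + _PROBE_ATOM_ORDER.index("O2"),
        ))

    system = SystemModel(
        atoms=atoms,
        protein_heavy=np.array(protein_idx, dtype=int),
        probes=probes,
        lipid_phosphates=np.array(phosphate_idx, dtype=int),
        leaflet_upper=frozenset(upper_res),
        leaflet_lower=frozenset(lower_res),
        lipid_tail_ctl2=np.array(tail_idx, dtype=int),
        metadata={"water_count": spec.water_per_probe * spec.n_probes,
                  "probe_fraction_label": spec.probe_fraction_label},
    )
    system.validate()
    return system, np.array(coords), probe_atom_start


def _solvent_sampler(spec: SynthSpec, protein_xyz: np.ndarray, rng):
    """Uniform free-probe centre sampler for the configured placement region."""
    lx, ly, lz = spec.box
    z_upper = spec.midplane_z + spec.leaflet_z
    z_lower = spec.midplane_z - spec.leaflet_z
    lower = (2.0, max(2.0 + 1e-6, z_lower - 2.0))
    upper = (z_upper + 2.0, lz - 2.0)

    def sample():
        for _ in range(10000):
            if spec.placement == "distal":
                zr = lower
            elif spec.placement == "upper":
                zr = upper
            else:  # all: pick slab proportionally to its thickness
                t_low = lower[1] - lower[0]
                t_up = upper[1] - upper[0]
                zr = lower if rng.random() < t_low / (t_low + t_up) else upper
            p = np.array([rng.uniform(0, lx), rng.uniform(0, ly),
                          rng.uniform(*zr)])
            if spec.placement == "distal":
                return p
            if np.min(np.linalg.norm(protein_xyz - p, axis=1)) >= spec.exclusion_radius:
                return p
        raise RuntimeError("could not place a free probe outside the "
                           "protein exclusion zone")

    return sample


def _free_orientation(spec: SynthSpec, rng) -> np.ndarray:
    if spec.orientation_plan == "plus_z":
        return np.array([0.0, 0.0, 1.0])
    if spec.orientation_plan == "minus_z":
        return np.array([0.0, 0.0, -1.0])
    vec = rng.standard_normal(3)
    return vec / np.linalg.norm(vec)


def _plant_geometry(plant: ContactPlant, protein_xyz: np.ndarray):
    """Deterministic planted placement: (4,3) coords, cos theta_r, d_min."""
    pc = protein_xyz.mean(axis=0)
    pa = protein_xyz[plant.atom]
    radial = pa - pc
    nr = np.linalg.norm(radial)
    direction = radial / nr if nr > 1e-9 else np.array([0.0, 0.0, 1.0])
    v_dir, _ = _orientation_basis(direction)
    if plant.orientation == "radial_out":
        u = direction
        cos_r = 1.0
    elif plant.orientation == "radial_in":
        u = -direction
        cos_r = -1.0
    else:
        kind, angle_deg = plant.orientation
        if kind != "fixed_angle":
            raise ValueError(f"unknown plant orientation {plant.orientation!r}")
        theta = np.deg2rad(float(angle_deg))
        u = np.cos(theta) * direction + np.sin(theta) * v_dir
        cos_r = float(np.cos(theta))
    v, _ = _orientation_basis(u)
    xyz = _probe_coords(pa + plant.distance * direction, u, v)
    per_atom_d = np.linalg.norm(xyz[:, None, :] - protein_xyz[None, :, :],
                                axis=2).min(axis=0)  # (n_protein,)
    return xyz, cos_r, per_atom_d


def build_synthetic(spec: SynthSpec, out_dir=None,
                    params: OccupancyParams = OccupancyParams(),
                    write_xtc: bool = False):
    """Generate (SystemModel, Trajectory, GroundTruth), optionally writing files.

    Deterministic for a fixed spec (seed included).  With ``out_dir`` set,
    writes ``system.pdb``, ``traj.dcd`` (and optionally ``traj.xtc``) and
    ``ground_truth.yaml`` there.
    """
    rng = np.random.default_rng(spec.seed)
    system, coords0, probe_start = _build_atoms(spec)
    protein_xyz = coords0[system.protein_heavy]
    sampler = _solvent_sampler(spec, protein_xyz, rng)

    # resolve plants: realized frame sets + deterministic geometry
    plants = []
    frame_claims: dict[tuple[int, int], int] = {}  # (frame, probe) -> plant no.
    for pi, plant in enumerate(spec.contact_schedule):
        if not 0 <= plant.atom < spec.n_protein_atoms:
            raise ValueError(f"plant {pi}: protein atom {plant.atom} out of range")
        if not 0 <= plant.probe < spec.n_probes:
            raise ValueError(f"plant {pi}: probe {plant.probe} out of range")
        if plant.frames is not None:
            frames = sorted(set(int(f) for f in plant.frames))
            if frames and (frames[0] < 0 or frames[-1] >= spec.n_frames):
                raise ValueError(f"plant {pi}: frame index out of range")
            prob = len(frames) / spec.n_frames
        else:
            mask = rng.random(spec.n_frames) < plant.probability
            frames = np.nonzero(mask)[0].tolist()
            prob = plant.probability
        for f in frames:
            key = (f, plant.probe)
            if key in frame_claims:
                raise ValueError(
                    f"plants {frame_claims[key]} and {pi} both claim probe "
                    f"{plant.probe} in frame {f}"
                )
            frame_claims[key] = pi
        xyz, cos_r, per_atom_d = _plant_geometry(plant, protein_xyz)
        plants.append({"plant": plant, "frames": set(frames), "prob": prob,
                       "xyz": xyz, "cos_r": cos_r, "per_atom_d": per_atom_d})

    # assemble frames
    n_atoms = system.n_atoms
    frames_xyz = np.empty((spec.n_frames, n_atoms, 3))
    boxes = np.tile(np.asarray(spec.box, dtype=float), (spec.n_frames, 1))
    times = np.arange(spec.n_frames, dtype=float) * spec.dt_ps
    for k in range(spec.n_frames):
        xyz = coords0.copy()
        if spec.phosphate_jitter > 0:
            jit = rng.normal(0.0, spec.phosphate_jitter,
                             size=system.lipid_phosphates.size)
            xyz[system.lipid_phosphates, 2] += jit
        placed = set()
        for entry in plants:
            if k in entry["frames"]:
                start = probe_start[entry["plant"].probe]
                xyz[start:start + 4] = entry["xyz"]
                placed.add(entry["plant"].probe)
        for j in range(spec.n_probes):
            if j in placed:
                continue
            center = sampler()
            u = _free_orientation(spec, rng)
            v, _ = _orientation_basis(u)
            start = probe_start[j]
            xyz[start:start + 4] = _probe_coords(center, u, v)
        frames_xyz[k] = xyz
    traj = Trajectory(frames_xyz, boxes, times)

    # ground-truth expectations (free-probe background < 1e-12, neglected)
    scale_per_probe = params.scale / spec.n_probes
    expected_R = {int(i): 0.0 for i in system.protein_heavy}
    realized_R = dict(expected_R)
    planted_probability: dict[int, float] = {}
    expected_cos: dict[int, float] = {}
    for entry in plants:
        w = switching_weight(entry["per_atom_d"], params)
        for a, gi in enumerate(system.protein_heavy):
            expected_R[int(gi)] += scale_per_probe * entry["prob"] * float(w[a])
            realized_R[int(gi)] += (scale_per_probe
                                    * len(entry["frames"]) / spec.n_frames
                                    * float(w[a]))
        gi = int(system.protein_heavy[entry["plant"].atom])
        planted_probability[gi] = planted_probability.get(gi, 0.0) + entry["prob"]
        expected_cos[gi] = entry["cos_r"]

    lx, ly, _ = spec.box
    gt = GroundTruth(
        expected_R=expected_R,
        realized_R=realized_R,
        planted_probability=planted_probability,
        expected_cos_surface=expected_cos,
        protein_atoms=system.protein_heavy.copy(),
        water_count=spec.water_per_probe * spec.n_probes,
        probe_count=spec.n_probes,
        expected_apl=(lx * ly / spec.n_lipids_per_leaflet
                      if spec.n_lipids_per_leaflet else float("nan")),
        expected_thickness=2.0 * spec.leaflet_z,
        probe_fraction_label=spec.probe_fraction_label,
        params=params,
    )

    if out_dir is not None:
        _write_fixture(system, traj, gt, spec, out_dir, write_xtc)
    return system, traj, gt


def _write_fixture(system: SystemModel, traj: Trajectory, gt: GroundTruth,
                   spec: SynthSpec, out_dir, write_xtc: bool) -> None:
    import MDAnalysis as mda

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pdb = out / "system.pdb"
    u = make_universe(system, traj.coordinates[0], box=traj.boxes[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(pdb))
    # record the bookkept water count in the header
    text = pdb.read_text().splitlines()
    remark = (f"REMARK 250 SYNTHETIC FIXTURE: WATER COUNT {gt.water_count} "
              f"(RATIO {spec.water_per_probe}:1), PROBES {gt.probe_count}")
    pdb.write_text("\n".join([remark, *text]) + "\n")

    targets = [out / "traj.dcd"] + ([out / "traj.xtc"] if write_xtc else [])
    for path in targets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
                for k in range(traj.n_frames):
                    u.atoms.positions = traj.coordinates[k]
                    u.dimensions = [*traj.boxes[k], 90.0, 90.0, 90.0]
                    u.trajectory.ts.time = traj.times[k]
                    w.write(u.atoms)

    payload = {
        "expected_R": {int(k): float(v) for k, v in gt.expected_R.items()},
        "realized_R": {int(k): float(v) for k, v in gt.realized_R.items()},
        "planted_probability": {int(k): float(v)
                                for k, v in gt.planted_probability.items()},
        "expected_cos_surface": {int(k): float(v)
                                 for k, v in gt.expected_cos_surface.items()},
        "protein_atoms": [int(i) for i in gt.protein_atoms],
        "water_count": int(gt.water_count),
        "probe_count": int(gt.probe_count),
        "expected_apl": float(gt.expected_apl),
        "expected_thickness": float(gt.expected_thickness),
        "probe_fraction_label": gt.probe_fraction_label,
        "seed": spec.seed,
    }
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def make_paired_runs(spec: SynthSpec, delta_p: dict[int, float],
                     params: OccupancyParams = OccupancyParams(),
                     seed_offset: int = 7919):
    """Two runs differing only in planted contact probabilities.

    ``delta_p`` maps protein-bead ordinals to probability shifts applied
    in run *y*; a bead without an existing plant gets a fresh plant
    (distance 0) on an unused probe.  Expected ΔR (x − y) per shifted bead
    is −scale·Δp/N_probes.  Returns ``((sys_x, traj_x, gt_x),
    (sys_y, traj_y, gt_y))``.
    """
    plants_x = list(spec.contact_schedule)
    by_atom = {p.atom: i for i, p in enumerate(plants_x)}
    used_probes = {p.probe for p in plants_x}
    plants_y = list(plants_x)
    extra_x = []
    for atom, dp in delta_p.items():
        if atom in by_atom:
            old = plants_y[by_atom[atom]]
            if old.probability is None:
                raise ValueError("probability shifts need probability-mode plants")
            new_p = old.probability + dp
            if not 0.0 <= new_p <= 1.0:
                raise ValueError(f"shifted probability {new_p} outside [0, 1]")
            plants_y[by_atom[atom]] = replace(old, probability=new_p)
        else:
            if not 0.0 <= dp <= 1.0:
                raise ValueError(f"new contact probability {dp} outside [0, 1]")
            free = next(j for j in range(spec.n_probes) if j not in used_probes)
            used_probes.add(free)
            new_plant = ContactPlant(atom=atom, probe=free, distance=0.0,
                                     probability=dp)
            plants_y.append(new_plant)
            extra_x.append(replace(new_plant, probability=0.0))
    spec_x = replace(spec, contact_schedule=tuple(plants_x + extra_x))
    spec_y = replace(spec, contact_schedule=tuple(plants_y),
                     seed=(spec.seed + seed_offset) % (2 ** 31 - 1))
    return build_synthetic(spec_x, params=params), build_synthetic(spec_y, params=params)
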
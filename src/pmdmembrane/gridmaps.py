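"""Grid-based probe densities and free energies.

Two complementary grid views of probe sampling around the protein:

* *proximal* number-density maps — only probes whose minimum heavy-atom
  distance to the protein is within a cutoff (default 4 Å) contribute;
  time-averaged counts per 1 Å³ voxel are Boltzmann-inverted to grid free
  energies G = −kB·T·ln(ρ/ρ_ref), so G ≤ −1 kcal/mol isosurfaces mark
  favourable probe sites;
* whole-box molar *concentration* profiles on a fine hexahedral mesh
  (default 0.37 Å spacing), normalised by the standard-state concentration
  C0 = 1 M = 1/1660.3 molecule/Å³ and per probe heavy atom, optionally
  denoised with a 7-point face-neighbour average.

Both assume the trajectory has first been rigid-body superposed onto a
reference frame (Kabsch least squares), which this module also provides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import N_PROBE_HEAVY, ScalarField3D, SystemModel, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "BOLTZMANN_KCAL",
    "C0_MOLECULES_PER_A3",
    "AlignmentSpec",
    "ConcentrationGrid",
    "FreeEnergyGrid",
    "align_trajectory",
    "proximal_density_grid",
    "density_to_free_energy",
    "concentration_grid",
    "smooth_grid",
    "threshold_isosurface_report",
]

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 0.0019872041
#: Standard-state concentration: 1 M in molecules per Å³.
C0_MOLECULES_PER_A3 = 1.0 / 1660.3


@dataclass
class AlignmentSpec:
    """Rigid-body superposition spec.

    ``reference``: frame index into the trajectory, or an (n_atoms, 3)
    coordinate array.  ``fit_atoms``: indices used for the least-squares
    fit; ``exclusions`` are removed from ``fit_atoms`` first (e.g. flexible
    switch regions and termini).
    """

    reference: int | np.ndarray = 0
    fit_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    exclusions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def resolved_fit(self) -> np.ndarray:
        fit = np.asarray(self.fit_atoms, dtype=int)
        excl = set(np.asarray(self.exclusions, dtype=int).tolist())
        return np.array([i for i in fit if i not in excl], dtype=int)


@dataclass
class ConcentrationGrid:
    """Molar probe concentration on a hexahedral mesh."""

    field: ScalarField3D
    c0: float = C0_MOLECULES_PER_A3
    n_heavy: int = N_PROBE_HEAVY
    frame_count: int = 0

    def conservation_sum(self) -> float:
        """Mean probe-molecule equivalents inside the grid per frame."""
        return float(self.field.values.sum() * self.field.voxel_volume * self.c0)


@dataclass
class FreeEnergyGrid:
    """Boltzmann-inverted grid free energies (kcal/mol)."""

    field: ScalarField3D
    temperature: float = 310.0
    reference_density: float = 0.0
    cap: float = 5.0


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation R and centroids aligning mobile onto reference."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mc, rc


def align_trajectory(system: SystemModel, traj: Trajectory,
                     spec: AlignmentSpec) -> Trajectory:
    """Superpose every frame onto the reference by least squares.

    The rotation/translation fitted on ``spec.fit_atoms`` (minus
    exclusions) is applied to *all* atoms of the frame, so inter-atomic
    distances — and hence occupancies — are unchanged.  Boxes and times
    are carried over unmodified.
    """
    fit = spec.resolved_fit()
    if fit.size < 3:
        raise ValueError("need at least 3 fit atoms for a rigid-body superposition")
    traj.check_against(system)
    if isinstance(spec.reference, (int, np.integer)):
        ref_xyz = traj.coordinates[int(spec.reference)][fit]
    else:
        ref_all = np.asarray(spec.reference, dtype=float)
        ref_xyz = ref_all[fit] if ref_all.shape[0] == system.n_atoms else ref_all
        if ref_xyz.shape != (fit.size, 3):
            raise ValueError("reference coordinates do not match fit selection")

    out = np.empty_like(traj.coordinates)
    for k in range(traj.n_frames):
        xyz = traj.coordinates[k]
        R, mc, rc = _kabsch(xyz[fit], ref_xyz)
        out[k] = (xyz - mc) @ R.T + rc
    return Trajectory(out, traj.boxes.copy(), traj.times.copy())


def _default_bounds(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounds of the largest box, anchored at the coordinate minimum."""
    lo = traj.coordinates.reshape(-1, 3).min(axis=0)
    span = traj.boxes.max(axis=0)
    return lo, lo + span


def _bin_counts(points: np.ndarray, origin: np.ndarray, spacing: np.ndarray,
                dims: tuple[int, int, int]) -> tuple[np.ndarray, int]:
    """Histogram points into half-open voxels [origin + i*dx, origin + (i+1)*dx).

    Returns (counts array, number of dropped out-of-range points); points
    exactly on the upper edge fall out of range and are dropped.
    """
    rel = (points - origin) / spacing
    idx = np.floor(rel).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(dims)), axis=1)
    counts = np.zeros(dims, dtype=float)
    if np.any(ok):
        np.add.at(counts, tuple(idx[ok].T), 1.0)
    return counts, int((~ok).sum())


def proximal_density_grid(system: SystemModel, traj: Trajectory,
                          cutoff: float = 4.0, spacing: float = 1.0,
                          bounds: tuple | None = None) -> ScalarField3D:
    """Time-averaged number density (per Å³) of protein-proximal probe heavy atoms.

    A probe contributes all its heavy atoms in frame k iff its minimum
    heavy-atom distance (minimum image) to any protein heavy atom is
    ≤ ``cutoff``; pass ``cutoff=None`` to include every probe.  The caller
    is responsible for aligning the trajectory first.
    """
    from .occupancy import min_probe_distances

    prot = system.protein_heavy
    probes = system.probe_heavy_indices()
    if prot.size == 0 or len(probes) == 0:
        raise ValueError("need protein heavy atoms and probes")
    traj.check_against(system)

    spacing3 = np.full(3, float(spacing))
    if bounds is None:
        lo, hi = _default_bounds(traj)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    dims = tuple(np.maximum(1, np.ceil((hi - lo) / spacing3 - 1e-9).astype(int)))

    counts = np.zeros(dims, dtype=float)
    dropped = 0
    for k in range(traj.n_frames):
        xyz = traj.coordinates[k]
        if cutoff is None:
            keep = np.ones(len(probes), dtype=bool)
        else:
            d = min_probe_distances(xyz[prot], xyz[probes], traj.boxes[k])
            keep = d.min(axis=0) <= cutoff
        if not np.any(keep):
            continue
        pts = xyz[probes[keep].ravel()]
        c, drop = _bin_counts(pts, lo, spacing3, dims)
        counts += c
        dropped += drop
    if dropped:
        logger.info("proximal_density_grid: %d heavy-atom positions fell "
                    "outside the grid bounds", dropped)
    voxel = float(np.prod(spacing3))
    return ScalarField3D(origin=lo, spacing=spacing3,
                         values=counts / (traj.n_frames * voxel),
                         units="A^-3")


def density_to_free_energy(density: ScalarField3D, reference_density: float,
                           temperature: float = 310.0,
                           cap: float = 5.0) -> FreeEnergyGrid:
    """Boltzmann inversion G = −kB·T·ln(ρ/ρ_ref), capped at +``cap``.

    Empty voxels (ρ = 0, log divergent) carry the cap value as a documented
    sentinel; any value above the cap is clipped to it.
    """
    if reference_density <= 0:
        raise ValueError("reference density must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rho = density.values
    kT = BOLTZMANN_KCAL * temperature
    G = np.full_like(rho, float(cap))
    pos = rho > 0
    with np.errstate(divide="ignore"):
        G[pos] = -kT * np.log(rho[pos] / reference_density)
    G = np.minimum(G, cap)
    fld = ScalarField3D(origin=density.origin.copy(), spacing=density.spacing.copy(),
                        values=G, units="kcal/mol")
    return FreeEnergyGrid(field=fld, temperature=temperature,
                          reference_density=reference_density, cap=cap)


def concentration_grid(system: SystemModel, traj: Trajectory,
                       spacing: float = 0.37,
                       bounds: tuple | None = None) -> ConcentrationGrid:
    """Molar probe concentration c_ijk on a hexahedral mesh.

    c_ijk = (counts of probe heavy atoms in voxel, summed over frames)
    / (dx·dy·dz · N_frames · N_heavy · C0).  Conservation:
    ``conservation_sum()`` (= Σ c·V·C0) equals the mean number of
    probe-molecule equivalents inside the bounds per frame.
    """
    probes = system.probe_heavy_indices()
    if len(probes) == 0:
        raise ValueError("system has no probe molecules")
    traj.check_against(system)
    spacing3 = np.full(3, float(spacing))
    if bounds is None:
        lo, hi = _default_bounds(traj)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if np.any(hi - lo <= 0):
        raise ValueError("grid bounds have zero or negative extent")
    dims = tuple(np.maximum(1, np.ceil((hi - lo) / spacing3 - 1e-9).astype(int)))

    counts = np.zeros(dims, dtype=float)
    dropped = 0
    flat = probes.ravel()
    for k in range(traj.n_frames):
        c, drop = _bin_counts(traj.coordinates[k][flat], lo, spacing3, dims)
        counts += c
        dropped += drop
    if dropped:
        logger.info("concentration_grid: %d heavy-atom positions outside "
                    "bounds (includes upper-edge drops)", dropped)
    voxel = float(np.prod(spacing3))
    values = counts / (voxel * traj.n_frames * N_PROBE_HEAVY * C0_MOLECULES_PER_A3)
    fld = ScalarField3D(origin=lo, spacing=spacing3, values=values, units="M")
    return ConcentrationGrid(field=fld, frame_count=traj.n_frames)


def smooth_grid(grid: ConcentrationGrid, renormalize: bool = False) -> ConcentrationGrid:
    """7-point face-neighbour average: c' = (c + 6 face neighbours) / 7.

    Out-of-bounds neighbours contribute zero while the divisor stays 7
    (the literal reading of the averaging formula); ``renormalize=True``
    divides by the actual neighbour count instead, which conserves mass at
    the boundary too.
    """
    c = grid.field.values
    acc = c.copy()
    cnt = np.ones_like(c)
    for axis in range(3):
        for shift in (1, -1):
            rolled = np.roll(c, shift, axis=axis)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = 0.0
            acc += rolled
            mask = np.ones_like(c)
            mask[tuple(sl)] = 0.0
            cnt += mask
    out = acc / cnt if renormalize else acc / 7.0
    fld = ScalarField3D(origin=grid.field.origin.copy(),
                        spacing=grid.field.spacing.copy(),
                        values=out, units=grid.field.units)
    return ConcentrationGrid(field=fld, c0=grid.c0, n_heavy=grid.n_heavy,
                             frame_count=grid.frame_count)


def threshold_isosurface_report(grid: ScalarField3D, level: float,
                                direction: str = "below") -> tuple[int, ScalarField3D]:
    """Count nodes passing a threshold and export a 0/1 mask field.

    ``direction='below'`` selects nodes ≤ level (e.g. free energy
    ≤ −1 kcal/mol); ``'above'`` selects nodes ≥ level (e.g. concentration
    ≥ 3.2 M).
    """
    if direction == "below":
        mask = grid.values <= level
    elif direction == "above":
        mask = grid.values >= level
    else:
        raise ValueError("direction must be 'above' or 'below'")
    fld = ScalarField3D(origin=grid.origin.copy(), spacing=grid.spacing.copy(),
                        values=mask.astype(float), units="mask")
    return int(mask.sum()), fld
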
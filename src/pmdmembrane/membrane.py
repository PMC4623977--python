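"""Bilayer diagnostics and probe orientation order parameters.

Whether a co-solvent probe perturbs the bilayer is judged from four
estimators: the number-density profile of lipid phosphates and probe
centres of mass along the bilayer normal (the box z axis), the probe
orientation order parameter ⟨cos θ⟩ against the membrane normal, the area
per lipid Lx·Ly/N per leaflet, and the bilayer thickness (distance between
mean phosphate z of the two leaflets).  A fifth estimator reports probe
orientation against the *protein* surface: ⟨cos θ_r⟩ between the probe
central-carbon→hydroxyl-oxygen vector and the outward radial direction
from the protein centre, at protein atoms whose occupancy exceeds a
threshold — positive values mean the hydroxyl points away from the
surface, i.e. the site is apolar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import SystemModel, Trajectory
from .occupancy import OccupancyProfile, min_probe_distances

logger = logging.getLogger(__name__)

__all__ = [
    "DensityProfileZ",
    "OrientationProfileZ",
    "SurfaceOrientation",
    "BilayerMetrics",
    "density_profile_z",
    "probe_orientation_vs_normal",
    "probe_orientation_vs_surface",
    "area_per_lipid",
    "bilayer_thickness",
]


@dataclass
class DensityProfileZ:
    bin_centers: np.ndarray
    bin_width: float
    lipid_phosphate: np.ndarray   # number density per Å³
    probe_center_of_mass: np.ndarray

    def integral(self, group: str, box_xy_area: float) -> float:
        """Mean per-frame group count recovered from the profile."""
        rho = getattr(self, group)
        return float(rho.sum() * box_xy_area * self.bin_width)


@dataclass
class OrientationProfileZ:
    bin_centers: np.ndarray
    mean_cos: np.ndarray   # NaN where a bin is empty
    counts: np.ndarray


@dataclass
class SurfaceOrientation:
    mean_cos: dict[int, float]
    threshold: float
    center: np.ndarray
    event_counts: dict[int, int] | None = None


@dataclass
class BilayerMetrics:
    series: np.ndarray    # per-frame values
    mean: float
    sd: float
    units: str = "A"


def _probe_com(system: SystemModel, xyz: np.ndarray) -> np.ndarray:
    """Centres of mass of probe heavy atoms, shape (n_probes, 3)."""
    probes = system.probe_heavy_indices()
    masses = np.array([[system.atoms[i].mass for i in row] for row in probes])
    pos = xyz[probes]                                    # (J, H, 3)
    return (pos * masses[..., None]).sum(axis=1) / masses.sum(axis=1)[:, None]


def density_profile_z(system: SystemModel, traj: Trajectory,
                      bin_width: float = 1.0, recenter: bool = True) -> DensityProfileZ:
    """Per-group number density along z, averaged over frames.

    Phosphates contribute one count per atom; probes contribute their
    heavy-atom centre of mass.  ``recenter`` shifts z per frame so the
    bilayer midplane (mean phosphate z) sits at 0.  Densities divide by
    Lx·Ly·bin_width of each frame.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if system.lipid_phosphates.size == 0:
        raise ValueError("phosphate selection is empty")
    traj.check_against(system)

    # common z range across frames, after optional recentring
    z_phos_all, z_com_all, weights = [], [], []
    for k in range(traj.n_frames):
        xyz = traj.coordinates[k]
        zp = xyz[system.lipid_phosphates, 2]
        shift = zp.mean() if recenter else 0.0
        z_phos_all.append(zp - shift)
        if system.probes:
            z_com_all.append(_probe_com(system, xyz)[:, 2] - shift)
        else:
            z_com_all.append(np.empty(0))
        weights.append(1.0 / (traj.boxes[k, 0] * traj.boxes[k, 1]))

    allz = np.concatenate(z_phos_all + z_com_all)
    lo = np.floor(allz.min() / bin_width) * bin_width
    hi = np.ceil(allz.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    rho_p = np.zeros(centers.size)
    rho_c = np.zeros(centers.size)
    for k in range(traj.n_frames):
        rho_p += np.histogram(z_phos_all[k], bins=edges)[0] * weights[k]
        if z_com_all[k].size:
            rho_c += np.histogram(z_com_all[k], bins=edges)[0] * weights[k]
    norm = traj.n_frames * bin_width
    return DensityProfileZ(bin_centers=centers, bin_width=bin_width,
                           lipid_phosphate=rho_p / norm,
                           probe_center_of_mass=rho_c / norm)


def probe_orientation_vs_normal(system: SystemModel, traj: Trajectory,
                                bin_width: float = 1.0,
                                recenter: bool = True) -> OrientationProfileZ:
    """⟨cos θ⟩ of the probe C→O vector against +z, binned by probe COM z.

    Probe-frames with a zero-length C→O vector are skipped (count logged).
    Empty bins report NaN, distinguishing "no data" from ⟨cos θ⟩ = 0.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not system.probes:
        raise ValueError("system has no probes")
    traj.check_against(system)
    cc = np.array([p.central_carbon for p in system.probes])
    oh = np.array([p.hydroxyl_oxygen for p in system.probes])

    zvals, cosvals = [], []
    skipped = 0
    for k in range(traj.n_frames):
        xyz = traj.coordinates[k]
        shift = xyz[system.lipid_phosphates, 2].mean() \
            if (recenter and system.lipid_phosphates.size) else 0.0
        vec = xyz[oh] - xyz[cc]
        norm = np.linalg.norm(vec, axis=1)
        ok = norm > 1e-12
        skipped += int((~ok).sum())
        com_z = _probe_com(system, xyz)[:, 2] - shift
        zvals.append(com_z[ok])
        cosvals.append(vec[ok, 2] / norm[ok])
    if skipped:
        logger.warning("probe_orientation_vs_normal: skipped %d zero-length "
                       "C->O probe-frames", skipped)
    z = np.concatenate(zvals)
    c = np.concatenate(cosvals)
    lo = np.floor(z.min() / bin_width) * bin_width
    edges = np.arange(lo, z.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    idx = np.clip(np.digitize(z, edges) - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1).astype(int)
    sums = np.bincount(idx, weights=c, minlength=edges.size - 1)
    mean = np.full(counts.size, np.nan)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    return OrientationProfileZ(bin_centers=0.5 * (edges[:-1] + edges[1:]),
                               mean_cos=mean, counts=counts)


def probe_orientation_vs_surface(system: SystemModel, traj: Trajectory,
                                 occupancy: OccupancyProfile,
                                 threshold: float = 0.24,
                                 contact_cutoff: float = 6.0,
                                 center_selection: np.ndarray | None = None,
                                 ) -> SurfaceOrientation:
    """⟨cos θ_r⟩ per retained protein atom against the outward radial direction.

    Retained atoms have occupancy R_i ≥ ``threshold``.  For each frame and
    each probe in contact with a retained atom (minimum heavy-atom
    distance ≤ ``contact_cutoff``, minimum image), cos θ_r between the
    probe C→O unit vector and the unit vector from the protein centre
    (geometric centre of ``center_selection``, default all protein heavy
    atoms) to the atom is accumulated; per-atom means are returned.
    """
    traj.check_against(system)
    retained = np.array(sorted(i for i, r in occupancy.R.items() if r >= threshold),
                        dtype=int)
    if retained.size == 0:
        logger.warning("no protein atoms pass the occupancy threshold %.3g", threshold)
        return SurfaceOrientation({}, threshold, np.full(3, np.nan), {})
    if center_selection is None:
        center_selection = system.protein_heavy
    probes = system.probe_heavy_indices()
    cc = np.array([p.central_carbon for p in system.probes])
    oh = np.array([p.hydroxyl_oxygen for p in system.probes])

    sums = {int(i): 0.0 for i in retained}
    counts = {int(i): 0 for i in retained}
    center_acc = np.zeros(3)
    for k in range(traj.n_frames):
        xyz = traj.coordinates[k]
        center = xyz[center_selection].mean(axis=0)
        center_acc += center
        vec = xyz[oh] - xyz[cc]
        vnorm = np.linalg.norm(vec, axis=1)
        ok = vnorm > 1e-12
        d = min_probe_distances(xyz[retained], xyz[probes], traj.boxes[k])
        radial = xyz[retained] - center
        rnorm = np.linalg.norm(radial, axis=1)
        for a, i in enumerate(retained):
            if rnorm[a] <= 1e-12:
                continue
            contacts = np.where(ok & (d[a] <= contact_cutoff))[0]
            for j in contacts:
                cosv = float(vec[j] @ radial[a] / (vnorm[j] * rnorm[a]))
                sums[int(i)] += cosv
                counts[int(i)] += 1
    mean = {i: sums[i] / counts[i] for i in sums if counts[i] > 0}
    return SurfaceOrientation(mean_cos=mean, threshold=threshold,
                              center=center_acc / traj.n_frames,
                              event_counts=counts)


def _leaflet_counts(system: SystemModel, leaflet: str) -> int:
    if leaflet == "upper":
        return len(system.leaflet_upper)
    if leaflet == "lower":
        return len(system.leaflet_lower)
    raise ValueError("leaflet must be 'upper', 'lower' or 'both'")


def area_per_lipid(system: SystemModel, traj: Trajectory,
                   leaflet: str = "both") -> BilayerMetrics:
    """Per-frame area per lipid Lx·Ly/N_lipids; 'both' averages the leaflets."""
    traj.check_against(system)
    if leaflet == "both":
        nu, nl = len(system.leaflet_upper), len(system.leaflet_lower)
        if nu == 0 or nl == 0:
            raise ValueError("both leaflets must be non-empty")
        area = traj.boxes[:, 0] * traj.boxes[:, 1]
        series = 0.5 * (area / nu + area / nl)
    else:
        n = _leaflet_counts(system, leaflet)
        if n == 0:
            raise ValueError(f"{leaflet} leaflet is empty")
        series = traj.boxes[:, 0] * traj.boxes[:, 1] / n
    return BilayerMetrics(series=series, mean=float(series.mean()),
                          sd=float(series.std(ddof=1)) if series.size > 1 else 0.0,
                          units="A^2")


def bilayer_thickness(system: SystemModel, traj: Trajectory) -> BilayerMetrics:
    """Per-frame |mean phosphate z(upper) − mean phosphate z(lower)|."""
    traj.check_against(system)
    if not system.leaflet_upper or not system.leaflet_lower:
        raise ValueError("both leaflets must be non-empty")
    up_idx = np.array([i for i in system.lipid_phosphates
                       if system.atoms[i].residue_id in system.leaflet_upper])
    lo_idx = np.array([i for i in system.lipid_phosphates
                       if system.atoms[i].residue_id in system.leaflet_lower])
    if up_idx.size == 0 or lo_idx.size == 0:
        raise ValueError("a leaflet has no phosphate atoms")
    series = np.abs(traj.coordinates[:, up_idx, 2].mean(axis=1)
                    - traj.coordinates[:, lo_idx, 2].mean(axis=1))
    return BilayerMetrics(series=series, mean=float(series.mean()),
                          sd=float(series.std(ddof=1)) if series.size > 1 else 0.0,
                          units="A")
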
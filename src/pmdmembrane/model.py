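"""Shared in-memory data model.

The toolkit analyses probe-based MD simulations of membrane-bound proteins:
a protein sitting on a lipid bilayer in mixed water/organic-probe solvent.
Every analysis consumes the same two containers, a :class:`SystemModel`
(atoms plus resolved role selections: protein heavy atoms, probe molecules,
lipid phosphates, leaflets, lipid-tail carbons) and a :class:`Trajectory`
(frames of coordinates with orthorhombic periodic boxes).

Coordinates are in Å, times in ps, masses in amu.  Indices are 0-based
internally; PDB serial numbers become 1-based only on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "ProbeTopology",
    "SystemModel",
    "Trajectory",
    "ScalarField3D",
    "N_PROBE_HEAVY",
]

#: Heavy atoms per probe molecule (isopropanol: three carbons + hydroxyl O).
N_PROBE_HEAVY = 4


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity and classification, no coordinates."""

    index: int
    name: str
    residue_name: str
    residue_id: int
    segment: str = ""
    type_label: str = ""  # CHARMM atom type, e.g. "CTL2"; may be empty
    element: str = ""
    mass: float = 0.0

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"atom {self.index}: mass must be >= 0")


@dataclass(frozen=True)
class ProbeTopology:
    """Heavy-atom layout of one probe molecule.

    A probe carries exactly ``N_PROBE_HEAVY`` heavy atoms, one of which is
    the designated central carbon and one the hydroxyl oxygen; the central
    carbon → hydroxyl oxygen vector defines the probe orientation used by
    the order-parameter analyses.
    """

    heavy_atoms: tuple[int, ...]
    central_carbon: int
    hydroxyl_oxygen: int

    def __post_init__(self) -> None:
        if len(self.heavy_atoms) != N_PROBE_HEAVY:
            raise ValueError(
                f"probe must have exactly {N_PROBE_HEAVY} heavy atoms, "
                f"got {len(self.heavy_atoms)}"
            )
        if len(set(self.heavy_atoms)) != N_PROBE_HEAVY:
            raise ValueError("probe heavy atoms must be distinct")
        if self.central_carbon not in self.heavy_atoms:
            raise ValueError("central carbon must be one of the heavy atoms")
        if self.hydroxyl_oxygen not in self.heavy_atoms:
            raise ValueError("hydroxyl oxygen must be one of the heavy atoms")
        if self.central_carbon == self.hydroxyl_oxygen:
            raise ValueError("central carbon and hydroxyl oxygen must differ")


@dataclass
class SystemModel:
    """Atoms plus resolved role selections.

    Selections are numpy integer index arrays into ``atoms``.  Leaflet
    membership is stored as sets of lipid residue ids (a lipid belongs to
    exactly one leaflet).
    """

    atoms: list[AtomRecord]
    protein_heavy: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    probes: list[ProbeTopology] = field(default_factory=list)
    lipid_phosphates: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    leaflet_upper: frozenset[int] = frozenset()
    leaflet_lower: frozenset[int] = frozenset()
    lipid_tail_ctl2: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    #: bookkeeping extras (e.g. recorded water count); not used by estimators
    metadata: dict = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self) -> None:
        """Check structural invariants; raise ``ValueError`` on violation."""
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be 0-based and contiguous")
        probe_set: set[int] = set()
        for p in self.probes:
            probe_set.update(p.heavy_atoms)
        prot = set(self.protein_heavy.tolist())
        lip = set(self.lipid_phosphates.tolist()) | set(self.lipid_tail_ctl2.tolist())
        if probe_set & prot:
            raise ValueError("probe heavy atoms overlap protein selection")
        if probe_set & lip:
            raise ValueError("probe heavy atoms overlap lipid selections")
        if set(self.leaflet_upper) & set(self.leaflet_lower):
            raise ValueError("leaflet residue sets must be disjoint")
        n = self.n_atoms
        for sel in (self.protein_heavy, self.lipid_phosphates, self.lipid_tail_ctl2):
            if sel.size and (sel.min() < 0 or sel.max() >= n):
                raise ValueError("selection index out of range")

    def probe_heavy_indices(self) -> np.ndarray:
        """(n_probes, N_PROBE_HEAVY) array of heavy-atom indices."""
        if not self.probes:
            return np.empty((0, N_PROBE_HEAVY), dtype=int)
        return np.array([p.heavy_atoms for p in self.probes], dtype=int)


@dataclass
class Trajectory:
    """Ordered frames of coordinates with orthorhombic periodic boxes.

    ``coordinates``: (n_frames, n_atoms, 3) in Å.
    ``boxes``: (n_frames, 3) orthorhombic box lengths (Lx, Ly, Lz) in Å.
    ``times``: (n_frames,) in ps, non-decreasing.
    """

    coordinates: np.ndarray
    boxes: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        nf = self.coordinates.shape[0]
        if self.boxes.shape != (nf, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if self.times.shape != (nf,):
            raise ValueError("times must have shape (n_frames,)")
        if nf and np.any(self.boxes <= 0):
            raise ValueError("box lengths must be positive")
        if nf > 1 and np.any(np.diff(self.times) < 0):
            raise ValueError("frame times must be non-decreasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def check_against(self, system: SystemModel) -> None:
        if self.n_atoms != system.n_atoms:
            raise ValueError(
                f"trajectory has {self.n_atoms} atoms but system has "
                f"{system.n_atoms}"
            )

    def slice(self, start: int | None = None, stop: int | None = None,
              stride: int | None = None) -> "Trajectory":
        sl = slice(start, stop, stride)
        return Trajectory(self.coordinates[sl], self.boxes[sl], self.times[sl])


@dataclass
class ScalarField3D:
    """Regular hexahedral scalar field (node-centred values).

    Node (i, j, k) sits at ``origin + (i*dx, j*dy, k*dz)``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray  # shape (nx, ny, nz)
    units: str = ""

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,) or self.spacing.shape != (3,):
            raise ValueError("origin and spacing must be 3-vectors")
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))
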
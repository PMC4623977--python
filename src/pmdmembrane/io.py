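"""Topology/trajectory reading, role-selection resolution, and writers.

Reading goes through MDAnalysis (PDB topology, DCD/XTC trajectories);
volumetric maps are written/read as OpenDX through gridDataFormats so any
standard molecular viewer can render them; per-atom scalar tables go to CSV
(pandas) or into the temperature-factor column of a PDB for structure
coloring.

CHARMM atom-type labels (needed to pick the lipid-tail repulsion targets,
e.g. ``CTL2``) are not carried by PDB files, so they are attached from a
sidecar table mapping (residue name, atom name) -> type.  A built-in table
covers POPC/POPS acyl chains, isopropanol, and the synthetic reduced models
emitted by :mod:`pmdmembrane.synth`; user tables extend/override it via the
selection config.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from gridData import Grid

from .model import AtomRecord, ProbeTopology, ScalarField3D, SystemModel, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "TopologyError",
    "default_type_table",
    "load_selection_config",
    "load_system",
    "load_trajectory",
    "write_scalar_field",
    "read_scalar_field",
    "write_atom_scalars",
    "read_atom_scalars",
    "make_universe",
]


class ConfigurationError(ValueError):
    """Selection config refers to names absent from the topology."""


class TopologyError(ValueError):
    """Topology violates a structural requirement (e.g. probe atom count)."""


_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "NA": 22.990, "CL": 35.45, "K": 39.098,
}


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (leading digits stripped)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[:2].upper() in ("NA", "CL") and len(stripped) <= 3:
        return stripped[:2].upper()
    return stripped[0].upper()


def _chain_carbon_types(chain: int, last: int, double_bond: tuple[int, int] | None):
    """CHARMM36 acyl-chain carbon types for one lipid tail: C<chain>2..C<chain><last>."""
    out = {}
    for pos in range(2, last + 1):
        name = f"C{chain}{pos}"
        if double_bond and pos in double_bond:
            out[name] = "CEL1"
        elif pos == last:
            out[name] = "CTL3"
        else:
            out[name] = "CTL2"
    return out


def default_type_table() -> dict[str, dict[str, str]]:
    """Built-in (residue name -> atom name -> CHARMM type) sidecar table.

    Covers the atoms the analyses actually select on: lipid phosphates and
    acyl-chain carbons of POPC/POPS (palmitoyl sn-1, oleoyl sn-2 with the
    9-10 double bond), isopropanol heavy atoms (CGenFF-style labels), and
    the reduced synthetic residues (``LIP`` pseudo-lipid, ``PRO`` protein
    bead).
    """
    tails = {}
    tails.update(_chain_carbon_types(3, 16, None))          # palmitoyl sn-1
    tails.update(_chain_carbon_types(2, 18, (9, 10)))       # oleoyl sn-2
    popc = {"P": "PL", **tails}
    pops = {"P": "PL", **tails}
    ipa = {"C1": "CG331", "C2": "CG311", "C3": "CG331", "O2": "OG311"}
    return {
        "POPC": popc,
        "POPS": pops,
        "IPA": ipa,
        "LIP": {"P": "PL", "C1": "CTL2", "C2": "CTL2"},
        "PRO": {"CA": "CT1"},
    }


_DEFAULT_SOLVENT = ("TIP3", "HOH", "WAT", "SOL", "SOD", "CLA", "NA", "CL", "POT")


def load_selection_config(path_or_mapping) -> dict:
    """Load a selection config from YAML path or mapping; fill defaults."""
    if isinstance(path_or_mapping, (str, Path)):
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(path_or_mapping)
    probe = dict(cfg.get("probe", {}))
    probe.setdefault("resname", "IPA")
    probe.setdefault("central_carbon", "C2")
    probe.setdefault("hydroxyl_oxygen", "O2")
    lipids = dict(cfg.get("lipids", {}))
    lipids.setdefault("resnames", ["POPC", "POPS", "LIP"])
    lipids.setdefault("phosphate_atom", "P")
    lipids.setdefault("tail_type_labels", ["CTL2"])
    cfg["probe"] = probe
    cfg["lipids"] = lipids
    cfg.setdefault("protein", {})
    cfg.setdefault("solvent_resnames", list(_DEFAULT_SOLVENT))
    cfg.setdefault("type_table", {})
    return cfg


def _read_pdb_atoms(topology_path):
    """Parse a PDB into per-atom arrays + coordinates via MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
    atoms = u.atoms
    names = [str(n) for n in atoms.names]
    resnames = [str(r) for r in atoms.resnames]
    resids = [int(r) for r in atoms.resids]
    try:
        segids = [str(s) for s in atoms.segids]
    except AttributeError:
        segids = [""] * len(names)
    coords = atoms.positions.astype(float).copy()
    return names, resnames, resids, segids, coords


def load_system(topology_path, selection_config) -> SystemModel:
    """Read a PDB topology and resolve all role selections.

    ``selection_config`` is a mapping (or YAML path) naming the probe
    residue and its central-carbon/hydroxyl-oxygen atom names, the lipid
    residue names, phosphate atom name and tail type labels, and optional
    protein restriction and type-table extensions.

    Leaflets are assigned per lipid by the sign of its mean phosphate z
    relative to the bilayer midplane (mean of all phosphate z) in the
    topology coordinates.
    """
    cfg = load_selection_config(selection_config)
    names, resnames, resids, segids, coords = _read_pdb_atoms(topology_path)
    n = len(names)

    table = default_type_table()
    for res, mapping in (cfg.get("type_table") or {}).items():
        table.setdefault(res, {}).update(mapping)

    probe_res = cfg["probe"]["resname"]
    cc_name = cfg["probe"]["central_carbon"]
    oh_name = cfg["probe"]["hydroxyl_oxygen"]
    lipid_resnames = set(cfg["lipids"]["resnames"])
    phosphate_atom = cfg["lipids"]["phosphate_atom"]
    tail_types = set(cfg["lipids"]["tail_type_labels"])
    solvent = set(cfg["solvent_resnames"])

    if probe_res in lipid_resnames:
        raise ConfigurationError(
            f"probe residue name {probe_res!r} also listed as a lipid residue"
        )

    atoms: list[AtomRecord] = []
    for i in range(n):
        elem = _element_from_name(names[i])
        atoms.append(AtomRecord(
            index=i,
            name=names[i],
            residue_name=resnames[i],
            residue_id=resids[i],
            segment=segids[i],
            type_label=table.get(resnames[i], {}).get(names[i], ""),
            element=elem,
            mass=_ELEMENT_MASSES.get(elem, 12.011),
        ))

    present_resnames = set(resnames)
    if probe_res not in present_resnames:
        raise ConfigurationError(
            f"probe residue name {probe_res!r} not found in topology"
        )

    heavy = np.array([a.element != "H" for a in atoms])

    # --- probes: group by (segment, residue id) within the probe resname
    probes: list[ProbeTopology] = []
    probe_keys: dict[tuple, list[int]] = {}
    for i, a in enumerate(atoms):
        if a.residue_name == probe_res and heavy[i]:
            probe_keys.setdefault((a.segment, a.residue_id), []).append(i)
    for key in sorted(probe_keys):
        idx = probe_keys[key]
        if len(idx) != 4:
            raise TopologyError(
                f"probe residue {key} has {len(idx)} heavy atoms, expected 4"
            )
        cc = [i for i in idx if atoms[i].name == cc_name]
        oh = [i for i in idx if atoms[i].name == oh_name]
        if len(cc) != 1:
            raise ConfigurationError(
                f"probe residue {key}: central carbon atom {cc_name!r} "
                f"matched {len(cc)} atoms"
            )
        if len(oh) != 1:
            raise ConfigurationError(
                f"probe residue {key}: hydroxyl oxygen atom {oh_name!r} "
                f"matched {len(oh)} atoms"
            )
        probes.append(ProbeTopology(tuple(idx), cc[0], oh[0]))
    if not probes:
        raise ConfigurationError(f"no probe residues {probe_res!r} with heavy atoms")

    # --- lipids
    is_lipid = np.array([a.residue_name in lipid_resnames for a in atoms])
    lipid_present = lipid_resnames & present_resnames
    phosphates = np.array(
        [i for i, a in enumerate(atoms) if is_lipid[i] and a.name == phosphate_atom],
        dtype=int,
    )
    if lipid_present and phosphates.size == 0:
        raise ConfigurationError(
            f"phosphate atom name {phosphate_atom!r} not found in lipid "
            f"residues {sorted(lipid_present)}"
        )
    tail_sel = np.array(
        [i for i, a in enumerate(atoms) if is_lipid[i] and a.type_label in tail_types],
        dtype=int,
    )

    # --- leaflets: mean phosphate z per lipid vs bilayer midplane
    leaflet_upper: set[int] = set()
    leaflet_lower: set[int] = set()
    if phosphates.size:
        midplane = float(np.mean(coords[phosphates, 2]))
        by_lipid: dict[int, list[float]] = {}
        for i in phosphates:
            by_lipid.setdefault(atoms[i].residue_id, []).append(coords[i, 2])
        for rid, zs in by_lipid.items():
            (leaflet_upper if float(np.mean(zs)) >= midplane else leaflet_lower).add(rid)

    # --- protein heavy atoms
    probe_atom_set = {i for p in probes for i in p.heavy_atoms}
    prot_cfg = cfg.get("protein") or {}
    prot_segments = set(prot_cfg.get("segments") or [])
    prot_resnames = set(prot_cfg.get("resnames") or [])
    protein_idx = []
    for i, a in enumerate(atoms):
        if not heavy[i] or is_lipid[i] or i in probe_atom_set:
            continue
        if a.residue_name in solvent or a.residue_name == probe_res:
            continue
        if prot_segments and a.segment not in prot_segments:
            continue
        if prot_resnames and a.residue_name not in prot_resnames:
            continue
        protein_idx.append(i)
    protein_heavy = np.array(protein_idx, dtype=int)

    system = SystemModel(
        atoms=atoms,
        protein_heavy=protein_heavy,
        probes=probes,
        lipid_phosphates=phosphates,
        leaflet_upper=frozenset(leaflet_upper),
        leaflet_lower=frozenset(leaflet_lower),
        lipid_tail_ctl2=tail_sel,
        metadata={
            "topology_path": str(topology_path),
            "reference_coordinates": coords,
            "selection_config": cfg,
        },
    )
    system.validate()
    logger.info(
        "loaded %s: %d atoms, %d protein heavy, %d probes, %d phosphates "
        "(%d/%d upper/lower leaflet lipids), %d tail atoms",
        topology_path, n, protein_heavy.size, len(probes), phosphates.size,
        len(leaflet_upper), len(leaflet_lower), tail_sel.size,
    )
    return system


_ORTHO_TOL = 1e-3


def load_trajectory(system: SystemModel, trajectory_paths: Sequence, frame_range=None) -> Trajectory:
    """Read DCD/XTC file(s), concatenate in path order, slice by frame index.

    ``frame_range`` is ``(start, stop, stride)`` (any entry may be None),
    applied to the concatenated frame list.  Only orthorhombic boxes are
    supported; triclinic input raises ``ValueError``.
    """
    import MDAnalysis as mda

    if isinstance(trajectory_paths, (str, Path)):
        trajectory_paths = [trajectory_paths]
    top = system.metadata.get("topology_path")
    if top is None:
        raise ValueError("system carries no topology path; load it via load_system")

    coords, boxes, times = [], [], []
    frame_counter = 0
    time_offset = 0.0
    for path in trajectory_paths:
        file_times = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(top, str(path))
        if u.atoms.n_atoms != system.n_atoms:
            raise ValueError(
                f"{path}: trajectory has {u.atoms.n_atoms} atoms, "
                f"system has {system.n_atoms}"
            )
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or np.any(np.asarray(dims[:3]) <= 0):
                raise ValueError(f"{path}: frame {frame_counter} has no periodic box")
            if np.any(np.abs(np.asarray(dims[3:6]) - 90.0) > _ORTHO_TOL):
                raise ValueError(
                    f"{path}: frame {frame_counter} has a triclinic box; "
                    "only orthorhombic boxes are supported"
                )
            coords.append(ts.positions.astype(float).copy())
            boxes.append(np.asarray(dims[:3], dtype=float).copy())
            file_times.append(float(ts.time))
            frame_counter += 1
        # each file restarts its own clock; shift so concatenated times
        # stay non-decreasing
        if file_times:
            shift = time_offset - file_times[0]
            times.extend(t + shift for t in file_times)
            span = file_times[-1] - file_times[0]
            dt = span / max(1, len(file_times) - 1) if len(file_times) > 1 else 1.0
            time_offset += span + dt

    traj = Trajectory(np.array(coords), np.array(boxes), np.array(times))
    if frame_range is not None:
        start, stop, stride = (tuple(frame_range) + (None, None, None))[:3]
        traj = traj.slice(start, stop, stride)
    if traj.n_frames == 0:
        raise ValueError("frame selection produced an empty trajectory")
    traj.check_against(system)
    logger.info("loaded %d frames from %d file(s)", traj.n_frames, len(trajectory_paths))
    return traj


def write_scalar_field(field: ScalarField3D, path) -> None:
    """Write a scalar field as OpenDX (viewable in VMD/PyMOL/ChimeraX)."""
    if not np.all(np.isfinite(field.values)):
        raise ValueError("scalar field contains non-finite values")
    g = Grid(field.values, origin=field.origin, delta=field.spacing)
    g.export(str(path), file_format="dx")


def read_scalar_field(path, units: str = "") -> ScalarField3D:
    """Read an OpenDX scalar field written by :func:`write_scalar_field`."""
    g = Grid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    return ScalarField3D(
        origin=np.asarray(g.origin, dtype=float),
        spacing=delta,
        values=np.asarray(g.grid, dtype=float),
        units=units,
    )


def write_atom_scalars(system: SystemModel, values: Mapping[int, float], path,
                       mode: str = "csv", coordinates: np.ndarray | None = None) -> None:
    """Write per-atom scalars as CSV or into PDB B-factors.

    CSV columns: index, name, residue, resid, value (atoms without a value
    omitted).  ``pdb_bfactor`` writes every atom, missing values as 0.00,
    using ``coordinates`` or the system's stored reference coordinates.
    """
    bad = [i for i, v in values.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite scalar values for atoms {sorted(bad)[:10]}")
    unknown = [i for i in values if i < 0 or i >= system.n_atoms]
    if unknown:
        raise ValueError(f"scalar values keyed by unknown atom indices {sorted(unknown)[:10]}")

    if mode == "csv":
        rows = [
            {
                "index": i,
                "name": system.atoms[i].name,
                "residue": system.atoms[i].residue_name,
                "resid": system.atoms[i].residue_id,
                "value": float(values[i]),
            }
            for i in sorted(values)
        ]
        pd.DataFrame(rows, columns=["index", "name", "residue", "resid", "value"]).to_csv(
            path, index=False
        )
    elif mode == "pdb_bfactor":
        if coordinates is None:
            coordinates = system.metadata.get("reference_coordinates")
        if coordinates is None:
            raise ValueError("pdb_bfactor mode needs coordinates")
        coordinates = np.asarray(coordinates, dtype=float)
        if coordinates.shape != (system.n_atoms, 3):
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        _write_bfactor_pdb(system, coordinates, values, path)
    else:
        raise ValueError(f"unknown mode {mode!r}")


def make_universe(system: SystemModel, coords: np.ndarray,
                  box: np.ndarray | None = None):
    """Build an in-memory MDAnalysis Universe mirroring a SystemModel.

    Used for writing PDB/DCD output; one MDAnalysis residue per contiguous
    (segment, resid) run.
    """
    import MDAnalysis as mda

    n = system.n_atoms
    resids = [a.residue_id for a in system.atoms]
    segs = [a.segment or "S" for a in system.atoms]
    res_keys: list[tuple] = []
    res_index = np.empty(n, dtype=int)
    for i, key in enumerate(zip(segs, resids)):
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        res_index[i] = len(res_keys) - 1
    seg_keys = sorted({k[0] for k in res_keys})
    seg_index = np.array([seg_keys.index(k[0]) for k in res_keys], dtype=int)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n, n_residues=len(res_keys), n_segments=len(seg_keys),
            atom_resindex=res_index, residue_segindex=seg_index,
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in system.atoms])
        u.add_TopologyAttr("resnames", [
            system.atoms[int(np.argmax(res_index == r))].residue_name
            for r in range(len(res_keys))
        ])
        u.add_TopologyAttr("resids", [k[1] for k in res_keys])
        u.add_TopologyAttr("segids", seg_keys)
        u.add_TopologyAttr("elements", [a.element for a in system.atoms])
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.atoms.positions = np.asarray(coords, dtype=float)
        if box is not None:
            u.dimensions = [float(box[0]), float(box[1]), float(box[2]),
                            90.0, 90.0, 90.0]
    return u


def _write_bfactor_pdb(system: SystemModel, coords: np.ndarray,
                       values: Mapping[int, float], path) -> None:
    u = make_universe(system, coords)
    tf = np.zeros(system.n_atoms)
    for i, v in values.items():
        tf[i] = v
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.tempfactors = tf
        u.atoms.write(str(path))


def read_atom_scalars(path) -> dict[int, float]:
    """Read a CSV written by :func:`write_atom_scalars` back to a dict."""
    df = pd.read_csv(path)
    return {int(i): float(v) for i, v in zip(df["index"], df["value"])}
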
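"""Structure/trajectory input and periodic-boundary-aware geometry.

Everything downstream of this module works in a uniform unit system:
lengths in nanometres, times in nanoseconds.  File formats that use other
conventions (PDB angstroms, XTC picosecond timestamps) are converted at the
I/O boundary.  Only orthorhombic simulation boxes are supported; bilayer
systems in scope are orthorhombic and the minimum-image arithmetic stays
simple and testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "ProteinResidue",
    "LipidMolecule",
    "DEFAULT_LIPID_TYPES",
    "DEFAULT_HEAD_PARTICLES",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "min_distance_series",
    "minimum_image_distance",
]

#: residue-name -> lipid-type classification, user-extensible via config
DEFAULT_LIPID_TYPES: dict[str, str] = {
    "CHOL": "cholesterol",
    "CHL1": "cholesterol",
    "ERG": "cholesterol",
    "POPC": "phospholipid",
    "POPE": "phospholipid",
    "DOPC": "phospholipid",
    "DPPC": "phospholipid",
    "POPS": "phospholipid",
    "POPG": "phospholipid",
}

#: lipid-type -> candidate head-particle names (first match wins);
#: for cholesterol this is the beta3-hydroxyl bead/atom
DEFAULT_HEAD_PARTICLES: dict[str, tuple[str, ...]] = {
    "cholesterol": ("ROH", "OH", "O3", "O1"),
    "phospholipid": ("PO4", "P", "P8", "PO41"),
}

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H", "HIE": "H", "HID": "H",
}


class TopologyError(ValueError):
    """Raised when a structure file cannot be mapped onto the domain model."""


@dataclass(frozen=True)
class ProteinResidue:
    """One protein residue: a label like ``F387`` plus its particle indices."""

    label: str
    resname: str
    resid: int
    chain: str
    indices: np.ndarray  # particle indices, int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProteinResidue({self.label}, {len(self.indices)} particles)"


@dataclass(frozen=True)
class LipidMolecule:
    """One lipid molecule with its type, particles and designated head particle."""

    mol_id: int
    lipid_type: str
    indices: np.ndarray
    head_index: int


@dataclass
class Topology:
    """Particle-level system description shared by every analysis stage.

    Particles are partitioned into protein residues and lipid molecules;
    ``box`` holds orthorhombic edge lengths in nm.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chains: np.ndarray
    protein_residues: list[ProteinResidue]
    lipids: list[LipidMolecule]
    box: np.ndarray
    unmapped_resnames: list[str] = field(default_factory=list)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    @property
    def lipid_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for lip in self.lipids:
            census[lip.lipid_type] = census.get(lip.lipid_type, 0) + 1
        return census

    def lipids_of_type(self, lipid_type: str) -> list[LipidMolecule]:
        return [l for l in self.lipids if l.lipid_type == lipid_type]

    def residue_by_label(self, label: str) -> ProteinResidue:
        for res in self.protein_residues:
            if res.label == label:
                return res
        raise KeyError(label)

    def validate(self) -> None:
        covered = np.zeros(self.n_particles, dtype=bool)
        for res in self.protein_residues:
            covered[res.indices] = True
        for lip in self.lipids:
            if covered[lip.indices].any():
                raise TopologyError("particle assigned to more than one group")
            covered[lip.indices] = True
        if not np.all(self.box > 0):
            raise TopologyError("box lengths must be positive")


@dataclass
class Trajectory:
    """Per-frame coordinates (nm) on a fixed particle set.

    ``coords`` has shape (frames, particles, 3); ``timestep_ns`` is the time
    between consecutive stored frames.
    """

    coords: np.ndarray
    timestep_ns: float
    box: np.ndarray

    @property
    def frame_count(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, particles, 3)")
        if self.timestep_ns <= 0:
            raise ValueError("timestep must be positive")


def _require_orthorhombic(dimensions: np.ndarray) -> np.ndarray:
    """Return nm edge lengths from an MDAnalysis dimensions array (A, degrees)."""
    if dimensions is None or not np.all(dimensions[:3] > 0):
        raise TopologyError("structure has no valid box dimensions")
    if not np.allclose(dimensions[3:], 90.0, atol=1e-3):
        raise TopologyError(
            f"only orthorhombic boxes are supported, got angles {dimensions[3:]}"
        )
    return np.asarray(dimensions[:3], dtype=float) / 10.0


def read_structure(
    path: str | Path,
    lipid_types: dict[str, str] | None = None,
    head_particles: dict[str, tuple[str, ...]] | None = None,
    strict: bool = True,
) -> Topology:
    """Read a PDB or GRO file into a :class:`Topology`.

    Residues whose name appears in ``lipid_types`` become lipid molecules;
    standard amino-acid names become protein residues.  Anything else raises
    :class:`TopologyError` in strict mode, or is kept as a protein-like
    residue and recorded in ``unmapped_resnames`` otherwise.
    """
    import MDAnalysis as mda

    lipid_types = DEFAULT_LIPID_TYPES if lipid_types is None else lipid_types
    head_particles = (
        DEFAULT_HEAD_PARTICLES if head_particles is None else head_particles
    )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    names = np.asarray(u.atoms.names, dtype=object)
    resnames_atom = np.asarray(u.atoms.resnames, dtype=object)
    resids_atom = np.asarray(u.atoms.resids, dtype=int)
    try:
        chains_atom = np.asarray(u.atoms.chainIDs, dtype=object)
    except (AttributeError, mda.exceptions.NoDataError):
        chains_atom = np.asarray(
            [getattr(a, "segid", "") or "A" for a in u.atoms], dtype=object
        )

    protein: list[ProteinResidue] = []
    lipids: list[LipidMolecule] = []
    unmapped: list[str] = []
    mol_id = 0
    for res in u.residues:
        idx = np.asarray(res.atoms.ix, dtype=int)
        rname = str(res.resname).strip()
        if rname in lipid_types:
            ltype = lipid_types[rname]
            head = _find_head(names, idx, head_particles.get(ltype, ()))
            lipids.append(LipidMolecule(mol_id, ltype, idx, head))
            mol_id += 1
        elif rname in _AA3:
            label = f"{_AA3[rname]}{int(res.resid)}"
            protein.append(
                ProteinResidue(label, rname, int(res.resid),
                               str(chains_atom[idx[0]]), idx)
            )
        else:
            if strict:
                raise TopologyError(
                    f"unknown residue name {rname!r}; extend the lipid-type "
                    "mapping or disable strict mode"
                )
            unmapped.append(rname)
            label = f"{rname}{int(res.resid)}"
            protein.append(
                ProteinResidue(label, rname, int(res.resid),
                               str(chains_atom[idx[0]]), idx)
            )

    box = _require_orthorhombic(u.dimensions)
    topo = Topology(
        names=names,
        resnames=resnames_atom,
        resids=resids_atom,
        chains=chains_atom,
        protein_residues=protein,
        lipids=lipids,
        box=box,
        unmapped_resnames=unmapped,
    )
    topo.validate()
    return topo


def _find_head(names: np.ndarray, indices: np.ndarray,
               candidates: tuple[str, ...]) -> int:
    for cand in candidates:
        for i in indices:
            if str(names[i]).strip() == cand:
                return int(i)
    return int(indices[0])


def read_trajectory(
    path: str | Path,
    topology: Topology,
    timestep_ns: float | None = None,
) -> Trajectory:
    """Read an XTC or DCD trajectory against ``topology``.

    The timestep is taken from the file's frame timestamps when present;
    ``timestep_ns`` overrides it (mandatory for formats without reliable
    time metadata).
    """
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".xtc":
        reader = XTCReader(str(path))
    elif suffix == ".dcd":
        reader = DCDReader(str(path))
    else:
        raise ValueError(f"unsupported trajectory format {suffix!r}")

    frames = []
    times_ps = []
    box = None
    with reader:
        for ts in reader:
            if ts.n_atoms != topology.n_particles:
                raise ValueError(
                    f"particle-count mismatch: trajectory has {ts.n_atoms}, "
                    f"topology has {topology.n_particles}"
                )
            frames.append(ts.positions.astype(np.float64) / 10.0)
            times_ps.append(float(ts.time))
            if box is None and ts.dimensions is not None and ts.dimensions[:3].any():
                box = _require_orthorhombic(np.asarray(ts.dimensions, dtype=float))
    if not frames:
        raise ValueError(f"trajectory {path} contains zero frames")

    if timestep_ns is None:
        if len(times_ps) >= 2 and times_ps[1] > times_ps[0]:
            timestep_ns = (times_ps[1] - times_ps[0]) / 1000.0
        else:
            raise ValueError(
                "trajectory carries no usable time metadata; pass timestep_ns"
            )
    coords = np.stack(frames)
    return Trajectory(coords=coords, timestep_ns=float(timestep_ns),
                      box=topology.box if box is None else box)


def write_structure(
    path: str | Path,
    names: np.ndarray,
    resnames: np.ndarray,
    resids: np.ndarray,
    coords_nm: np.ndarray,
    box_nm: np.ndarray,
) -> None:
    """Write a single-frame PDB (nm -> angstrom conversion applied)."""
    import MDAnalysis as mda

    n = len(names)
    resid_arr = np.asarray(resids, dtype=int)
    # contiguous runs of equal resid define residues
    boundaries = np.flatnonzero(np.diff(resid_arr) != 0) + 1
    res_starts = np.concatenate([[0], boundaries])
    atom_resindex = np.zeros(n, dtype=int)
    for ri, start in enumerate(res_starts):
        end = res_starts[ri + 1] if ri + 1 < len(res_starts) else n
        atom_resindex[start:end] = ri
    u = mda.Universe.empty(
        n, n_residues=len(res_starts), atom_resindex=atom_resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", list(names))
    u.add_TopologyAttr("resnames", [str(resnames[s]) for s in res_starts])
    u.add_TopologyAttr("resids", [int(resid_arr[s]) for s in res_starts])
    u.atoms.positions = np.asarray(coords_nm, dtype=np.float32) * 10.0
    u.dimensions = np.array(
        [box_nm[0] * 10, box_nm[1] * 10, box_nm[2] * 10, 90.0, 90.0, 90.0],
        dtype=np.float32,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(
    path: str | Path,
    coords_nm: np.ndarray,
    box_nm: np.ndarray,
    timestep_ns: float,
) -> None:
    """Write an XTC (or DCD) trajectory from an (F, N, 3) nm coordinate array."""
    import MDAnalysis as mda

    coords_nm = np.asarray(coords_nm)
    n_frames, n_atoms = coords_nm.shape[:2]
    dims = np.array(
        [box_nm[0] * 10, box_nm[1] * 10, box_nm[2] * 10, 90.0, 90.0, 90.0],
        dtype=np.float32,
    )
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n_atoms) as w:
            for i in range(n_frames):
                u.atoms.positions = coords_nm[i].astype(np.float32) * 10.0
                u.dimensions = dims
                u.trajectory.ts.frame = i
                u.trajectory.ts.time = i * timestep_ns * 1000.0  # ps
                u.trajectory.ts.data["time"] = i * timestep_ns * 1000.0
                w.write(u.atoms)


def minimum_image_distance(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances in an orthorhombic box.

    ``a`` (..., na, 3) and ``b`` (..., nb, 3) broadcast to (..., na, nb).
    """
    delta = a[..., :, None, :] - b[..., None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta * delta).sum(axis=-1))


def min_distance_series(
    trajectory: Trajectory,
    set_a: np.ndarray,
    set_b: np.ndarray,
    chunk: int = 2000,
) -> np.ndarray:
    """Per-frame minimum distance (nm) between two particle selections.

    The minimum is taken over all cross pairs under the minimum-image
    convention; symmetric in its two selections.
    """
    set_a = np.asarray(set_a, dtype=int)
    set_b = np.asarray(set_b, dtype=int)
    if set_a.size == 0 or set_b.size == 0:
        raise ValueError("both selections must be non-empty")
    box = trajectory.box
    out = np.empty(trajectory.frame_count)
    for start in range(0, trajectory.frame_count, chunk):
        stop = min(start + chunk, trajectory.frame_count)
        d = minimum_image_distance(
            trajectory.coords[start:stop, set_a],
            trajectory.coords[start:stop, set_b],
            box,
        )
        out[start:stop] = d.min(axis=(1, 2))
    return out
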
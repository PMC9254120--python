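"""Ground-truthed synthetic inputs for every analysis stage.

The generator emulates a coarse-grained membrane-protein system — a static
set of protein beads embedded in a two-leaflet bilayer of cholesterol and
phospholipid — with *known* binding-site locations, residence times and
dissociation constants, so that the whole detection/kinetics/titration
pipeline can be validated against exact ground truth.

Binding is modelled as a site-level continuous-time Markov chain, not as
force-field physics: an empty site binds a randomly chosen free cholesterol
with per-frame probability c * x * dt (c the association scale in
1/(us * mole-%), x the instantaneous free cholesterol mole-%), and a bound
cholesterol unbinds with probability k_off * dt.  The stationary occupancy
is therefore exactly x / (x + Kd) with Kd = k_off / c, and bound durations
are memoryless with mean 1/k_off.  Coordinates are rendered afterwards,
consistently with the binding states: bound cholesterol sits on the site
anchor (with small jitter, inside the lower contact cutoff of every site
residue), free lipids perform 2D Brownian motion in their leaflet, and free
cholesterol is kept outside an exclusion radius of all protein beads so
that no contact can occur outside the Markov chain's ledger — the emitted
ground truth is exact frame by frame.

Cholesterol is represented with 3 beads (hydroxyl ROH, ring centre RC,
tail CT) so orientation classification is exercisable; a site can be
designated "flipped", in which case its bound cholesterol is written with
the hydroxyl nearer the bilayer midplane than the ring centre.
Phospholipids are single head beads.  Everything is deterministic under the
spec's mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .md_io import (
    LipidMolecule,
    ProteinResidue,
    Topology,
    Trajectory,
    write_structure,
    write_trajectory,
)
from .pharm import DoseResponseDataset

__all__ = [
    "PlantedSite",
    "SyntheticSpec",
    "SiteTruth",
    "GroundTruth",
    "SyntheticSystem",
    "BellTruth",
    "default_spec",
    "titration_template",
    "simulate_occupancy_titration",
    "generate_membrane_trajectory",
    "generate_titration_dataset",
    "generate_dose_response",
]

_SITE_RESNAMES = ("PHE", "SER", "GLN", "LEU", "ALA", "VAL", "THR", "ILE")


@dataclass
class PlantedSite:
    """Definition and kinetics of one planted binding site."""

    site_id: int
    anchor_xy: tuple[float, float]
    n_residues: int = 6
    leaflet: int = 1  # +1 upper / -1 lower
    ring_radius: float = 0.3  # nm, residue beads around the anchor
    k_on_scale_per_us_pct: float = 0.1894  # c: binding rate per mole-% free chol
    k_off_per_us: float = 1.25
    flipped: bool = False
    capture_radius: float = 1.2  # nm, free-cholesterol exclusion around anchor

    @property
    def kd_pct(self) -> float:
        """Equilibrium dissociation constant in mole-% free cholesterol."""
        if self.k_on_scale_per_us_pct <= 0:
            return np.inf
        return self.k_off_per_us / self.k_on_scale_per_us_pct

    @property
    def tau_ns(self) -> float:
        return 1000.0 / self.k_off_per_us


@dataclass
class SyntheticSpec:
    """Full description of a synthetic bilayer trajectory."""

    box: tuple[float, float, float] = (12.0, 12.0, 4.0)
    n_lipids: int = 100
    cholesterol_pct: float = 25.0
    sites: list[PlantedSite] = field(default_factory=list)
    extra_residues_xy: list[tuple[float, float]] = field(default_factory=list)
    leaflet_offset: float = 1.8  # phosphate planes at midplane +- offset
    residue_z_offset: float = 0.7  # site residue depth from the midplane
    step_sd: float = 0.1  # nm, Brownian step SD per frame
    jitter_sd: float = 0.05  # nm, bound-pose jitter (clipped at 0.1)
    extra_exclusion: float = 0.9  # nm, free-chol exclusion around stray beads
    timestep_ns: float = 1.0
    n_frames: int = 20000
    seed: int = 0

    @property
    def n_chol(self) -> int:
        return int(round(self.n_lipids * self.cholesterol_pct / 100.0))

    @property
    def n_phospholipid(self) -> int:
        return self.n_lipids - self.n_chol

    def validate(self) -> None:
        if self.n_frames < 1 or self.timestep_ns <= 0:
            raise ValueError("need n_frames >= 1 and a positive timestep")
        if not (0.0 <= self.cholesterol_pct <= 100.0):
            raise ValueError("cholesterol percentage out of range")
        area = self.box[0] * self.box[1]
        if (self.n_lipids / 2) * 0.2 > area:
            raise ValueError("overfilled leaflet: too many lipids for the box")
        dt_us = self.timestep_ns / 1000.0
        for s in self.sites:
            if s.k_off_per_us * dt_us >= 1.0:
                raise ValueError(
                    f"site {s.site_id}: k_off * dt >= 1, timestep too coarse"
                )
            if s.k_on_scale_per_us_pct * 100.0 * dt_us >= 1.0:
                raise ValueError(
                    f"site {s.site_id}: binding probability >= 1 at this timestep"
                )
        ids = [s.site_id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError("site ids must be unique")


@dataclass
class SiteTruth:
    site_id: int
    residues: list[str]
    tau_ns: float
    kd_pct: float
    flipped: bool
    leaflet: int


@dataclass
class GroundTruth:
    """Exact binding record underlying a generated trajectory."""

    sites: list[SiteTruth]
    #: (frames, n_sites) lipid mol_id bound at each site, -1 when empty
    occupant: np.ndarray
    timestep_ns: float

    def events(self, site_id: int) -> list[tuple[int, int, int]]:
        """(start_frame, end_frame_exclusive, lipid_id) bound runs."""
        col = [i for i, s in enumerate(self.sites) if s.site_id == site_id]
        if not col:
            raise KeyError(site_id)
        series = self.occupant[:, col[0]]
        out = []
        start = None
        for t in range(series.size):
            if series[t] >= 0 and (t == 0 or series[t] != series[t - 1]
                                   or series[t - 1] < 0):
                if start is not None:
                    out.append((start, t, int(series[start])))
                start = t
            elif series[t] < 0 and start is not None:
                out.append((start, t, int(series[start])))
                start = None
        if start is not None:
            out.append((start, series.size, int(series[start])))
        return out

    def bound_durations_ns(self, site_id: int,
                           drop_censored: bool = True) -> np.ndarray:
        evs = self.events(site_id)
        n = self.occupant.shape[0]
        out = [
            (e - s) * self.timestep_ns
            for s, e, _ in evs
            if not (drop_censored and (e == n or s == 0))
        ]
        return np.asarray(out)

    def occupancy_pct(self, site_id: int) -> float:
        col = [i for i, s in enumerate(self.sites) if s.site_id == site_id][0]
        return float((self.occupant[:, col] >= 0).mean() * 100.0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "timestep_ns": self.timestep_ns,
            "sites": [
                {
                    "site_id": s.site_id,
                    "residues": s.residues,
                    "tau_ns": s.tau_ns,
                    "kd_pct": None if np.isinf(s.kd_pct) else s.kd_pct,
                    "flipped": s.flipped,
                    "leaflet": s.leaflet,
                }
                for s in self.sites
            ],
            "occupant": self.occupant.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


@dataclass
class SyntheticSystem:
    """In-memory generated system plus (optionally) its on-disk files."""

    topology: Topology
    trajectory: Trajectory
    ground_truth: GroundTruth
    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    structure_path: Path | None = None
    trajectory_path: Path | None = None


def default_spec(seed: int = 0, n_frames: int = 20000) -> SyntheticSpec:
    """Desk-scale default: 100 lipids at 25 mole-% cholesterol, two planted
    6-residue sites.

    Site 1 is the high-affinity, flipped-orientation site (tau 0.8 us,
    Kd 6.6 mole-%); site 2 is a canonical-orientation site with Kd
    10.7 mole-%.  Two stray residues are included so detection has
    non-site protein to ignore.
    """
    return SyntheticSpec(
        sites=[
            PlantedSite(site_id=1, anchor_xy=(3.0, 6.0), flipped=True,
                        k_off_per_us=1.25,
                        k_on_scale_per_us_pct=1.25 / 6.6),
            PlantedSite(site_id=2, anchor_xy=(9.0, 6.0), flipped=False,
                        k_off_per_us=1.25,
                        k_on_scale_per_us_pct=1.25 / 10.7),
        ],
        extra_residues_xy=[(6.0, 2.0), (6.0, 10.0)],
        n_frames=n_frames,
        seed=seed,
    )


def titration_template(kd_pct: float = 6.6, k_off_per_us: float = 12.5,
                       seed: int = 0, n_frames: int = 8000,
                       n_lipids: int = 1000) -> SyntheticSpec:
    """Single-site spec for occupancy titrations.

    The template trades kinetic realism for equilibrium precision, which is
    what a titration measures: the equilibrium occupancy depends only on
    Kd = k_off/c, so fast exchange (tau = 80 ns by default) packs many
    independent binding cycles into a desk-scale trajectory and the
    occupancy estimate at half-saturation lands within a few percent — the
    precision the paper obtains from multi-microsecond sampling of slower
    kinetics.  The large lipid reservoir keeps free-cholesterol depletion
    by the single bound copy negligible, so the time-averaged free
    cholesterol fraction is an unbiased abscissa for the saturation fit.
    """
    return SyntheticSpec(
        box=(14.0, 14.0, 4.0),
        n_lipids=n_lipids,
        sites=[PlantedSite(site_id=1, anchor_xy=(7.0, 7.0),
                           k_off_per_us=k_off_per_us,
                           k_on_scale_per_us_pct=k_off_per_us / kd_pct)],
        n_frames=n_frames,
        seed=seed,
    )


def _protein_layout(spec: SyntheticSpec):
    """Static protein bead coordinates, names and site membership."""
    coords, resnames, labels = [], [], []
    site_residue_labels: dict[int, list[str]] = {}
    resid = 0
    zmid = spec.box[2] / 2.0
    for site in spec.sites:
        members = []
        for j in range(site.n_residues):
            resid += 1
            ang = 2 * np.pi * j / site.n_residues
            coords.append([
                site.anchor_xy[0] + site.ring_radius * np.cos(ang),
                site.anchor_xy[1] + site.ring_radius * np.sin(ang),
                zmid + site.leaflet * spec.residue_z_offset,
            ])
            rn = _SITE_RESNAMES[j % len(_SITE_RESNAMES)]
            resnames.append(rn)
            members.append(resid)
        site_residue_labels[site.site_id] = members
    for xy in spec.extra_residues_xy:
        resid += 1
        coords.append([xy[0], xy[1], zmid + spec.residue_z_offset])
        resnames.append("GLY")
    return (np.asarray(coords), resnames, site_residue_labels)


def _simulate_ctmc(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Site-occupancy Markov chain; returns (frames, n_sites) lipid ids."""
    n_sites = len(spec.sites)
    n_chol = spec.n_chol
    occupant = np.full((spec.n_frames, n_sites), -1, dtype=np.int64)
    if n_sites == 0 or n_chol == 0:
        return occupant
    dt_us = spec.timestep_ns / 1000.0
    free = list(range(n_chol))  # cholesterol molecule indices (0-based)
    state = [-1] * n_sites

    # stationary initial condition so occupancy needs no burn-in
    for si, site in enumerate(spec.sites):
        x = 100.0 * len(free) / spec.n_lipids
        p_occ = x / (x + site.kd_pct) if np.isfinite(site.kd_pct) else 0.0
        if free and rng.random() < p_occ:
            pick = int(rng.integers(len(free)))
            state[si] = free.pop(pick)
    occupant[0] = state

    u = rng.random((spec.n_frames, n_sites))
    for t in range(1, spec.n_frames):
        x = 100.0 * len(free) / spec.n_lipids
        for si, site in enumerate(spec.sites):
            if state[si] >= 0:
                if u[t, si] < site.k_off_per_us * dt_us:
                    free.append(state[si])
                    state[si] = -1
            else:
                p_on = site.k_on_scale_per_us_pct * x * dt_us
                if free and u[t, si] < p_on:
                    pick = int(rng.integers(len(free)))
                    state[si] = free.pop(pick)
        occupant[t] = state
    return occupant


def _brownian_xy(rng: np.random.Generator, n: int, frames: int,
                 box_xy: np.ndarray, step_sd: float) -> np.ndarray:
    start = rng.random((1, n, 2)) * box_xy
    steps = rng.normal(0.0, step_sd, size=(frames - 1, n, 2)).astype(np.float64)
    path = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    return np.mod(path, box_xy)


def _exclude_discs(xy: np.ndarray, centers: np.ndarray, radii: np.ndarray,
                   box_xy: np.ndarray, chunk: int = 4000) -> None:
    """Push points radially out of exclusion discs (minimum-image, in place).

    Disc centres are assumed mutually separated by more than the sum of
    their radii, so a single pass per disc cannot create new violations.
    """
    for start in range(0, xy.shape[0], chunk):
        stop = min(start + chunk, xy.shape[0])
        block = xy[start:stop]
        for c, r in zip(centers, radii):
            delta = block - c
            delta -= box_xy * np.round(delta / box_xy)
            dist = np.sqrt((delta**2).sum(axis=-1))
            inside = dist < r
            if not inside.any():
                continue
            d = np.where(dist[inside] > 1e-9, dist[inside], 1.0)[:, None]
            unit = np.where(
                dist[inside][:, None] > 1e-9, delta[inside] / d,
                np.array([1.0, 0.0]),
            )
            block[inside] = np.mod(c + unit * r, box_xy)


def generate_membrane_trajectory(
    spec: SyntheticSpec,
    out_dir: str | Path | None = None,
    basename: str = "synthetic",
) -> SyntheticSystem:
    """Generate a bilayer trajectory with planted sites and exact ground truth.

    Returns the in-memory system; when ``out_dir`` is given, also writes
    ``<basename>.pdb``, ``<basename>.xtc`` and ``<basename>.truth.json``.
    Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    box_xy = box[:2]
    zmid = box[2] / 2.0
    F = spec.n_frames
    n_chol, n_popc = spec.n_chol, spec.n_phospholipid

    prot_xyz, prot_resnames, site_members = _protein_layout(spec)
    n_prot = prot_xyz.shape[0]

    occupant = _simulate_ctmc(spec, rng)

    chol_xy = _brownian_xy(rng, n_chol, F, box_xy, spec.step_sd) if n_chol else (
        np.zeros((F, 0, 2)))
    popc_xy = _brownian_xy(rng, n_popc, F, box_xy, spec.step_sd) if n_popc else (
        np.zeros((F, 0, 2)))

    # free cholesterol never approaches protein beads: exclusion discs
    if n_chol and n_prot:
        centers = [np.asarray(s.anchor_xy) for s in spec.sites]
        radii = [s.capture_radius for s in spec.sites]
        centers += [np.asarray(xy) for xy in spec.extra_residues_xy]
        radii += [spec.extra_exclusion] * len(spec.extra_residues_xy)
        _exclude_discs(chol_xy, np.asarray(centers), np.asarray(radii), box_xy)

    # leaflet assignment: alternate to keep the bilayer symmetric
    chol_leaflet = np.where(np.arange(n_chol) % 2 == 0, 1, -1)
    popc_leaflet = np.where(np.arange(n_popc) % 2 == 0, 1, -1)

    n_particles = n_prot + 3 * n_chol + n_popc
    coords = np.empty((F, n_particles, 3), dtype=np.float32)
    coords[:, :n_prot] = prot_xyz[None, :, :]

    # unbound cholesterol: canonical orientation in its own leaflet
    # (stack offsets from the midplane: hydroxyl 1.6, ring 1.1, tail 0.6)
    oh = n_prot + 3 * np.arange(n_chol)
    for bead, off in ((0, 1.6), (1, 1.1), (2, 0.6)):
        idx = oh + bead
        coords[:, idx, 0] = chol_xy[..., 0]
        coords[:, idx, 1] = chol_xy[..., 1]
        coords[:, idx, 2] = zmid + chol_leaflet * off

    popc0 = n_prot + 3 * n_chol
    coords[:, popc0:, 0] = popc_xy[..., 0]
    coords[:, popc0:, 1] = popc_xy[..., 1]
    coords[:, popc0:, 2] = zmid + popc_leaflet * spec.leaflet_offset

    # overwrite bound cholesterol: anchored at the site with jitter, and a
    # bead stack matching the site's designated orientation
    for si, site in enumerate(spec.sites):
        bound_frames = np.flatnonzero(occupant[:, si] >= 0)
        if bound_frames.size == 0:
            continue
        jitter = np.clip(
            rng.normal(0.0, spec.jitter_sd, size=(bound_frames.size, 2)),
            -0.1, 0.1,
        )
        lids = occupant[bound_frames, si]
        cols = n_prot + 3 * lids
        xy = np.asarray(site.anchor_xy) + jitter
        if site.flipped:
            stack = (0.25, 0.7, 1.15)  # hydroxyl buried at the midplane
        else:
            stack = (1.15, 0.7, 0.25)
        for bead, off in enumerate(stack):
            coords[bound_frames, cols + bead, 0] = xy[:, 0]
            coords[bound_frames, cols + bead, 1] = xy[:, 1]
            coords[bound_frames, cols + bead, 2] = zmid + site.leaflet * off

    names, resnames, resids, topology = _build_topology(
        spec, prot_resnames, n_chol, n_popc, box
    )
    trajectory = Trajectory(coords=coords, timestep_ns=spec.timestep_ns, box=box)

    truth_sites = []
    label_by_resid = {r.resid: r.label for r in topology.protein_residues}
    for site in spec.sites:
        truth_sites.append(SiteTruth(
            site_id=site.site_id,
            residues=[label_by_resid[r] for r in site_members[site.site_id]],
            tau_ns=site.tau_ns,
            kd_pct=site.kd_pct,
            flipped=site.flipped,
            leaflet=site.leaflet,
        ))
    truth = GroundTruth(sites=truth_sites, occupant=occupant,
                        timestep_ns=spec.timestep_ns)

    system = SyntheticSystem(
        topology=topology, trajectory=trajectory, ground_truth=truth,
        names=names, resnames=resnames, resids=resids,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        system.structure_path = out_dir / f"{basename}.pdb"
        system.trajectory_path = out_dir / f"{basename}.xtc"
        write_structure(system.structure_path, names, resnames, resids,
                        coords[0], box)
        write_trajectory(system.trajectory_path, coords, box, spec.timestep_ns)
        truth.to_json(out_dir / f"{basename}.truth.json")
    return system


def _build_topology(spec: SyntheticSpec, prot_resnames: list[str],
                    n_chol: int, n_popc: int, box: np.ndarray):
    names, resnames, resids = [], [], []
    protein_residues: list[ProteinResidue] = []
    lipids: list[LipidMolecule] = []
    from .md_io import _AA3  # one-letter labels consistent with read_structure

    idx = 0
    resid = 0
    for rn in prot_resnames:
        resid += 1
        names.append("BB")
        resnames.append(rn)
        resids.append(resid)
        protein_residues.append(ProteinResidue(
            label=f"{_AA3[rn]}{resid}", resname=rn, resid=resid, chain="A",
            indices=np.array([idx]),
        ))
        idx += 1
    mol_id = 0
    for _ in range(n_chol):
        resid += 1
        beads = []
        for nm in ("ROH", "RC", "CT"):
            names.append(nm)
            resnames.append("CHOL")
            resids.append(resid)
            beads.append(idx)
            idx += 1
        lipids.append(LipidMolecule(mol_id, "cholesterol",
                                    np.array(beads), beads[0]))
        mol_id += 1
    for _ in range(n_popc):
        resid += 1
        names.append("PO4")
        resnames.append("POPC")
        resids.append(resid)
        lipids.append(LipidMolecule(mol_id, "phospholipid",
                                    np.array([idx]), idx))
        mol_id += 1
        idx += 1

    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resids = np.asarray(resids, dtype=int)
    topology = Topology(
        names=names, resnames=resnames, resids=resids,
        chains=np.asarray(["A"] * len(names), dtype=object),
        protein_residues=protein_residues, lipids=lipids, box=box.copy(),
    )
    topology.validate()
    return names, resnames, resids, topology


def generate_titration_dataset(
    template: SyntheticSpec,
    compositions_pct: list[float],
    replicates: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[dict], pd.DataFrame]:
    """One trajectory per (composition, replicate) from a common template.

    Each record holds the composition, replicate id and generated
    :class:`SyntheticSystem`; the manifest table lists them with file paths
    when ``out_dir`` is given.  Child seeds are spawned deterministically
    from ``seed``.
    """
    if len(compositions_pct) < 3:
        raise ValueError("need >= 3 compositions for a titration")
    for comp in compositions_pct:
        if not (0.0 < comp <= 100.0):
            raise ValueError(f"invalid composition {comp}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(compositions_pct) * replicates)
    records: list[dict] = []
    rows = []
    i = 0
    for comp in compositions_pct:
        for rep in range(replicates):
            spec = SyntheticSpec(
                box=template.box,
                n_lipids=template.n_lipids,
                cholesterol_pct=comp,
                sites=template.sites,
                extra_residues_xy=template.extra_residues_xy,
                leaflet_offset=template.leaflet_offset,
                residue_z_offset=template.residue_z_offset,
                step_sd=template.step_sd,
                jitter_sd=template.jitter_sd,
                extra_exclusion=template.extra_exclusion,
                timestep_ns=template.timestep_ns,
                n_frames=template.n_frames,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
            )
            basename = f"titr_c{comp:g}_r{rep}"
            system = generate_membrane_trajectory(
                spec, out_dir=out_dir, basename=basename
            )
            records.append({
                "composition_pct": comp, "replicate": rep, "system": system,
            })
            rows.append({
                "composition_label": f"{comp:g}%",
                "composition_pct": comp,
                "replicate": rep,
                "structure": (str(system.structure_path)
                              if system.structure_path else ""),
                "trajectory": (str(system.trajectory_path)
                               if system.trajectory_path else ""),
            })
            i += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return records, manifest


def simulate_occupancy_titration(
    template: SyntheticSpec,
    compositions_pct: list[float],
    replicates: int,
    seed: int,
) -> list[dict]:
    """Per-replicate (free cholesterol %, site occupancy %) without rendering.

    Runs only the binding Markov chain of :func:`generate_membrane_trajectory`
    for each (composition, replicate) and reads occupancy and time-averaged
    free cholesterol straight off its state ledger.  Because free
    cholesterol never enters the contact cutoffs except through that ledger,
    contact detection on the rendered trajectory recovers exactly these
    numbers (asserted by the test suite); this path simply skips the
    coordinate rendering, which makes large repeated-statistics studies
    cheap.  Seeding matches :func:`generate_titration_dataset`, so the two
    routes produce identical occupancies for identical inputs.
    """
    if len(compositions_pct) < 3:
        raise ValueError("need >= 3 compositions for a titration")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(compositions_pct) * replicates)
    out = []
    i = 0
    for comp in compositions_pct:
        for rep in range(replicates):
            spec = SyntheticSpec(
                box=template.box, n_lipids=template.n_lipids,
                cholesterol_pct=comp, sites=template.sites,
                extra_residues_xy=template.extra_residues_xy,
                leaflet_offset=template.leaflet_offset,
                residue_z_offset=template.residue_z_offset,
                step_sd=template.step_sd, jitter_sd=template.jitter_sd,
                extra_exclusion=template.extra_exclusion,
                timestep_ns=template.timestep_ns,
                n_frames=template.n_frames,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
            )
            spec.validate()
            rng = np.random.default_rng(spec.seed)
            occupant = _simulate_ctmc(spec, rng)
            n_bound = (occupant >= 0).sum(axis=1).astype(float)
            x = 100.0 * (spec.n_chol - n_bound) / spec.n_lipids
            out.append({
                "composition_pct": comp,
                "replicate": rep,
                "x_free_pct": float(x.mean()),
                "occupancy_pct": {
                    s.site_id: float((occupant[:, si] >= 0).mean() * 100.0)
                    for si, s in enumerate(spec.sites)
                },
            })
            i += 1
    return out


@dataclass(frozen=True)
class BellTruth:
    """Ground-truth hormetic dose-response parameters.

    Defaults follow the glucagon/cAMP phenomenology the module emulates:
    the inhibitory arm requires 10-fold more agonist than the stimulatory
    arm, with a sub-maximal inhibitory span so the curve rises then falls.
    """

    basal: float = 5.0
    span_s: float = 100.0
    ec50_s_m: float = 1e-10
    span_i: float = 75.0
    ec50_i_m: float = 1e-9

    def total(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return (self.basal + self.span_s / (1 + self.ec50_s_m / c)
                - self.span_i / (1 + self.ec50_i_m / c))

    def stimulatory(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.basal + self.span_s / (1 + self.ec50_s_m / c)

    def inhibitory(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.span_i / (1 + self.ec50_i_m / c)


def generate_dose_response(
    truth: BellTruth | None = None,
    noise_sd: float = 2.0,
    n_replicates: int = 3,
    seed: int = 0,
    concentrations_m: np.ndarray | None = None,
) -> tuple[DoseResponseDataset, DoseResponseDataset, BellTruth]:
    """Paired (total, PTX) hormetic dose-response datasets.

    The total response is the bell truth plus Gaussian noise; the PTX
    dataset contains only the stimulatory component (pertussis toxin blocks
    the inhibitory arm), with independent noise.  ``noise_sd`` is in
    response units (default 2, i.e. 2% of the default stimulatory span).
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    truth = BellTruth() if truth is None else truth
    if concentrations_m is None:
        concentrations_m = np.logspace(-12.5, -6.5, 10)
    rng = np.random.default_rng(seed)
    conc = np.tile(concentrations_m, n_replicates)
    rep = np.repeat(np.arange(n_replicates), concentrations_m.size)
    total = truth.total(conc) + rng.normal(0.0, noise_sd, conc.size)
    ptx = truth.stimulatory(conc) + rng.normal(0.0, noise_sd, conc.size)
    return (
        DoseResponseDataset(conc, total, condition="total", replicate=rep),
        DoseResponseDataset(conc, ptx, condition="ptx", replicate=rep.copy()),
        truth,
    )
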
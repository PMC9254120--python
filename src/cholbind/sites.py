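"""Binding-site detection, scoring, pose extraction and orientation.

Residues that are repeatedly touched by the *same* lipid molecule at the
same time belong to one binding site.  This co-binding structure is encoded
as a weighted graph — nodes are residues, an edge weight is the fraction of
frames in which at least one lipid bridges the two residues simultaneously
— and sites are the modularity communities of that graph.  Each site is
then scored with its occupancy (fraction of frames holding >= 1 lipid) and
a site-level residence time, representative bound poses are extracted by
clustering site-local lipid coordinates, and cholesterol orientation
(canonical vs flipped, i.e. hydroxyl pointing to the membrane/water
interface vs buried at the bilayer midplane) is classified per pose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import ContactRecord, events_from_bound
from .kinetics import KineticFit, fit_residence_time, survival_function
from .md_io import LipidMolecule, Topology, Trajectory

__all__ = [
    "BindingSite",
    "BoundPose",
    "build_cocontact_graph",
    "detect_sites",
    "score_site",
    "rank_sites",
    "site_bound_by_lipid",
    "representative_pose",
    "classify_orientation",
    "estimate_midplane",
    "sites_to_frame",
]


@dataclass
class BindingSite:
    """A residue community with occupancy and residence-time scores."""

    site_id: int
    residues: list[str]
    occupancy_pct: float
    kinetic_fit: KineticFit | None
    per_residue_tau_ns: dict[str, float]
    n_events: int
    empty: bool = False

    @property
    def tau_ns(self) -> float | None:
        return None if self.kinetic_fit is None else self.kinetic_fit.tau_ns


@dataclass
class BoundPose:
    """A lipid pose in the site-local frame after superposition."""

    frame: int
    lipid_id: int
    coords: np.ndarray  # (n_lipid_particles, 3), nm, site-local
    cluster_id: int
    cluster_size: int
    rank: int = -1


def build_cocontact_graph(
    contacts: list[ContactRecord],
) -> nx.Graph:
    """Residue co-contact graph from per-(lipid, residue) bound series.

    Edge weight = fraction of frames in which at least one lipid molecule is
    simultaneously bound to both residues; every residue with a contact is a
    node even if it gains no edges.
    """
    if not contacts:
        raise ValueError("no contacts supplied")
    # group bound series by lipid
    by_lipid: dict[int, dict[str, np.ndarray]] = {}
    n_frames = contacts[0].bound.size
    for rec in contacts:
        by_lipid.setdefault(rec.lipid_id, {})[rec.residue] = rec.bound

    graph = nx.Graph()
    for rec in contacts:
        graph.add_node(rec.residue)

    pair_or: dict[tuple[str, str], np.ndarray] = {}
    for residues in by_lipid.values():
        labels = sorted(residues)
        for i, r1 in enumerate(labels):
            b1 = residues[r1]
            for r2 in labels[i + 1:]:
                both = b1 & residues[r2]
                if not both.any():
                    continue
                key = (r1, r2)
                if key in pair_or:
                    pair_or[key] |= both
                else:
                    pair_or[key] = both.copy()
    for (r1, r2), series in pair_or.items():
        w = float(np.clip(series.mean(), 0.0, 1.0))
        if w > 0:
            graph.add_edge(r1, r2, weight=w)
    graph.graph["n_frames"] = n_frames
    return graph


def detect_sites(
    graph: nx.Graph,
    min_residues: int = 4,
    weight_floor: float = 0.05,
    seed: int = 0,
    resolution: float = 1.0,
) -> list[list[str]]:
    """Residue communities of the co-contact graph.

    Edges below ``weight_floor`` are pruned, Louvain modularity communities
    are found under a fixed seed, and communities smaller than
    ``min_residues`` are discarded (suppressing spurious one- or two-residue
    "sites" from incidental contacts).  Deterministic given seed.
    """
    pruned = nx.Graph()
    pruned.add_nodes_from(graph.nodes)
    for r1, r2, data in graph.edges(data=True):
        if data["weight"] >= weight_floor:
            pruned.add_edge(r1, r2, weight=data["weight"])
    if pruned.number_of_edges() == 0:
        return []
    communities = nx.community.louvain_communities(
        pruned, weight="weight", resolution=resolution, seed=seed
    )
    kept = [sorted(c) for c in communities if len(c) >= min_residues]
    kept.sort()  # stable order prior to kinetic ranking
    return kept


def site_bound_by_lipid(
    residues: list[str],
    contacts: list[ContactRecord],
) -> dict[int, np.ndarray]:
    """Per-lipid bound-to-site series: OR over the site's residues."""
    residue_set = set(residues)
    out: dict[int, np.ndarray] = {}
    for rec in contacts:
        if rec.residue not in residue_set:
            continue
        if rec.lipid_id in out:
            out[rec.lipid_id] |= rec.bound
        else:
            out[rec.lipid_id] = rec.bound.copy()
    return out


def score_site(
    residues: list[str],
    contacts: list[ContactRecord],
    timestep_ns: float,
    stride: int = 1,
    n_bootstrap: int = 200,
    seed: int = 0,
    min_events: int = 20,
) -> BindingSite:
    """Occupancy, site-level residence time and per-residue residence times.

    Site-level events are maximal runs of the per-lipid OR over site
    residues; occupancy is the percentage of frames in which any lipid is
    bound to any site residue.
    """
    per_lipid = site_bound_by_lipid(residues, contacts)
    if not per_lipid:
        return BindingSite(-1, sorted(residues), 0.0, None, {}, 0, empty=True)

    any_bound = np.zeros(next(iter(per_lipid.values())).size, dtype=bool)
    durations, censored = [], []
    for bound in per_lipid.values():
        any_bound |= bound
        for ev in events_from_bound(bound, timestep_ns, stride):
            durations.append(ev.duration_ns)
            censored.append(ev.censored)
    occupancy = float(any_bound.mean() * 100.0)

    fit = None
    if durations:
        curve = survival_function(np.asarray(durations),
                                  np.asarray(censored, dtype=bool))
        fit = fit_residence_time(curve, n_bootstrap=n_bootstrap, seed=seed,
                                 min_events=min_events)

    per_res_tau: dict[str, float] = {}
    for label in sorted(residues):
        res_dur = [ev.duration_ns for rec in contacts if rec.residue == label
                   for ev in rec.events]
        res_cens = [ev.censored for rec in contacts if rec.residue == label
                    for ev in rec.events]
        if res_dur:
            res_curve = survival_function(np.asarray(res_dur),
                                          np.asarray(res_cens, dtype=bool))
            res_fit = fit_residence_time(res_curve, n_bootstrap=0, seed=seed,
                                         min_events=min_events)
            per_res_tau[label] = res_fit.tau_ns

    return BindingSite(
        site_id=-1,
        residues=sorted(residues),
        occupancy_pct=occupancy,
        kinetic_fit=fit,
        per_residue_tau_ns=per_res_tau,
        n_events=len(durations),
    )


def rank_sites(sites: list[BindingSite]) -> list[BindingSite]:
    """Assign site ids by descending residence time, occupancy as tie-break."""
    def key(s: BindingSite):
        tau = s.tau_ns if s.tau_ns is not None else -np.inf
        return (-tau, -s.occupancy_pct, s.residues)

    ordered = sorted(sites, key=key)
    for i, s in enumerate(ordered, start=1):
        s.site_id = i
    return ordered


def _kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``mobile`` onto ``reference``."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return rot, mc, rc


def _unwrap(coords: np.ndarray, anchor: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Shift coordinates to the periodic image closest to ``anchor``."""
    delta = coords - anchor
    delta -= box * np.round(delta / box)
    return anchor + delta


def representative_pose(
    site: BindingSite,
    contacts: list[ContactRecord],
    trajectory: Trajectory,
    topology: Topology,
    rmsd_cutoff: float = 0.2,
    max_poses: int = 400,
) -> list[BoundPose]:
    """Cluster bound lipid poses at a site and return ranked representatives.

    Poses (lipid coordinates on site-occupied frames) are expressed in the
    site-local frame by superposing the site residue particles of each frame
    onto those of the first occupied frame, then clustered agglomeratively
    (average linkage) at ``rmsd_cutoff`` on lipid-particle RMSD.  Clusters
    are ranked by size, tie-broken by earliest frame; each representative is
    the cluster medoid.  Frames are subsampled evenly to ``max_poses`` to
    bound the quadratic RMSD matrix.
    """
    per_lipid = site_bound_by_lipid(site.residues, contacts)
    pose_keys = sorted(
        (int(f), lid)
        for lid, bound in per_lipid.items()
        for f in np.flatnonzero(bound)
    )
    if not pose_keys:
        raise ValueError("site has no occupied frames")
    if len(pose_keys) > max_poses:
        sel = np.linspace(0, len(pose_keys) - 1, max_poses).round().astype(int)
        pose_keys = [pose_keys[i] for i in np.unique(sel)]

    res_idx = np.concatenate(
        [topology.residue_by_label(lbl).indices for lbl in site.residues]
    )
    lipid_by_id = {l.mol_id: l for l in topology.lipids}
    box = trajectory.box

    ref_frame = pose_keys[0][0]
    ref_anchor = trajectory.coords[ref_frame, res_idx[0]]
    ref_res = _unwrap(trajectory.coords[ref_frame, res_idx], ref_anchor, box)

    local_coords = []
    for frame, lid in pose_keys:
        anchor = trajectory.coords[frame, res_idx[0]]
        res = _unwrap(trajectory.coords[frame, res_idx], anchor, box)
        lip = _unwrap(trajectory.coords[frame, lipid_by_id[lid].indices],
                      res.mean(axis=0), box)
        rot, mc, rc = _kabsch(res, ref_res)
        local_coords.append((lip - mc) @ rot + rc)
    poses = np.stack(local_coords)  # (P, B, 3)

    # pairwise lipid RMSD in the common site-local frame
    diff = poses[:, None] - poses[None, :]
    rmsd = np.sqrt((diff**2).sum(axis=-1).mean(axis=-1))

    if len(pose_keys) == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(rmsd, checks=False), method="average")
        labels = fcluster(z, t=rmsd_cutoff, criterion="distance")

    clusters: dict[int, np.ndarray] = {
        cid: np.flatnonzero(labels == cid) for cid in np.unique(labels)
    }
    # rank clusters: size desc, earliest member frame as tie-break
    order = sorted(
        clusters,
        key=lambda cid: (-clusters[cid].size,
                         min(pose_keys[i][0] for i in clusters[cid])),
    )
    out: list[BoundPose] = []
    for rank, cid in enumerate(order, start=1):
        members = clusters[cid]
        within = rmsd[np.ix_(members, members)].sum(axis=1)
        medoid = members[int(np.argmin(within))]  # ties -> earliest frame
        frame, lid = pose_keys[medoid]
        out.append(
            BoundPose(frame=frame, lipid_id=lid, coords=poses[medoid],
                      cluster_id=int(cid), cluster_size=int(members.size),
                      rank=rank)
        )
    return out


def estimate_midplane(trajectory: Trajectory, topology: Topology) -> np.ndarray:
    """Per-frame bilayer midplane z (nm): mean z over all lipid particles."""
    lip_idx = np.concatenate([l.indices for l in topology.lipids])
    return trajectory.coords[:, lip_idx, 2].mean(axis=1)


def classify_orientation(
    hydroxyl_z: float,
    ring_z: float,
    midplane_z: float,
) -> tuple[str, int]:
    """Cholesterol orientation relative to the bilayer midplane.

    "flipped" when the beta3-hydroxyl sits closer to the midplane than the
    ring centre (hydroxyl buried in the membrane core), "canonical"
    otherwise.  The leaflet (+1 upper / -1 lower) is the sign of the ring
    centre's offset from the midplane.
    """
    flipped = abs(hydroxyl_z - midplane_z) < abs(ring_z - midplane_z)
    leaflet = 1 if ring_z >= midplane_z else -1
    return ("flipped" if flipped else "canonical"), leaflet


def classify_lipid_orientation(
    trajectory: Trajectory,
    topology: Topology,
    lipid: LipidMolecule,
    frames: np.ndarray,
    midplane_z: np.ndarray,
) -> list[tuple[str, int]]:
    """Per-frame orientation labels for one cholesterol molecule.

    The ring centre is the centroid of the lipid's non-head particles.
    """
    body = np.array([i for i in lipid.indices if i != lipid.head_index])
    if body.size == 0:
        raise ValueError("lipid needs at least one ring particle besides the head")
    out = []
    for f in np.asarray(frames, dtype=int):
        oh_z = float(trajectory.coords[f, lipid.head_index, 2])
        ring_z = float(trajectory.coords[f, body, 2].mean())
        out.append(classify_orientation(oh_z, ring_z, float(midplane_z[f])))
    return out


def sites_to_frame(sites: list[BindingSite]) -> pd.DataFrame:
    """Site summary table (CSV-ready)."""
    rows = []
    for s in sites:
        fit = s.kinetic_fit
        rows.append({
            "site_id": s.site_id,
            "residues": ";".join(s.residues),
            "n_residues": len(s.residues),
            "occupancy_pct": s.occupancy_pct,
            "tau_ns": None if fit is None else fit.tau_ns,
            "ci_low_ns": None if fit is None or fit.ci_ns is None else fit.ci_ns[0],
            "ci_high_ns": None if fit is None or fit.ci_ns is None else fit.ci_ns[1],
            "model": None if fit is None else fit.model,
            "n_events": s.n_events,
        })
    return pd.DataFrame(rows, columns=[
        "site_id", "residues", "n_residues", "occupancy_pct", "tau_ns",
        "ci_low_ns", "ci_high_ns", "model", "n_events",
    ])
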
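"""Dual-cutoff (hysteresis) lipid-residue contact detection.

A contact opens when the lipid-residue minimum distance drops strictly below
the lower cutoff and stays open until the distance reaches or exceeds the
upper cutoff.  The two-threshold scheme suppresses rattling of the bound
state when a lipid hovers near a single cutoff, which would otherwise
fragment one long binding event into many short ones and bias residence
times downward.

Boundary convention (fixed so results are bit-reproducible): strict ``<``
at the lower cutoff to open, ``>=`` at the upper cutoff to close.  The
closing frame is not part of the event.  An event still open at the final
frame is closed there and flagged censored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .md_io import Topology, Trajectory, minimum_image_distance

__all__ = [
    "ContactParameters",
    "ContactEvent",
    "ContactRecord",
    "detect_contacts",
    "bound_state_series",
    "events_from_bound",
    "classify_dissociation",
    "contacts_to_frame",
]

# conventional dual-cutoff values for coarse-grained and atomistic systems
CG_CUTOFFS = (0.475, 0.70)
ATOMISTIC_CUTOFFS = (0.35, 0.55)


@dataclass(frozen=True)
class ContactParameters:
    lower_cutoff: float = CG_CUTOFFS[0]
    upper_cutoff: float = CG_CUTOFFS[1]
    stride: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.lower_cutoff <= self.upper_cutoff):
            raise ValueError(
                f"need 0 < lower <= upper, got {self.lower_cutoff}/{self.upper_cutoff}"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class ContactEvent:
    start_frame: int
    duration_frames: int
    duration_ns: float
    censored: bool


@dataclass
class ContactRecord:
    """Bound-state series and contact events for one (lipid, residue) pair."""

    lipid_id: int
    residue: str
    bound: np.ndarray  # bool per analysed frame
    events: list[ContactEvent] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def occupancy(self) -> float:
        """Fraction of frames in the bound state."""
        return float(self.bound.mean())


def bound_state_series(distances: np.ndarray, lower: float,
                       upper: float) -> np.ndarray:
    """Vectorised hysteresis rule applied to one distance series.

    State turns on where d < lower, off where d >= upper, and otherwise
    carries the previous state forward (off before the first trigger).
    """
    d = np.asarray(distances)
    n = d.shape[0]
    code = np.zeros(n, dtype=np.int8)
    code[d < lower] = 1
    code[d >= upper] = -1
    # forward-fill the most recent nonzero trigger
    idx = np.where(code != 0, np.arange(n), -1)
    np.maximum.accumulate(idx, out=idx)
    bound = (idx >= 0) & (code[np.clip(idx, 0, None)] == 1)
    return bound


def events_from_bound(bound: np.ndarray, timestep_ns: float,
                      stride: int = 1) -> list[ContactEvent]:
    """Maximal runs of True as contact events; a run touching the final
    frame is censored."""
    b = np.asarray(bound, dtype=bool)
    if b.size == 0:
        return []
    padded = np.concatenate([[False], b, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    frame_ns = timestep_ns * stride
    return [
        ContactEvent(
            start_frame=int(s),
            duration_frames=int(e - s),
            duration_ns=float((e - s) * frame_ns),
            censored=bool(e == b.size),
        )
        for s, e in zip(starts, ends)
    ]


def detect_contacts(
    trajectory: Trajectory,
    topology: Topology,
    lipid_type: str,
    params: ContactParameters,
    chunk: int = 2000,
) -> list[ContactRecord]:
    """Detect dual-cutoff contacts between every lipid of ``lipid_type`` and
    every protein residue.

    Returns one :class:`ContactRecord` per (lipid, residue) pair with at
    least one event.  Distances are minimum-image minima over all particle
    pairs of the lipid molecule and the residue.
    """
    lipids = topology.lipids_of_type(lipid_type)
    if not lipids:
        raise ValueError(f"no lipids of type {lipid_type!r} in topology")
    residues = topology.protein_residues
    if not residues:
        return []

    frames = np.arange(0, trajectory.frame_count, params.stride)
    coords = trajectory.coords[frames]
    box = trajectory.box

    lip_idx = np.concatenate([l.indices for l in lipids])
    lip_sizes = np.array([len(l.indices) for l in lipids])
    lip_starts = np.concatenate([[0], np.cumsum(lip_sizes)[:-1]])

    records: list[ContactRecord] = []
    n_frames = coords.shape[0]
    for res in residues:
        # (frames, n_lipid_particles) min over residue particles, chunked
        dmin = np.empty((n_frames, len(lip_idx)))
        for start in range(0, n_frames, chunk):
            stop = min(start + chunk, n_frames)
            d = minimum_image_distance(
                coords[start:stop, lip_idx], coords[start:stop, res.indices], box
            )
            dmin[start:stop] = d.min(axis=2)
        # reduce to per-molecule minima
        dmol = np.minimum.reduceat(dmin, lip_starts, axis=1)
        for li, lip in enumerate(lipids):
            bound = bound_state_series(
                dmol[:, li], params.lower_cutoff, params.upper_cutoff
            )
            if not bound.any():
                continue
            events = events_from_bound(bound, trajectory.timestep_ns, params.stride)
            records.append(
                ContactRecord(lipid_id=lip.mol_id, residue=res.label,
                              bound=bound, events=events)
            )
    return records


def classify_dissociation(
    distance_series: np.ndarray,
    threshold: float,
    dwell: int,
    timestep_ns: float,
) -> tuple[float, float | None]:
    """Bound fraction and dissociation time of a single distance trace.

    The lipid is considered dissociated at the first frame from which the
    distance stays at or above ``threshold`` for at least ``dwell``
    consecutive frames; the dwell requirement ignores brief excursions that
    do not commit to the unbound state.

    Returns ``(bound_fraction, dissociation_time_ns or None)``.
    """
    d = np.asarray(distance_series, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    if dwell < 1:
        raise ValueError("dwell must be >= 1")
    below = d < threshold
    bound_fraction = float(below.mean())

    above = ~below
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= dwell:
            return bound_fraction, float(s * timestep_ns)
    return bound_fraction, None


def contacts_to_frame(records: list[ContactRecord]) -> pd.DataFrame:
    """Flatten contact events to a tidy table (CSV-ready)."""
    rows = [
        {
            "lipid_id": r.lipid_id,
            "residue": r.residue,
            "start_frame": ev.start_frame,
            "duration_frames": ev.duration_frames,
            "duration_ns": ev.duration_ns,
            "censored": ev.censored,
        }
        for r in records
        for ev in r.events
    ]
    return pd.DataFrame(
        rows,
        columns=["lipid_id", "residue", "start_frame", "duration_frames",
                 "duration_ns", "censored"],
    )
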
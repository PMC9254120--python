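"""Config-driven orchestration of the full analysis pipeline.

A validated :class:`PipelineConfig` (YAML-friendly, unknown keys rejected)
drives the stages in order: input (files or synthetic generation) ->
contact detection -> site detection and scoring -> pose extraction and
orientation -> optional occupancy titration -> optional dose-response
pharmacology.  Every stochastic step derives its stream from the single
top-level seed, so a rerun with an identical config produces a
byte-identical JSON report.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .contacts import ContactParameters, contacts_to_frame, detect_contacts
from .md_io import read_structure, read_trajectory
from .pharm import (
    DoseResponseDataset,
    agonism_index,
    fit_bell,
    fit_logistic3,
    gi_component,
)
from .sites import (
    build_cocontact_graph,
    classify_lipid_orientation,
    detect_sites,
    estimate_midplane,
    rank_sites,
    representative_pose,
    score_site,
    sites_to_frame,
)
from .synthetic import SyntheticSpec, default_spec, generate_membrane_trajectory
from .titration import (
    aggregate_replicates,
    fit_saturation,
    free_cholesterol_percent,
    points_to_frame,
    site_occupancy_percent,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilesInput(_Model):
    structure: str
    trajectory: str
    timestep_ns: Optional[float] = None


class SyntheticInput(_Model):
    preset: Literal["default"] = "default"
    n_frames: int = 20000
    write_files: bool = False


class ContactsConfig(_Model):
    lower_cutoff: float = 0.475
    upper_cutoff: float = 0.70
    stride: int = 1
    lipid_type: str = "cholesterol"


class KineticsConfig(_Model):
    min_events: int = 20
    n_bootstrap: int = 200


class SitesConfig(_Model):
    min_residues: int = 4
    weight_floor: float = 0.05
    resolution: float = 1.0
    rmsd_cutoff: float = 0.2
    max_poses: int = 400


class TitrationConfig(_Model):
    manifest: str
    timestep_ns: Optional[float] = None


class PharmConfig(_Model):
    csv: str
    total: Optional[str] = None
    ptx: Optional[str] = None
    vehicle: Optional[str] = None
    treatments: list[str] = []


class PipelineConfig(_Model):
    """Validated end-to-end pipeline configuration."""

    seed: int
    output_dir: str
    files: Optional[FilesInput] = None
    synthetic: Optional[SyntheticInput] = None
    contacts: ContactsConfig = ContactsConfig()
    kinetics: KineticsConfig = KineticsConfig()
    sites: SitesConfig = SitesConfig()
    titration: Optional[TitrationConfig] = None
    pharm: Optional[PharmConfig] = None

    @model_validator(mode="after")
    def _one_input_mode(self):
        if (self.files is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input mode required: set either 'files' or "
                "'synthetic'"
            )
        return self


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; raises with field-level messages."""
    raw = yaml.safe_load(Path(path).read_text())
    return PipelineConfig.model_validate(raw)


def _round_floats(obj, ndigits: int = 6):
    """Stable rounding so reports are byte-identical across platforms."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_poses_pdb(path: Path, poses, names: list[str]) -> None:
    """Minimal multi-model PDB of ranked representative poses."""
    with open(path, "w") as fh:
        for pose in poses:
            fh.write(f"MODEL     {pose.rank:>4}\n")
            fh.write(
                f"REMARK   rank {pose.rank} cluster_size {pose.cluster_size} "
                f"frame {pose.frame} lipid {pose.lipid_id}\n"
            )
            for i, (nm, xyz) in enumerate(zip(names, pose.coords), start=1):
                x, y, z = (float(v) * 10.0 for v in xyz)  # nm -> A
                fh.write(
                    f"ATOM  {i:>5} {nm:<4} CHO A{1:>4}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the JSON report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "cholbind_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }

    # ---- input ----
    ground_truth = None
    if config.synthetic is not None:
        spec = default_spec(seed=config.seed, n_frames=config.synthetic.n_frames)
        system = generate_membrane_trajectory(
            spec, out_dir=out_dir if config.synthetic.write_files else None
        )
        topology, trajectory = system.topology, system.trajectory
        ground_truth = system.ground_truth
        report["stages"]["input"] = {
            "mode": "synthetic",
            "n_frames": trajectory.frame_count,
            "n_particles": topology.n_particles,
            "lipid_census": topology.lipid_census,
            "planted_sites": [
                {"site_id": s.site_id, "residues": s.residues,
                 "tau_ns": s.tau_ns, "kd_pct": s.kd_pct, "flipped": s.flipped}
                for s in ground_truth.sites
            ],
        }
    else:
        topology = read_structure(config.files.structure)
        trajectory = read_trajectory(
            config.files.trajectory, topology,
            timestep_ns=config.files.timestep_ns,
        )
        report["stages"]["input"] = {
            "mode": "files",
            "n_frames": trajectory.frame_count,
            "n_particles": topology.n_particles,
            "lipid_census": topology.lipid_census,
        }

    # ---- contacts ----
    params = ContactParameters(
        lower_cutoff=config.contacts.lower_cutoff,
        upper_cutoff=config.contacts.upper_cutoff,
        stride=config.contacts.stride,
    )
    records = detect_contacts(trajectory, topology,
                              config.contacts.lipid_type, params)
    contacts_df = contacts_to_frame(records)
    contacts_df.to_csv(out_dir / "contacts.csv", index=False)
    report["stages"]["contacts"] = {
        "n_records": len(records),
        "n_events": int(len(contacts_df)),
        "lower_cutoff_nm": params.lower_cutoff,
        "upper_cutoff_nm": params.upper_cutoff,
    }

    # ---- sites + kinetics ----
    site_report = []
    sites_ranked = []
    if records:
        graph = build_cocontact_graph(records)
        communities = detect_sites(
            graph, min_residues=config.sites.min_residues,
            weight_floor=config.sites.weight_floor, seed=config.seed,
            resolution=config.sites.resolution,
        )
        scored = [
            score_site(c, records, trajectory.timestep_ns,
                       stride=params.stride,
                       n_bootstrap=config.kinetics.n_bootstrap,
                       seed=config.seed + i,
                       min_events=config.kinetics.min_events)
            for i, c in enumerate(communities)
        ]
        sites_ranked = rank_sites(scored)
        sites_to_frame(sites_ranked).to_csv(out_dir / "sites.csv", index=False)
        per_res_rows = [
            {"site_id": s.site_id, "residue": r, "tau_ns": tau}
            for s in sites_ranked for r, tau in s.per_residue_tau_ns.items()
        ]
        pd.DataFrame(per_res_rows, columns=["site_id", "residue", "tau_ns"]) \
            .to_csv(out_dir / "site_residues.csv", index=False)

        midplane = estimate_midplane(trajectory, topology)
        lipid_by_id = {l.mol_id: l for l in topology.lipids}
        for s in sites_ranked:
            poses = representative_pose(
                s, records, trajectory, topology,
                rmsd_cutoff=config.sites.rmsd_cutoff,
                max_poses=config.sites.max_poses,
            )
            top = poses[0]
            lipid = lipid_by_id[top.lipid_id]
            pose_names = [str(topology.names[i]) for i in lipid.indices]
            _write_poses_pdb(out_dir / f"site{s.site_id}_poses.pdb",
                             poses[:5], pose_names)
            orient, leaflet = classify_lipid_orientation(
                trajectory, topology, lipid, [top.frame], midplane
            )[0]
            entry = {
                "site_id": s.site_id,
                "residues": s.residues,
                "occupancy_pct": s.occupancy_pct,
                "n_events": s.n_events,
                "n_pose_clusters": len(poses),
                "top_pose_frame": top.frame,
                "top_pose_orientation": orient,
                "top_pose_leaflet": leaflet,
            }
            if s.kinetic_fit is not None:
                entry["kinetics"] = s.kinetic_fit.to_dict()
            site_report.append(entry)
    report["stages"]["sites"] = {
        "n_sites": len(sites_ranked),
        "sites": site_report,
    }

    # ---- titration ----
    if config.titration is not None:
        report["stages"]["titration"] = _run_titration(
            config, sites_ranked, params, out_dir
        )

    # ---- pharm ----
    if config.pharm is not None:
        report["stages"]["pharm"] = _run_pharm(config.pharm, out_dir)

    payload = json.dumps(_round_floats(report), sort_keys=True, indent=2)
    (out_dir / "report.json").write_text(payload)
    return report


def _run_titration(config: PipelineConfig, sites_ranked, params, out_dir: Path):
    manifest = pd.read_csv(config.titration.manifest)
    required = {"composition_label", "structure", "trajectory", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"titration manifest lacks columns: {sorted(missing)}")
    if manifest["composition_label"].nunique() < 2:
        raise ValueError("titration manifest needs >= 2 compositions")

    per_site_points: dict[int, dict[str, list[tuple[float, float]]]] = {
        s.site_id: {} for s in sites_ranked
    }
    for _, row in manifest.iterrows():
        topo = read_structure(row["structure"])
        traj = read_trajectory(row["trajectory"], topo,
                               timestep_ns=config.titration.timestep_ns)
        recs = detect_contacts(traj, topo, config.contacts.lipid_type, params)
        x = free_cholesterol_percent(traj, topo, recs, params)
        for s in sites_ranked:
            occ = site_occupancy_percent(s.residues, recs)
            per_site_points[s.site_id].setdefault(
                str(row["composition_label"]), []
            ).append((x, occ))

    out = {}
    for s in sites_ranked:
        points = [aggregate_replicates(reps)
                  for reps in per_site_points[s.site_id].values()]
        points.sort(key=lambda p: p.x_free_pct)
        points_to_frame(points).to_csv(
            out_dir / f"site{s.site_id}_titration.csv", index=False
        )
        if len({p.x_free_pct for p in points}) >= 3:
            fit = fit_saturation(points)
            out[str(s.site_id)] = fit.to_dict()
        else:
            out[str(s.site_id)] = {"flagged": True,
                                   "flag_reason": "too few compositions"}
    return out


def _run_pharm(cfg: PharmConfig, out_dir: Path):
    df = pd.read_csv(cfg.csv)
    required = {"concentration_M", "response", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pharm csv lacks columns: {sorted(missing)}")
    out: dict = {}

    total = ptx = None
    if cfg.total:
        total = DoseResponseDataset.from_frame(df, cfg.total)
        out["total_bell"] = fit_bell(total).to_dict()
    if cfg.ptx:
        ptx = DoseResponseDataset.from_frame(df, cfg.ptx)
        out["ptx_logistic3"] = fit_logistic3(ptx).to_dict()
    if total is not None and ptx is not None:
        comp = gi_component(total, ptx)
        comp.to_csv(out_dir / "gi_component.csv", index=False)
        out["gi_component_auc"] = comp.attrs["auc"]

    if cfg.vehicle:
        vehicle_fit = fit_logistic3(
            DoseResponseDataset.from_frame(df, cfg.vehicle)
        )
        out["vehicle_logistic3"] = vehicle_fit.to_dict()
        indices = {}
        for treatment in cfg.treatments:
            tf = fit_logistic3(DoseResponseDataset.from_frame(df, treatment))
            indices[treatment] = agonism_index(tf, vehicle_fit,
                                               treatment).value
        if indices:
            out["agonism_indices"] = indices
    return out
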
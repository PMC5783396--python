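"""Reproducible multi-stage runs: config validation, stage execution,
tabular/JSON outputs and a run manifest with input/output digests.

A run config (YAML or JSON) selects stages::

    seed: 1
    simulate:            # optional: generate demo inputs first
      trajectory_mode: inactive
      n_frames: 400
    number:
      fasta: path/to/receptors.fasta
    scan:
      metadata: path/to/species_metadata.tsv
    geometry:
      pdb: path/to/complex.pdb
      bw_map: path/to/bw_map.tsv
      contact_cutoff: 3.5
      ionic_cutoff: 4.0
    trajectory:
      pdb: path/to/traj.pdb
      bw_map: path/to/bw_map.tsv
      dt: 1.0
      dwell_min: 5.0
      sd_threshold: 1.0
      tm35_threshold: 10.0

Stages run in order number -> scan -> geometry -> trajectory; every input
referenced by the config is checked for existence *before* any stage runs.
The manifest records the config snapshot, the seed, SHA-256 digests of all
inputs and outputs, and per-stage output paths, so identical config + seed
reproduce identical output digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .numbering import number_sequence, numbering_table, read_fasta
from .scan import hits_table, pocket_profile, read_metadata, scan_many, summarize_by_taxon
from .geometry import LigandPose, carboxylate_distance, ionic_pairs, ligand_contacts, read_structure
from .trajectory import (
    classify_state_stability,
    detect_flips,
    load_trajectory,
    saltbridge_traces,
    switch_dispersion,
    tm3_tm5_series,
)

__all__ = ["ConfigError", "StageError", "RunManifest", "run_pipeline",
           "load_config", "read_bw_map",
           "EXIT_OK", "EXIT_CONFIG", "EXIT_STAGE"]

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_STAGE = 3


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed after validation."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def read_bw_map(path) -> dict:
    """Read a residue-index -> BW-label map from TSV (columns resid, bw_label)."""
    df = pd.read_csv(path, sep="\t", dtype={"resid": int, "bw_label": str})
    if not {"resid", "bw_label"} <= set(df.columns):
        raise ConfigError(f"{path}: bw map needs columns resid, bw_label")
    return dict(zip(df["resid"], df["bw_label"]))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run (reproducibility contract: identical
    config + seed => identical output digests)."""

    version: str
    seed: int
    config: dict
    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stages: dict = field(default_factory=dict)    # stage -> output paths
    incomplete: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "version": self.version, "seed": self.seed, "config": self.config,
            "inputs": self.inputs, "outputs": self.outputs,
            "stages": self.stages, "incomplete": self.incomplete,
        }, indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


_STAGE_INPUT_KEYS = {
    "number": ("fasta",),
    "scan": ("metadata",),
    "geometry": ("pdb", "bw_map"),
    "trajectory": ("pdb", "bw_map"),
}


def _validate(cfg: dict, out_dir: Path) -> None:
    known = {"seed", "simulate", "number", "scan", "geometry", "trajectory",
             "anchor_config"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    if "scan" in cfg and "number" not in cfg:
        raise ConfigError("scan stage requires the number stage (its FASTA)")
    simulate = cfg.get("simulate") or {}
    for stage, keys in _STAGE_INPUT_KEYS.items():
        section = cfg.get(stage)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ConfigError(f"section {stage!r} must be a mapping")
        for key in keys:
            val = section.get(key)
            if val is None:
                if simulate:
                    continue  # produced by the simulate stage
                raise ConfigError(f"{stage}: missing required input {key!r}")
            if not Path(val).exists():
                raise ConfigError(f"{stage}: input path does not exist: {val}")


def _run_simulate(cfg: dict, seed: int, out_dir: Path, manifest: RunManifest) -> None:
    """Generate demo inputs (synthetic panel, toy complex, trajectory) and
    point the downstream stages at them."""
    from . import synthetic

    sim = cfg.get("simulate") or {}
    sim_dir = out_dir / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    seqs, metadata = synthetic.make_ortholog_panel(seed=seed)
    fasta = sim_dir / "panel.fasta"
    synthetic.write_fasta(seqs, fasta)
    meta_path = sim_dir / "species_metadata.tsv"
    metadata.to_csv(meta_path, sep="\t", index=False)
    cfg.setdefault("number", {}).setdefault("fasta", str(fasta))
    cfg.setdefault("scan", {}).setdefault("metadata", str(meta_path))
    outputs["fasta"] = str(fasta)
    outputs["metadata"] = str(meta_path)

    toy = synthetic.make_toy_complex(synthetic.ToyComplexConfig(
        carboxylate_distance=float(sim.get("carboxylate_distance", 10.2))))
    pdb = sim_dir / "complex.pdb"
    toy.write(pdb)
    bw_path = sim_dir / "bw_map.tsv"
    pd.DataFrame(
        sorted(toy.bw_map.items()), columns=["resid", "bw_label"]
    ).to_csv(bw_path, sep="\t", index=False)
    cfg.setdefault("geometry", {}).setdefault("pdb", str(pdb))
    cfg["geometry"].setdefault("bw_map", str(bw_path))
    outputs["complex"] = str(pdb)

    traj_cfg = synthetic.TrajectoryConfig(
        mode=sim.get("trajectory_mode", "inactive"),
        n_frames=int(sim.get("n_frames", 300)),
        seed=seed).resolved()
    straj = synthetic.make_trajectory(traj_cfg)
    traj_path = sim_dir / "trajectory.pdb"
    straj.write(traj_path)
    cfg.setdefault("trajectory", {}).setdefault("pdb", str(traj_path))
    cfg["trajectory"].setdefault("bw_map", str(bw_path))
    outputs["trajectory"] = str(traj_path)
    manifest.stages["simulate"] = outputs


def run_pipeline(config, out_dir) -> RunManifest:
    """Validate the config, run the configured stages in order, write outputs
    and the manifest to ``out_dir``; returns the manifest.

    Raises :class:`ConfigError` before any stage runs for invalid configs and
    :class:`StageError` (with partial outputs flagged in the manifest) when a
    stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = dict(load_config(config) if not isinstance(config, dict) else
               json.loads(json.dumps(config)))
    seed = int(cfg.get("seed", 0))
    _validate(cfg, out_dir)
    manifest = RunManifest(version=__version__, seed=seed, config=cfg)

    if cfg.get("simulate") is not None:
        _run_simulate(cfg, seed, out_dir, manifest)
        _validate(cfg, out_dir)  # simulated inputs must now all exist

    for stage in ("number", "scan", "geometry", "trajectory"):
        if cfg.get(stage) is None:
            continue
        for key in _STAGE_INPUT_KEYS[stage]:
            manifest.inputs[cfg[stage][key]] = _sha256(cfg[stage][key])

    numberings = {}
    seqs = []
    try:
        if "number" in cfg:
            seqs = read_fasta(cfg["number"]["fasta"])
            tables = []
            for seq in seqs:
                try:
                    numberings[seq.id] = number_sequence(seq)
                    tables.append(numbering_table(seq, numberings[seq.id]))
                except Exception:
                    continue
            path = out_dir / "numbering.tsv"
            pd.concat(tables, ignore_index=True).to_csv(path, sep="\t", index=False)
            manifest.stages["number"] = {"numbering": str(path)}

        if "scan" in cfg:
            hits, failed = scan_many(seqs)
            hpath = out_dir / "hits.tsv"
            hits_table(hits, failed).to_csv(hpath, sep="\t", index=False)
            metadata = read_metadata(cfg["scan"]["metadata"])
            tpath = out_dir / "taxa.tsv"
            summarize_by_taxon(hits, metadata).to_csv(tpath, sep="\t", index=False)
            ppath = out_dir / "pockets.tsv"
            rows = []
            for seq in seqs:
                if seq.id in numberings:
                    prof = pocket_profile(seq, numberings[seq.id])
                    row = {"seq_id": prof.seq_id, "n_acidic": prof.n_acidic}
                    row.update({lab: (aa or "") for lab, aa in
                                prof.residues.items()})
                    rows.append(row)
            pd.DataFrame(rows).to_csv(ppath, sep="\t", index=False)
            manifest.stages["scan"] = {"hits": str(hpath), "taxa": str(tpath),
                                       "pockets": str(ppath)}

        if "geometry" in cfg:
            g = cfg["geometry"]
            struct = read_structure(g["pdb"], bw_map=read_bw_map(g["bw_map"]))
            pose = LigandPose.from_structure(struct,
                                             resname=g.get("ligand_resname", "LIG"))
            contact_cutoff = float(g.get("contact_cutoff", 3.5))
            ionic_cutoff = float(g.get("ionic_cutoff", 4.0))
            contacts = ligand_contacts(struct, pose, cutoff=contact_cutoff)
            cpath = out_dir / "contacts.tsv"
            pd.DataFrame([{
                "label": c.label, "resid": c.resid,
                "min_distance": round(c.min_distance, 3),
                "contact_type": c.contact_type,
            } for c in contacts]).to_csv(cpath, sep="\t", index=False)
            ion = ionic_pairs(struct, pose, cutoff=ionic_cutoff)
            report = {
                "carboxylate_distance_3.32_5.43":
                    round(carboxylate_distance(struct, "3.32", "5.43"), 3),
                "ligand_nn_distance": round(pose.nn_distance, 3),
                "contact_cutoff": contact_cutoff,
                "ionic_cutoff": ionic_cutoff,
                "n_contacts": len(contacts),
                "double_salt_bridge": ion.double_salt_bridge,
                "ionic_pairs": [
                    {"n": p.n_name, "label": p.label, "o": p.o_name,
                     "distance": round(p.distance, 3)} for p in ion.pairs],
            }
            gpath = out_dir / "geometry.json"
            gpath.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            manifest.stages["geometry"] = {"contacts": str(cpath),
                                           "report": str(gpath)}

        if "trajectory" in cfg:
            t = cfg["trajectory"]
            traj = load_trajectory(t["pdb"], dt=float(t.get("dt", 1.0)),
                                   bw_map=read_bw_map(t["bw_map"]))
            traces = saltbridge_traces(traj)
            trpath = out_dir / "traces.tsv"
            frame_df = pd.DataFrame({"time_ns": traj.times})
            for key in sorted(traces):
                frame_df[key] = traces[key].values.round(3)
            frame_df.to_csv(trpath, sep="\t", index=False)
            dwell = float(t.get("dwell_min", 5.0))
            events = detect_flips(traces, dwell_min=dwell,
                                  contact_max=t.get("contact_max"))
            epath = out_dir / "flip_events.tsv"
            pd.DataFrame([{
                "start_ns": e.start, "end_ns": e.end,
                "before": e.before, "after": e.after,
            } for e in events]).to_csv(epath, sep="\t", index=False)
            n_snap = int(t.get("n_snapshots", 100))
            stats = switch_dispersion(traj, n_snapshots=min(n_snap, traj.n_frames))
            sd_threshold = float(t.get("sd_threshold", 1.0))
            tm35 = tm3_tm5_series(traj,
                                  threshold=float(t.get("tm35_threshold", 10.0)))
            summary = {
                "dwell_min_ns": dwell,
                "sd_threshold": sd_threshold,
                "n_flip_events": len(events),
                "switch_sd": {lab: round(d.sd, 3)
                              for lab, d in stats.residues.items()},
                "switch_class": classify_state_stability(stats, sd_threshold),
                "tm3_tm5_mean": round(tm35.mean, 3),
                "tm3_tm5_min": round(tm35.min, 3),
                "tm3_tm5_contracted": tm35.contracted,
            }
            spath = out_dir / "trajectory_summary.json"
            spath.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
            manifest.stages["trajectory"] = {"traces": str(trpath),
                                             "events": str(epath),
                                             "summary": str(spath)}
    except Exception as exc:
        done = [p for outs in manifest.stages.values() for p in outs.values()]
        manifest.incomplete = done
        manifest.write(out_dir / "manifest.json")
        raise StageError(f"pipeline stage failed: {exc}") from exc

    for outs in manifest.stages.values():
        for path in outs.values():
            manifest.outputs[path] = _sha256(path)
    manifest.write(out_dir / "manifest.json")
    return manifest
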
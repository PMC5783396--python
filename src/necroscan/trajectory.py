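"""Time-resolved observables on receptor-diamine trajectories.

A :class:`Trajectory` is an ordered stack of coordinate frames over a shared
topology (the tabular :class:`~necroscan.geometry.StructureModel`).  The
observables mirror what one inspects when judging whether a dicationic
ligand sits stably in an acidic pocket:

* amine-nitrogen to carboxylate distance traces (N1/N2 vs the 3.32 and
  5.42/5.43 aspartates),
* flip transitions — the symmetric diamine rotating 180 deg in the pocket so
  the two amines swap acidic partners,
* least-squares-superposed RMSD series,
* positional dispersion of the transmission-switch residues (3.40, 5.50,
  6.44): RMS distance of their C-beta atoms from the centroid over evenly
  spaced snapshots, with fluctuating/stable classification at a 1 Å
  threshold,
* the TM3-TM5 inter-carboxylate contraction series and its sub-10 Å flag.

Baseline trajectory format is multi-model PDB; frame times are assigned from
a configured time step because coordinate files commonly carry none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    ATOM_COLUMNS,
    CARBOXYLATE_OXYGENS,
    LigandPose,
    StructureError,
    StructureModel,
    carboxylate_centroid,
)

__all__ = [
    "Trajectory",
    "TrajectoryError",
    "DistanceTrace",
    "FlipEvent",
    "ResidueDispersion",
    "SwitchStats",
    "TM35Result",
    "load_trajectory",
    "saltbridge_traces",
    "assignment_series",
    "detect_flips",
    "rmsd_series",
    "switch_dispersion",
    "classify_state_stability",
    "tm3_tm5_series",
    "snapshot_indices",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class TrajectoryError(ValueError):
    """Raised for malformed trajectories or unresolvable selections."""


@dataclass
class Trajectory:
    """Ordered frames over a shared topology.

    ``coords`` has shape (n_frames, n_atoms, 3); ``times`` are in ns and must
    be strictly increasing; at least two frames are required.
    """

    topology: StructureModel
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 2:
            raise TrajectoryError("a trajectory needs at least 2 frames")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError("coords/topology atom-count mismatch")
        if len(self.times) != self.coords.shape[0]:
            raise TrajectoryError("times/frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("frame times must strictly increase")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.coords[i])

    def transformed(self, rotation, translation=np.zeros(3)) -> "Trajectory":
        """Apply one rigid transform to every frame (invariance checks)."""
        R = np.asarray(rotation, float)
        return Trajectory(topology=self.topology,
                          coords=self.coords @ R.T + np.asarray(translation, float),
                          times=self.times.copy())

    def select(self, selection) -> np.ndarray:
        """Resolve a selection to atom row indices.

        Accepts an integer index array, or one of the strings ``"all"``,
        ``"backbone"`` (receptor N/CA/C/O), ``"protein"`` (non-LIG residues)
        or ``"ligand"`` / a ligand residue name.
        """
        atoms = self.topology.atoms
        if isinstance(selection, str):
            if selection == "all":
                mask = np.ones(len(atoms), bool)
            elif selection == "backbone":
                mask = atoms["name"].isin(BACKBONE_NAMES) & (atoms["record"] == "ATOM")
            elif selection == "protein":
                mask = (atoms["record"] == "ATOM").to_numpy()
            elif selection == "ligand":
                mask = (atoms["record"] == "HETATM").to_numpy()
            else:
                mask = (atoms["resname"] == selection).to_numpy()
            idx = np.flatnonzero(mask)
        else:
            idx = np.asarray(selection, int)
        if idx.size == 0:
            raise TrajectoryError(f"empty atom selection {selection!r}")
        return idx


def _scan_model_atom_counts(path) -> list:
    counts, current, in_model = [], 0, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                current += 1
    if in_model:
        counts.append(current)
    return counts


def load_trajectory(path, dt: float = 1.0, bw_map=None) -> Trajectory:
    """Load a multi-model PDB as a trajectory.

    Frames follow file order; frame ``i`` gets time ``i * dt`` ns.  Raises
    :class:`TrajectoryError` naming the offending frame when models disagree
    in atom count, and when fewer than two frames are present.
    """
    import MDAnalysis as mda

    counts = _scan_model_atom_counts(path)
    if len(counts) < 2:
        raise TrajectoryError(
            f"{path}: {max(len(counts), 1)} frame(s) found; a trajectory "
            "needs at least 2"
        )
    for i, c in enumerate(counts):
        if c != counts[0]:
            raise TrajectoryError(
                f"{path}: frame {i + 1} has {c} atoms, frame 1 has {counts[0]}"
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    ag = u.atoms

    def _attr(name, default):
        try:
            return list(getattr(ag, name))
        except Exception:
            return [default] * len(ag)

    names = _attr("names", "X")
    resnames = [r.strip() for r in _attr("resnames", "UNK")]
    rows = pd.DataFrame({
        "serial": _attr("ids", 0),
        "name": names,
        "resname": resnames,
        "chain": [c.strip() or "A" for c in _attr("chainIDs", "A")],
        "resid": _attr("resids", 0),
        "x": frames[0, :, 0], "y": frames[0, :, 1], "z": frames[0, :, 2],
        "occupancy": _attr("occupancies", 1.0),
        "altloc": [a.strip() for a in _attr("altLocs", "")],
        "element": [e.strip() or n.strip()[:1] for e, n in
                    zip(_attr("elements", ""), names)],
        "record": [r.strip() or "ATOM" for r in _attr("record_types", "ATOM")],
    }, columns=ATOM_COLUMNS)
    topo = StructureModel(atoms=rows, bw_map=dict(bw_map or {}))
    times = np.arange(len(frames)) * float(dt)
    return Trajectory(topology=topo, coords=frames, times=times)


# ---------------------------------------------------------------------------
# Salt-bridge traces and flip transitions
# ---------------------------------------------------------------------------


@dataclass
class DistanceTrace:
    """A labelled distance time series (times in ns, distances in Å)."""

    label: str
    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def _carboxylate_rows(traj: Trajectory, label: str):
    resid = traj.topology.resolve_label(label)
    res = traj.topology.residue_atoms(resid)
    resname = res["resname"].iloc[0]
    if resname not in CARBOXYLATE_OXYGENS:
        raise TrajectoryError(f"{label} resolves to {resname}, not Asp/Glu")
    carboxylate_centroid(res)  # validates completeness
    onames = CARBOXYLATE_OXYGENS[resname]
    return res.index[res["name"].isin(onames)].to_numpy()


def _atom_row(traj: Trajectory, resname: str, name: str) -> int:
    atoms = traj.topology.atoms
    hit = atoms.index[(atoms["resname"] == resname) & (atoms["name"] == name)]
    if len(hit) != 1:
        raise TrajectoryError(f"expected exactly one atom {resname}:{name}")
    return int(hit[0])


def saltbridge_traces(traj: Trajectory, labels=("3.32", "5.43"),
                      lig_resname: str = "LIG", n1: str = "N1",
                      n2: str = "N2") -> dict:
    """Per-frame distances from each amine nitrogen to each labelled
    carboxylate-oxygen centroid.

    Returns four traces keyed ``"N1-3.32"``, ``"N1-5.43"``, ``"N2-3.32"``,
    ``"N2-5.43"`` (for the default labels).
    """
    oxy_rows = {lab: _carboxylate_rows(traj, lab) for lab in labels}
    n_rows = {n1: _atom_row(traj, lig_resname, n1),
              n2: _atom_row(traj, lig_resname, n2)}
    traces = {}
    for n_name, n_row in n_rows.items():
        n_xyz = traj.coords[:, n_row, :]
        for lab, rows in oxy_rows.items():
            cent = traj.coords[:, rows, :].mean(axis=1)
            d = np.linalg.norm(n_xyz - cent, axis=1)
            traces[f"{n_name}-{lab}"] = DistanceTrace(
                label=f"{n_name}-{lab}", times=traj.times.copy(), values=d)
    return traces


@dataclass(frozen=True)
class FlipEvent:
    """One 180-degree ligand reorientation: the amine/aspartate pairing swaps
    during (start, end) and the new pairing persists."""

    start: float
    end: float
    before: str
    after: str


_PAIRINGS = ("N1-{a}/N2-{b}", "N1-{b}/N2-{a}")


def _trace_keys(traces):
    keys = sorted(traces)
    labs = sorted({k.split("-", 1)[1] for k in keys})
    if len(labs) != 2 or len(keys) != 4:
        raise TrajectoryError("expected 4 traces over 2 carboxylate labels")
    a, b = labs
    return a, b


def assignment_series(traces: dict, contact_max: float = None) -> np.ndarray:
    """Per-frame pairing assignment: 0 for N1-first-label/N2-second-label,
    1 for the swapped pairing, by minimum summed distance.

    With ``contact_max`` set, frames where the winning pairing is not fully
    engaged (either distance above the cutoff) inherit the previous frame's
    assignment — the ligand is between partners and carries no orientation
    information.
    """
    a, b = _trace_keys(traces)
    base = np.stack([t.times for t in traces.values()])
    if not np.allclose(base, base[0]):
        raise TrajectoryError("traces do not share a time base")
    d_straight = traces[f"N1-{a}"].values + traces[f"N2-{b}"].values
    d_swapped = traces[f"N1-{b}"].values + traces[f"N2-{a}"].values
    assign = (d_swapped < d_straight).astype(int)
    if contact_max is not None:
        pair_max = np.where(
            assign == 0,
            np.maximum(traces[f"N1-{a}"].values, traces[f"N2-{b}"].values),
            np.maximum(traces[f"N1-{b}"].values, traces[f"N2-{a}"].values),
        )
        engaged = pair_max < contact_max
        if not engaged.any():
            return assign
        last = assign[np.argmax(engaged)]
        for i in range(len(assign)):
            if engaged[i]:
                last = assign[i]
            else:
                assign[i] = last
    return assign


def _runs(values: np.ndarray):
    """(value, start_frame, end_frame_inclusive) runs of a 1D sequence."""
    edges = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges, [len(values) - 1]])
    return [(int(values[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def detect_flips(traces: dict, dwell_min: float = 5.0,
                 contact_max: float = None) -> list:
    """Detect persistent pairing swaps in the four salt-bridge traces.

    A frame's assignment is the amine/aspartate pairing with the smaller
    summed distance.  An event is recorded between consecutive *persistent*
    runs (duration >= ``dwell_min`` ns) of different assignment; shorter
    excursions are treated as unresolved rattling, not flips.  Consecutive
    events therefore alternate orientations.
    """
    a, b = _trace_keys(traces)
    times = next(iter(traces.values())).times
    assign = assignment_series(traces, contact_max=contact_max)
    dt = float(np.median(np.diff(times)))
    runs = _runs(assign)
    persistent = []
    for value, s, e in runs:
        t_end = times[e] + dt if e == len(times) - 1 else times[e + 1]
        if t_end - times[s] >= dwell_min:
            persistent.append((value, s, e))
    names = {0: _PAIRINGS[0].format(a=a, b=b), 1: _PAIRINGS[1].format(a=a, b=b)}
    events = []
    for (v0, s0, e0), (v1, s1, e1) in zip(persistent, persistent[1:]):
        if v0 == v1:
            continue
        events.append(FlipEvent(start=float(times[e0]), end=float(times[s1]),
                                before=names[v0], after=names[v1]))
    return events


# ---------------------------------------------------------------------------
# Superposition-based observables
# ---------------------------------------------------------------------------


def _fit_rotation(mobile: np.ndarray, ref: np.ndarray):
    """Least-squares (Kabsch) rotation of centred mobile onto centred ref."""
    from MDAnalysis.analysis.align import rotation_matrix

    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    R, _ = rotation_matrix(mobile - mc, ref - rc)
    return np.asarray(R), mc, rc


def rmsd_series(traj: Trajectory, ref=0, fit_selection="backbone",
                report_selection="backbone") -> np.ndarray:
    """Per-frame RMSD (Å) against a reference after optimal superposition.

    The rigid fit is computed on ``fit_selection`` and the RMSD is reported
    on ``report_selection`` *without refitting* — so e.g. a ligand RMSD over
    a backbone fit measures ligand motion relative to the receptor.  Pass
    ``fit_selection=None`` to skip superposition.
    """
    rep_idx = traj.select(report_selection)
    if isinstance(ref, StructureModel):
        ref_coords = ref.coords
        if ref_coords.shape[0] != traj.topology.n_atoms:
            raise TrajectoryError("reference atom count mismatch")
    else:
        ref_coords = traj.coords[int(ref)]
    out = np.empty(traj.n_frames)
    if fit_selection is None:
        for f in range(traj.n_frames):
            diff = traj.coords[f, rep_idx] - ref_coords[rep_idx]
            out[f] = np.sqrt((diff ** 2).sum(axis=1).mean())
        return out
    fit_idx = traj.select(fit_selection)
    ref_fit = ref_coords[fit_idx]
    for f in range(traj.n_frames):
        R, mc, rc = _fit_rotation(traj.coords[f, fit_idx], ref_fit)
        moved = (traj.coords[f, rep_idx] - mc) @ R.T + rc
        diff = moved - ref_coords[rep_idx]
        out[f] = np.sqrt((diff ** 2).sum(axis=1).mean())
    return out


def snapshot_indices(n_frames: int, n_snapshots: int) -> np.ndarray:
    """Evenly spaced frame indices including the first and last frame."""
    if n_snapshots < 2:
        raise ValueError("need at least 2 snapshots")
    if n_snapshots > n_frames:
        raise TrajectoryError(
            f"requested {n_snapshots} snapshots from {n_frames} frames"
        )
    return np.round(np.arange(n_snapshots) * (n_frames - 1) / (n_snapshots - 1)
                    ).astype(int)


@dataclass(frozen=True)
class ResidueDispersion:
    label: str
    centroid: tuple
    sd: float          # RMS distance of C-beta positions from the centroid, Å
    n_snapshots: int


@dataclass(frozen=True)
class SwitchStats:
    """Per-residue C-beta positional dispersion of the transmission switch."""

    residues: dict  # bw_label -> ResidueDispersion

    def sd(self, label: str) -> float:
        return self.residues[label].sd


def switch_dispersion(traj: Trajectory, labels=("3.40", "5.50", "6.44"),
                      n_snapshots: int = 100,
                      fit_selection="backbone") -> SwitchStats:
    """C-beta positional dispersion of the transmission-switch residues.

    ``n_snapshots`` evenly spaced frames are superposed on the receptor
    backbone of the first frame; for each label the centroid of the C-beta
    positions and their RMS distance to it (the scalar "SD") are reported.
    Glycine (no C-beta) raises :class:`TrajectoryError`.
    """
    atoms = traj.topology.atoms
    cb_rows = {}
    for lab in labels:
        resid = traj.topology.resolve_label(lab)
        res = traj.topology.residue_atoms(resid)
        if res["resname"].iloc[0] == "GLY":
            raise TrajectoryError(f"{lab} resolves to glycine: no C-beta atom")
        hit = res.index[res["name"] == "CB"]
        if len(hit) != 1:
            raise TrajectoryError(f"{lab}: expected one CB atom on residue {resid}")
        cb_rows[lab] = int(hit[0])
    idx = snapshot_indices(traj.n_frames, n_snapshots)
    fit_idx = traj.select(fit_selection) if fit_selection is not None else None
    ref_fit = traj.coords[0, fit_idx] if fit_idx is not None else None
    positions = {lab: np.empty((len(idx), 3)) for lab in labels}
    for k, f in enumerate(idx):
        if fit_idx is None:
            frame = traj.coords[f]
        else:
            R, mc, rc = _fit_rotation(traj.coords[f, fit_idx], ref_fit)
            frame = (traj.coords[f] - mc) @ R.T + rc
        for lab, row in cb_rows.items():
            positions[lab][k] = frame[row]
    residues = {}
    for lab, pos in positions.items():
        centroid = pos.mean(axis=0)
        sd = float(np.sqrt(((pos - centroid) ** 2).sum(axis=1).mean()))
        residues[lab] = ResidueDispersion(label=lab, centroid=tuple(centroid),
                                          sd=sd, n_snapshots=len(idx))
    return SwitchStats(residues=residues)


def classify_state_stability(stats: SwitchStats, threshold: float = 1.0) -> dict:
    """Label each switch residue ``"fluctuating"`` when its C-beta dispersion
    is >= ``threshold`` Å (boundary inclusive), else ``"stable"``."""
    return {
        lab: ("fluctuating" if disp.sd >= threshold else "stable")
        for lab, disp in stats.residues.items()
    }


@dataclass
class TM35Result:
    """TM3-TM5 inter-carboxylate distance series and contraction summary."""

    times: np.ndarray
    values: np.ndarray
    threshold: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def contracted(self) -> bool:
        """Whether the pocket contracted below the threshold at any frame."""
        return bool(self.min < self.threshold)


def tm3_tm5_series(traj: Trajectory, labels=("3.32", "5.43"),
                   threshold: float = 10.0) -> TM35Result:
    """Per-frame carboxylate-centroid distance between the TM3 and TM5
    aspartates, with mean/min summary and a below-threshold flag."""
    rows_a = _carboxylate_rows(traj, labels[0])
    rows_b = _carboxylate_rows(traj, labels[1])
    ca = traj.coords[:, rows_a, :].mean(axis=1)
    cb = traj.coords[:, rows_b, :].mean(axis=1)
    values = np.linalg.norm(ca - cb, axis=1)
    return TM35Result(times=traj.times.copy(), values=values,
                      threshold=float(threshold))
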
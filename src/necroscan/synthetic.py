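"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here with planted
parameters, so each observable has a round-trip test: planted value in,
measured value out.

* :func:`make_sequences` — class-A-like receptor sequences with the seven
  anchor motifs planted at configurable indices and an optional acidic
  3.32 + 5.42/5.43 tandem.  The bundled hTAAR6/hTAAR8 *stand-in* layouts
  reproduce the published residue indexing of the human receptors
  (D112/D111 at 3.32, D202/D201 at 5.43, P209/P208 at 5.50, ...); the
  backgrounds are random and the records are synthetic stand-ins, not the
  RefSeq entries.
* :func:`make_toy_complex` — a pseudo-atom receptor/diamine complex whose
  inter-carboxylate distance, salt-bridge lengths and contact shell are
  planted exactly.
* :func:`make_trajectory` — a stochastic trajectory around a toy complex:
  mean-reverting (discrete Ornstein-Uhlenbeck) salt-bridge distances, an
  optional two-state Markov process that swaps the amine/aspartate pairing
  (ligand flips), Gaussian positional jitter on the transmission-switch
  C-beta atoms, and an optional TM3-TM5 contraction schedule.
* :func:`build_diamine` — ideal all-anti extended alpha,omega-diamine
  conformers from internal coordinates.

All generators take explicit seeds and are fully deterministic.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import ATOM_COLUMNS, LigandPose, StructureModel
from .numbering import DEFAULT_ANCHOR_CONFIG, ReceptorSequence, parse_label
from .trajectory import Trajectory

__all__ = [
    "SequenceLayout",
    "HTAAR6_STANDIN_LAYOUT",
    "HTAAR8_STANDIN_LAYOUT",
    "SequenceSpec",
    "make_sequence",
    "make_sequences",
    "write_fasta",
    "make_ortholog_panel",
    "panel_metadata",
    "PANEL_SPECIES",
    "ToyComplexConfig",
    "ToyComplex",
    "make_toy_complex",
    "make_symmetric_complex",
    "TrajectoryConfig",
    "SyntheticTrajectory",
    "make_trajectory",
    "DiamineConformer",
    "build_diamine",
    "write_pdb",
]


class GeometryError(ValueError):
    """Raised when a requested toy geometry is infeasible."""


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

#: Class-A consensus motif residues, by BW label.
CLASS_A_MOTIFS = {
    "1.49": "G", "1.50": "N",
    "2.46": "L", "2.47": "A", "2.48": "S", "2.49": "L", "2.50": "D",
    "3.49": "D", "3.50": "R", "3.51": "Y",
    "4.50": "W",
    "5.50": "P", "5.58": "Y",
    "6.47": "C", "6.48": "W", "6.49": "L", "6.50": "P",
    "7.49": "N", "7.50": "P", "7.51": "I", "7.52": "L", "7.53": "Y",
}

#: Background alphabet excludes Pro and Trp so that planted helix anchors are
#: the only candidates for the single-letter and Pro/Trp-bearing motifs; the
#: generator additionally mutates away accidental copies of the multi-letter
#: motifs.  This is a deliberate fixture property (unambiguous anchors), not
#: an attempt at compositional realism.
BACKGROUND_AAS = np.array(list("ACDEFGHIKLMNQRSTVY"))
BACKGROUND_WEIGHTS = np.array([
    0.09, 0.03, 0.04, 0.05, 0.06, 0.07, 0.02, 0.08, 0.04,
    0.11, 0.03, 0.04, 0.03, 0.04, 0.08, 0.06, 0.09, 0.04,
])
BACKGROUND_WEIGHTS = BACKGROUND_WEIGHTS / BACKGROUND_WEIGHTS.sum()


@dataclass(frozen=True)
class SequenceLayout:
    """Anchor indices (helix -> 1-based X.50 index), planted pocket residues
    (BW label -> amino acid) and total length of a synthetic receptor."""

    name: str
    length: int
    anchors: dict
    planted: dict = field(default_factory=dict)

    def index_of(self, label: str) -> int:
        helix, pos = parse_label(label)
        return self.anchors[helix] + (pos - 50)


_TAAR_POCKET = {
    "3.32": "D", "3.33": "V", "3.36": "C", "3.40": "L",
    "5.42": "T", "5.43": "D", "5.46": "S",
    "6.44": "F", "6.51": "Y", "6.52": "T", "6.54": "D", "6.58": "D",
    "7.36": "E", "7.43": "Y",
}

#: Stand-in layout reproducing the published hTAAR6 residue indexing
#: (synthetic background; not the NP_778237.1 sequence).
HTAAR6_STANDIN_LAYOUT = SequenceLayout(
    name="hTAAR6-standin", length=345,
    anchors={1: 50, 2: 78, 3: 130, 4: 157, 5: 209, 6: 273, 7: 307},
    planted=dict(_TAAR_POCKET),
)

#: Stand-in layout reproducing the published hTAAR8 residue indexing
#: (synthetic background; not the NP_444508.1 sequence).
HTAAR8_STANDIN_LAYOUT = SequenceLayout(
    name="hTAAR8-standin", length=342,
    anchors={1: 49, 2: 77, 3: 129, 4: 156, 5: 208, 6: 272, 7: 308},
    planted={**_TAAR_POCKET, "3.40": "V"},
)


@dataclass(frozen=True)
class SequenceSpec:
    """Plant plan for one synthetic receptor sequence."""

    id: str
    layout: SequenceLayout = HTAAR6_STANDIN_LAYOUT
    species: str = "synthetic"
    subtype: str = "TAAR"
    signature: bool = True       # plant the acidic 3.32 + TM5 tandem
    tm5_register: str = "5.43"   # which TM5 position carries the acidic residue
    overrides: dict = field(default_factory=dict)


def _merge_layer(target: dict, layer: dict, layout: SequenceLayout) -> None:
    """Merge one plant layer into target (index -> aa); conflicting plants
    *within* the layer raise; the layer overrides earlier layers."""
    staged: dict[int, str] = {}
    for key, aa in layer.items():
        idx = layout.index_of(key) if isinstance(key, str) else int(key)
        if idx in staged and staged[idx] != aa:
            raise ValueError(f"conflicting plants at index {idx}: "
                             f"{staged[idx]!r} vs {aa!r}")
        staged[idx] = aa
    target.update(staged)


def _plant_map(spec: SequenceSpec) -> dict:
    layout = spec.layout
    plan: dict[int, str] = {}
    _merge_layer(plan, CLASS_A_MOTIFS, layout)
    _merge_layer(plan, layout.planted, layout)
    if not spec.signature:
        _merge_layer(plan, {"3.32": "S", "5.42": "A", "5.43": "A"}, layout)
    elif spec.tm5_register == "5.42":
        _merge_layer(plan, {"5.42": "D", "5.43": "S"}, layout)
    _merge_layer(plan, spec.overrides, layout)
    for idx in plan:
        if not 1 <= idx <= layout.length:
            raise ValueError(f"planted index {idx} outside sequence of length "
                             f"{layout.length}")
    return plan


def _break_accidental_motifs(seq: list, plan: dict) -> None:
    """Mutate background positions so the anchor motifs occur only where
    planted.  Iterates to a fixpoint (mutations could create new matches)."""
    patterns = [pat for pats in DEFAULT_ANCHOR_CONFIG.exact.values()
                for pat, _ in pats if len(pat) > 1]
    planted_idx = set(plan)
    for _ in range(20):
        dirty = False
        s = "".join(seq)
        for pat in patterns:
            for m in re.finditer(rf"(?=({pat}))", s):
                span = range(m.start() + 1, m.start() + 1 + len(m.group(1)))
                if all((i in planted_idx) for i in span):
                    continue  # the planted motif itself
                for i in span:
                    if i in planted_idx:
                        continue
                    for repl in "QGATSN":
                        trial = seq[i - 1]
                        seq[i - 1] = repl
                        window = "".join(seq[max(0, m.start() - 1):
                                             m.start() + len(m.group(1)) + 1])
                        if not re.search(pat, window):
                            dirty = True
                            break
                        seq[i - 1] = trial
                    else:
                        continue
                    break
        if not dirty:
            return
    raise RuntimeError("failed to remove accidental anchor motifs")


def make_sequence(spec: SequenceSpec, rng: np.random.Generator) -> ReceptorSequence:
    """Generate one synthetic receptor sequence from a plant plan."""
    plan = _plant_map(spec)
    seq = list(rng.choice(BACKGROUND_AAS, size=spec.layout.length,
                          p=BACKGROUND_WEIGHTS))
    for idx, aa in plan.items():
        seq[idx - 1] = aa
    _break_accidental_motifs(seq, plan)
    return ReceptorSequence(id=spec.id, species=spec.species,
                            subtype=spec.subtype, residues="".join(seq))


def make_sequences(specs, seed: int = 0) -> list:
    """Generate a batch of synthetic sequences (one shared seeded stream, so
    a given (specs, seed) pair is fully reproducible)."""
    rng = np.random.default_rng(seed)
    return [make_sequence(spec, rng) for spec in specs]


def write_fasta(seqs, path) -> None:
    """Write sequences as FASTA with ``id|species|subtype`` headers."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}|{s.species}|{s.subtype}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i:i + 60] + "\n")


#: Synthetic mammalian panel: (code, species, lineage, n_taar_genes,
#: subtypes carried).  14 species, 26 sequences; gene counts are plausible
#: placeholders carried as metadata, not computed quantities.
PANEL_SPECIES = (
    ("md", "Monodelphis domestica", "Marsupialia", 21, ("TAAR6", "TAAR8")),
    ("tm", "Trichechus manatus", "Afrotheria", 3, ("TAAR6", "TAAR8")),
    ("la", "Loxodonta africana", "Afrotheria", 9, ("TAAR6", "TAAR8")),
    ("bt", "Bos taurus", "Artiodactyla", 21, ("TAAR6",)),
    ("cd", "Camelus dromedarius", "Artiodactyla", 8, ("TAAR6", "TAAR8")),
    ("ss", "Sus scrofa", "Artiodactyla", 9, ("TAAR6", "TAAR8")),
    ("ec", "Equus caballus", "Perissodactyla", 10, ("TAAR6", "TAAR8")),
    ("um", "Ursus maritimus", "Carnivora", 8, ("TAAR6", "TAAR8")),
    ("fc", "Felis catus", "Carnivora", 2, ("TAAR6",)),
    ("rn", "Rattus norvegicus", "Rodentia", 17, ("TAAR6", "TAAR8")),
    ("mm", "Mus musculus", "Rodentia", 15, ("TAAR6", "TAAR8")),
    ("pa", "Pongo abelii", "Primates", 6, ("TAAR6", "TAAR8")),
    ("gg", "Gorilla gorilla", "Primates", 6, ("TAAR6", "TAAR8")),
    ("hs", "Homo sapiens", "Primates", 6, ("TAAR6", "TAAR8")),
)


def make_ortholog_panel(seed: int = 0):
    """Synthetic 26-sequence mammalian TAAR6/TAAR8 ortholog panel.

    Every sequence carries the acidic 3.32 + 5.43 tandem on the hTAAR6/8
    stand-in layouts.  Returns ``(sequences, metadata)`` where metadata also
    contains a dog row with no TAAR6/8 sequences (its diamine-sensor
    signature is famously absent).
    """
    specs = []
    for code, species, lineage, n_genes, subtypes in PANEL_SPECIES:
        for subtype in subtypes:
            layout = (HTAAR6_STANDIN_LAYOUT if subtype == "TAAR6"
                      else HTAAR8_STANDIN_LAYOUT)
            specs.append(SequenceSpec(id=f"{code}{subtype}", layout=layout,
                                      species=species, subtype=subtype))
    return make_sequences(specs, seed=seed), panel_metadata()


def panel_metadata() -> pd.DataFrame:
    """Metadata TSV contents for the synthetic panel (plus the dog row)."""
    rows = []
    for code, species, lineage, n_genes, subtypes in PANEL_SPECIES:
        for subtype in subtypes:
            rows.append({"seq_id": f"{code}{subtype}", "species": species,
                         "lineage": lineage, "subtype": subtype,
                         "n_taar_genes": str(n_genes)})
    rows.append({"seq_id": "", "species": "Canis lupus familiaris",
                 "lineage": "Carnivora", "subtype": "",
                 "n_taar_genes": "2"})
    return pd.DataFrame(rows, columns=["seq_id", "species", "lineage",
                                       "subtype", "n_taar_genes"])


# ---------------------------------------------------------------------------
# PDB writing (single- and multi-model) via MDAnalysis
# ---------------------------------------------------------------------------


def write_pdb(atoms: pd.DataFrame, coords: np.ndarray, path) -> None:
    """Write an atom table with one or more coordinate frames as (multi-model)
    PDB.  ``coords`` is (n_atoms, 3) or (n_frames, n_atoms, 3)."""
    import MDAnalysis as mda
    import warnings

    coords = np.asarray(coords, float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    resid_keys = list(dict.fromkeys(zip(atoms["chain"], atoms["resid"])))
    res_index = {key: i for i, key in enumerate(resid_keys)}
    atom_resindex = np.array([res_index[(c, r)] for c, r in
                              zip(atoms["chain"], atoms["resid"])])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, n_residues=len(resid_keys),
                               atom_resindex=atom_resindex,
                               n_segments=1, trajectory=True)
        u.add_TopologyAttr("names", list(atoms["name"]))
        u.add_TopologyAttr("elements", list(atoms["element"]))
        u.add_TopologyAttr("occupancies", list(atoms["occupancy"]))
        u.add_TopologyAttr("altLocs", list(atoms["altloc"]))
        u.add_TopologyAttr("record_types", list(atoms["record"]))
        u.add_TopologyAttr("tempfactors", [0.0] * n_atoms)
        u.add_TopologyAttr("chainIDs", list(atoms["chain"]))
        first_row = {key: atoms[(atoms["chain"] == key[0])
                                & (atoms["resid"] == key[1])].iloc[0]
                     for key in resid_keys}
        u.add_TopologyAttr("resnames",
                           [first_row[key]["resname"] for key in resid_keys])
        u.add_TopologyAttr("resids", [key[1] for key in resid_keys])
        u.load_new(coords, order="fac")
        with mda.Writer(str(path), multiframe=(n_frames > 1),
                        n_atoms=n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Toy receptor-diamine complexes
# ---------------------------------------------------------------------------

_RESNAME_BY_LABEL = {
    "3.32": "ASP", "5.42": "ASP", "5.43": "ASP",
    "3.33": "VAL", "6.51": "TYR", "3.36": "CYS", "5.46": "SER",
    "6.48": "TRP", "6.52": "THR", "7.43": "TYR",
    "3.40": "LEU", "5.50": "PRO", "6.44": "PHE",
    "6.54": "ASP", "6.58": "ASP", "7.36": "GLU",
}

#: Side-chain carboxylate geometry used by the builders (Å).
_O_HALF_SEP = 0.55    # half the OD1-OD2 separation
_CG_O = 1.25          # carboxylate carbon to oxygen


@dataclass(frozen=True)
class ToyComplexConfig:
    """Planted parameters of a pseudo-atom receptor-diamine complex.

    Defaults follow the active-like regime: a 10.2 Å TM3-TM5
    inter-carboxylate distance with 2.8 Å amine-to-carboxylate salt bridges.
    The inactive-like pocket uses 11.6 Å.
    """

    carboxylate_distance: float = 10.2
    n_o_distance: float = 2.8
    n_carbons: int = 4
    contact_labels: tuple = ("3.33", "6.51")
    contact_distance: float = 3.0
    background_labels: tuple = ("3.36", "5.46", "6.48", "6.52", "7.43",
                                "6.54", "6.58", "7.36")
    include_switch_residues: bool = True
    ligand_offset: tuple = (0.0, 0.0, 0.0)
    layout: SequenceLayout = HTAAR6_STANDIN_LAYOUT


@dataclass
class ToyComplex:
    """A built toy complex with its planted ground truth."""

    structure: StructureModel
    pose: LigandPose
    bw_map: dict
    config: ToyComplexConfig

    def write(self, path) -> None:
        write_pdb(self.structure.atoms, self.structure.coords, path)


def _residue_rows(resid, resname, atom_specs, chain="A", record="ATOM"):
    rows = []
    for name, xyz in atom_specs:
        rows.append({
            "serial": 0, "name": name, "resname": resname, "chain": chain,
            "resid": resid, "x": xyz[0], "y": xyz[1], "z": xyz[2],
            "occupancy": 1.0, "altloc": "",
            "element": name.strip()[:1], "record": record,
        })
    return rows


def _acidic_residue(resid, centroid, resname="ASP"):
    """Asp/Glu pseudo-residue with its carboxylate-oxygen centroid placed
    exactly at ``centroid``; backbone trails away in -y."""
    c = np.asarray(centroid, float)
    o_names = ("OD1", "OD2") if resname == "ASP" else ("OE1", "OE2")
    c_name = "CG" if resname == "ASP" else "CD"
    y_off = math.sqrt(_CG_O ** 2 - _O_HALF_SEP ** 2)
    specs = [
        (o_names[0], c + (0.0, 0.0, _O_HALF_SEP)),
        (o_names[1], c + (0.0, 0.0, -_O_HALF_SEP)),
        (c_name, c + (0.0, -y_off, 0.0)),
        ("CB", c + (0.0, -y_off - 1.53, 0.0)),
        ("CA", c + (0.0, -y_off - 3.06, 0.0)),
        ("N", c + (-1.2, -y_off - 3.4, 0.0)),
        ("C", c + (1.2, -y_off - 3.6, 0.0)),
        ("O", c + (1.4, -y_off - 4.7, 0.0)),
    ]
    return _residue_rows(resid, resname, specs)


def _side_residue(resid, resname, target, direction, distance):
    """Residue whose C-beta sits exactly ``distance`` from ``target`` along
    ``direction``; all other atoms lie further out."""
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    p = np.asarray(target, float)
    cb = p + distance * u
    perp = np.array([u[1], -u[0], 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    specs = [
        ("CB", cb),
        ("CA", cb + 1.53 * u),
        ("N", cb + 2.4 * u + 0.9 * perp),
        ("C", cb + 2.6 * u - 0.9 * perp),
        ("O", cb + 3.7 * u - 1.1 * perp),
    ]
    return _residue_rows(resid, resname, specs)


def _ligand_rows(n1, n2, n_carbons, resname="LIG"):
    n1 = np.asarray(n1, float)
    n2 = np.asarray(n2, float)
    specs = [("N1", n1)]
    for i in range(1, n_carbons + 1):
        frac = i / (n_carbons + 1)
        pos = n1 + frac * (n2 - n1)
        pos = pos + np.array([0.0, 0.35 * (-1) ** i, 0.0])
        specs.append((f"C{i}", pos))
    specs.append(("N2", n2))
    return _residue_rows(900, resname, specs, record="HETATM")


def make_toy_complex(config: ToyComplexConfig = ToyComplexConfig()) -> ToyComplex:
    """Build a pseudo-atom receptor-diamine complex.

    The 3.32 carboxylate centroid sits at the origin and the 5.43 centroid at
    ``(carboxylate_distance, 0, 0)``; the two amine nitrogens are placed on
    the axis at ``n_o_distance`` from each centroid.  Residues listed in
    ``contact_labels`` are planted with their nearest heavy atom exactly
    ``contact_distance`` from the ligand; ``background_labels`` residues are
    placed ~12 Å away so they can never enter a contact shell at the usual
    cutoffs.
    """
    D = float(config.carboxylate_distance)
    r = float(config.n_o_distance)
    nn = D - 2.0 * r
    if nn < 1.0:
        raise GeometryError(
            f"infeasible geometry: carboxylate distance {D:.2f} Å cannot host "
            f"two {r:.2f} Å salt bridges (triangle inequality leaves "
            f"N-N = {nn:.2f} Å)"
        )
    layout = config.layout
    offset = np.asarray(config.ligand_offset, float)
    rows = []
    bw_map = {}

    def add(label, residue_rows):
        resid = residue_rows[0]["resid"]
        bw_map[resid] = label
        rows.extend(residue_rows)

    add("3.32", _acidic_residue(layout.index_of("3.32"), (0.0, 0.0, 0.0)))
    add("5.43", _acidic_residue(layout.index_of("5.43"), (D, 0.0, 0.0)))

    n1 = np.array([r, 0.0, 0.0]) + offset
    n2 = np.array([D - r, 0.0, 0.0]) + offset
    mid = 0.5 * (n1 + n2)
    lig = _ligand_rows(n1, n2, config.n_carbons)

    for i, label in enumerate(config.contact_labels):
        ang = 0.5 + 2.0 * math.pi * i / max(len(config.contact_labels), 1)
        direction = (0.0, math.cos(ang), math.sin(ang))
        resname = _RESNAME_BY_LABEL.get(label, "ALA")
        add(label, _side_residue(layout.index_of(label), resname,
                                 mid - offset, direction,
                                 config.contact_distance))
    for i, label in enumerate(config.background_labels):
        ang = 0.9 + 2.0 * math.pi * i / max(len(config.background_labels), 1)
        direction = (0.0, math.cos(ang), math.sin(ang))
        resname = _RESNAME_BY_LABEL.get(label, "ALA")
        add(label, _side_residue(layout.index_of(label), resname,
                                 mid - offset, direction, 12.0))
    if config.include_switch_residues:
        for i, label in enumerate(("3.40", "5.50", "6.44")):
            ang = 0.2 + 2.1 * i
            direction = (0.0, math.cos(ang), math.sin(ang))
            add(label, _side_residue(layout.index_of(label),
                                     _RESNAME_BY_LABEL[label],
                                     (mid - offset) + np.array([0, 0, -6.0]),
                                     direction, 8.0))
    rows.extend(lig)
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    atoms["serial"] = np.arange(1, len(atoms) + 1)
    struct = StructureModel(atoms=atoms, bw_map=bw_map)
    pose = LigandPose.from_structure(struct)
    return ToyComplex(structure=struct, pose=pose, bw_map=bw_map, config=config)


def make_symmetric_complex(n_o_distance: float = 2.8,
                           layout: SequenceLayout = HTAAR6_STANDIN_LAYOUT) -> ToyComplex:
    """Degenerate toy: a single aspartate with both amine nitrogens placed
    equidistant from its carboxylate centroid (both ionic pairs form, but no
    double salt bridge across two residues)."""
    rows = []
    bw_map = {layout.index_of("3.32"): "3.32"}
    rows.extend(_acidic_residue(layout.index_of("3.32"), (0.0, 0.0, 0.0)))
    d = float(n_o_distance)
    n1 = np.array([d * math.cos(0.5), d * math.sin(0.5), 0.0])
    n2 = np.array([d * math.cos(0.5), -d * math.sin(0.5), 0.0])
    rows.extend(_ligand_rows(n1, n2, 2))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    atoms["serial"] = np.arange(1, len(atoms) + 1)
    struct = StructureModel(atoms=atoms, bw_map=bw_map)
    cfg = ToyComplexConfig(carboxylate_distance=0.0, n_o_distance=d,
                           contact_labels=(), background_labels=(),
                           include_switch_residues=False, layout=layout)
    return ToyComplex(structure=struct, pose=LigandPose.from_structure(struct),
                      bw_map=bw_map, config=cfg)


# ---------------------------------------------------------------------------
# Stochastic trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryConfig:
    """Planted parameters of a synthetic receptor-diamine trajectory.

    The defaults encode the two study regimes:

    * ``active``  — contracted pocket (10.2 Å), no flips, small switch
      jitter (sigma 0.3 Å per axis, dispersion ~0.52 Å < 1 Å);
    * ``inactive`` — relaxed pocket (11.6 Å), Markov flip switching at
      0.01 /ns (order ten flips per microsecond), large switch jitter
      (sigma 0.8 Å per axis, dispersion ~1.39 Å >= 1 Å).

    1000 frames at dt = 1 ns emulate a 1 microsecond sampling scale.
    """

    mode: str = "active"
    n_frames: int = 1000
    dt: float = 1.0
    seed: int = 0
    complex: ToyComplexConfig = None
    bound_mean: float = 2.8
    bound_sigma: float = 0.2
    ou_tau: float = 1.0
    flip_rate: float = None          # per ns; None -> mode default
    switch_times: tuple = None       # explicit planted flip times (ns)
    switch_jitter_sigma: float = None  # Å per axis; None -> mode default
    distance_decay: tuple = None     # (start, end, tau_ns) contraction schedule
    distance_sigma: float = 0.0      # OU sigma on the TM3-TM5 distance

    def resolved(self) -> "TrajectoryConfig":
        if self.mode not in ("active", "inactive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        active = self.mode == "active"
        cplx = self.complex
        if cplx is None:
            cplx = ToyComplexConfig(
                carboxylate_distance=(self.distance_decay[0]
                                      if self.distance_decay
                                      else (10.2 if active else 11.6)))
        flip = self.flip_rate if self.flip_rate is not None else (
            0.0 if active else 0.01)
        jitter = self.switch_jitter_sigma if self.switch_jitter_sigma is not None \
            else (0.3 if active else 0.8)
        return replace(self, complex=cplx, flip_rate=flip,
                       switch_jitter_sigma=jitter)

    @classmethod
    def active(cls, **overrides) -> "TrajectoryConfig":
        return cls(mode="active", **overrides).resolved()

    @classmethod
    def inactive(cls, **overrides) -> "TrajectoryConfig":
        return cls(mode="inactive", **overrides).resolved()


@dataclass
class SyntheticTrajectory:
    """A generated trajectory plus its planted ground truth."""

    trajectory: Trajectory
    states: np.ndarray        # per-frame pairing state (0 straight, 1 swapped)
    switch_times: tuple       # times (ns) at which the state toggled
    planted: dict             # per-frame planted series (d1, d2, tm35)
    config: TrajectoryConfig

    def write(self, path) -> None:
        write_pdb(self.trajectory.topology.atoms, self.trajectory.coords, path)


def _ou_series(rng, n, mean, sigma, tau, dt):
    """Discrete Ornstein-Uhlenbeck: stationary N(mean, sigma^2)."""
    if sigma == 0.0:
        return np.full(n, float(mean))
    phi = math.exp(-dt / tau)
    innov = sigma * math.sqrt(1.0 - phi * phi)
    x = np.empty(n)
    x[0] = mean + sigma * rng.standard_normal()
    noise = rng.standard_normal(n - 1)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + innov * noise[i - 1]
    return x


def make_trajectory(config: TrajectoryConfig) -> SyntheticTrajectory:
    """Generate a two-state stochastic trajectory around a toy complex.

    Per frame: the TM5 aspartate follows the (optional) contraction schedule;
    the amine-to-carboxylate distances of the currently bound pairing follow
    mean-reverting noise around ``bound_mean``; in the swapped state the
    amines exchange partners; the transmission-switch C-beta atoms receive
    i.i.d. Gaussian jitter.  Fully deterministic for a given config.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    toy = make_toy_complex(cfg.complex)
    topo = toy.structure
    atoms = topo.atoms
    F = cfg.n_frames
    if F < 2:
        raise ValueError("n_frames must be >= 2")
    times = np.arange(F) * cfg.dt

    D0 = cfg.complex.carboxylate_distance
    if cfg.distance_decay is not None:
        start, end, tau = cfg.distance_decay
        tm35 = end + (start - end) * np.exp(-times / tau)
    else:
        tm35 = np.full(F, float(D0))
    if cfg.distance_sigma > 0:
        tm35 = tm35 + _ou_series(rng, F, 0.0, cfg.distance_sigma,
                                 cfg.ou_tau, cfg.dt)

    # pairing state: explicit planted switches, or a symmetric two-state
    # Markov process with rate flip_rate per ns
    if cfg.switch_times is not None:
        states = np.zeros(F, int)
        for t in cfg.switch_times:
            states[times >= t] += 1
        states %= 2
        switch_times = tuple(float(t) for t in cfg.switch_times)
    else:
        p = 1.0 - math.exp(-cfg.flip_rate * cfg.dt)
        toggles = rng.random(F - 1) < p
        states = np.concatenate([[0], np.cumsum(toggles) % 2]).astype(int)
        switch_times = tuple(times[1:][toggles].tolist())

    d1 = _ou_series(rng, F, cfg.bound_mean, cfg.bound_sigma, cfg.ou_tau, cfg.dt)
    d2 = _ou_series(rng, F, cfg.bound_mean, cfg.bound_sigma, cfg.ou_tau, cfg.dt)

    coords = np.repeat(topo.coords[None], F, axis=0)

    asp5_rows = atoms.index[atoms["resid"] == cfg.complex.layout.index_of("5.43")
                            ].to_numpy()
    coords[:, asp5_rows, 0] += (tm35 - D0)[:, None]

    lig_rows = atoms.index[atoms["resname"] == "LIG"].to_numpy()
    n1_row = int(atoms.index[(atoms["resname"] == "LIG")
                             & (atoms["name"] == "N1")][0])
    n2_row = int(atoms.index[(atoms["resname"] == "LIG")
                             & (atoms["name"] == "N2")][0])
    carbon_rows = [int(i) for i in lig_rows if i not in (n1_row, n2_row)]

    n1x = np.where(states == 0, d1, tm35 - d1)
    n2x = np.where(states == 0, tm35 - d2, d2)
    coords[:, n1_row, :] = 0.0
    coords[:, n1_row, 0] = n1x
    coords[:, n2_row, :] = 0.0
    coords[:, n2_row, 0] = n2x
    nc = len(carbon_rows)
    for j, row in enumerate(carbon_rows, start=1):
        frac = j / (nc + 1)
        coords[:, row, 0] = n1x + frac * (n2x - n1x)
        coords[:, row, 1] = 0.35 * (-1) ** j
        coords[:, row, 2] = 0.0

    if cfg.switch_jitter_sigma > 0 and cfg.complex.include_switch_residues:
        cb_rows = atoms.index[
            atoms["resid"].isin([cfg.complex.layout.index_of(l)
                                 for l in ("3.40", "5.50", "6.44")])
            & (atoms["name"] == "CB")].to_numpy()
        coords[:, cb_rows, :] += rng.normal(
            0.0, cfg.switch_jitter_sigma, size=(F, len(cb_rows), 3))

    traj = Trajectory(topology=topo, coords=coords, times=times)
    return SyntheticTrajectory(
        trajectory=traj, states=states, switch_times=switch_times,
        planted={"d1": d1, "d2": d2, "tm35": tm35}, config=cfg)


# ---------------------------------------------------------------------------
# Ideal diamine conformers
# ---------------------------------------------------------------------------

CC_BOND = 1.53
CN_BOND = 1.47
TETRAHEDRAL = math.radians(109.47)


@dataclass(frozen=True)
class DiamineConformer:
    """All-anti extended alpha,omega-diamine built from internal coordinates."""

    n_carbons: int
    names: tuple
    coords: np.ndarray
    nn_distance: float

    def as_pose_atoms(self) -> pd.DataFrame:
        rows = []
        for i, (name, xyz) in enumerate(zip(self.names, self.coords), start=1):
            rows.append({"serial": i, "name": name, "resname": "LIG",
                         "chain": "L", "resid": 900,
                         "x": xyz[0], "y": xyz[1], "z": xyz[2],
                         "occupancy": 1.0, "altloc": "",
                         "element": name[:1], "record": "HETATM"})
        return pd.DataFrame(rows, columns=ATOM_COLUMNS)


def build_diamine(n_carbons: int) -> DiamineConformer:
    """Build the planar all-anti zig-zag H2N-(CH2)n-NH2 heavy-atom chain.

    Bond lengths: C-C 1.53 Å, C-N 1.47 Å; all bond angles tetrahedral
    (109.47 deg); all dihedrals anti (180 deg), i.e. the maximally extended
    conformer of the protonated diamine backbone.  Returns the conformer and
    its N-N distance.
    """
    if n_carbons < 1:
        raise ValueError("need at least one carbon between the amines")
    bonds = [CN_BOND] + [CC_BOND] * (n_carbons - 1) + [CN_BOND]
    half = (math.pi - TETRAHEDRAL) / 2.0  # bond tilt from the chain axis
    coords = [np.zeros(3)]
    for i, length in enumerate(bonds):
        step = np.array([length * math.cos(half), 0.0,
                         (-1) ** i * length * math.sin(half)])
        coords.append(coords[-1] + step)
    coords = np.array(coords)
    names = tuple(["N1"] + [f"C{i}" for i in range(1, n_carbons + 1)] + ["N2"])
    nn = float(np.linalg.norm(coords[-1] - coords[0]))
    return DiamineConformer(n_carbons=n_carbons, names=names,
                            coords=coords, nn_distance=nn)
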
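"""Static geometric observables on receptor-diamine 3D structures.

Works on a light tabular structure model (one pandas row per atom) parsed
from PDB files, optionally joined with a generic-numbering map so residues
can be addressed by their Ballesteros-Weinstein label.  Observables:

* inter-carboxylate distance between two acidic pocket residues (the
  TM3-TM5 "pincer" that holds a dicationic ligand),
* the ligand contact shell at a heavy-atom distance cutoff,
* amine-nitrogen / carboxylate-oxygen ionic pairs and the double-salt-bridge
  motif in which each amine of the diamine engages a distinct Asp/Glu.

Distance conventions: "carboxyl moiety" positions are represented by the
centroid of the two side-chain carboxylate oxygens (OD1/OD2 for Asp,
OE1/OE2 for Glu); a carboxylate-carbon alternative (CG/CD) is available via
``method="carbon"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "StructureError",
    "StructureModel",
    "LigandPose",
    "ContactRecord",
    "IonicPair",
    "IonicContacts",
    "read_structure",
    "carboxylate_distance",
    "ligand_contacts",
    "ionic_pairs",
]

ATOM_COLUMNS = [
    "serial", "name", "resname", "chain", "resid",
    "x", "y", "z", "occupancy", "altloc", "element", "record",
]

CARBOXYLATE_OXYGENS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
CARBOXYLATE_CARBON = {"ASP": "CG", "GLU": "CD"}


class StructureError(ValueError):
    """Raised for unreadable structures or unresolvable residues/atoms."""


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


@dataclass
class StructureModel:
    """Atomic coordinates plus an optional residue-index -> BW-label map."""

    atoms: pd.DataFrame
    bw_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise StructureError(f"atom table missing column(s) {sorted(missing)}")
        if len(self.atoms) == 0:
            raise StructureError("structure contains no atoms")
        if not np.isfinite(self.coords).all():
            raise StructureError("non-finite coordinates in structure")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def coords(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(float)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        xyz = np.asarray(xyz, float)
        if xyz.shape != (self.n_atoms, 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return StructureModel(atoms=atoms, bw_map=dict(self.bw_map))

    def transformed(self, rotation: np.ndarray, translation=np.zeros(3)) -> "StructureModel":
        """Rigid-body transform of every atom (used in invariance checks)."""
        return self.with_coords(self.coords @ np.asarray(rotation).T + translation)

    def resolve_label(self, bw_label: str) -> int:
        """Residue index carrying a BW label, via the joined numbering map."""
        for resid, lab in self.bw_map.items():
            if lab == bw_label:
                return resid
        raise StructureError(f"label {bw_label} not present in the structure's "
                             "generic-numbering map")

    def residue_atoms(self, resid: int) -> pd.DataFrame:
        sub = self.atoms[self.atoms["resid"] == resid]
        if len(sub) == 0:
            raise StructureError(f"no atoms for residue {resid}")
        return sub


def read_structure(path, bw_map=None) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Keeps the first MODEL only; for altloc-disordered atoms the highest
    occupancy alternative is retained; hydrogens are kept if present.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure("s", str(path))
    except PDBConstructionException as exc:
        raise StructureError(f"{path}: malformed PDB record ({exc})") from exc
    except ValueError as exc:
        raise StructureError(f"{path}: malformed coordinate field ({exc})") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no atoms in PDB file")
    model = models[0]
    rows = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(),
                               key=lambda a: (a.get_occupancy() or 0.0))
                x, y, z = atom.get_coord()
                rows.append({
                    "serial": atom.get_serial_number(),
                    "name": atom.get_name(),
                    "resname": residue.get_resname().strip(),
                    "chain": chain.id,
                    "resid": residue.get_id()[1],
                    "x": float(x), "y": float(y), "z": float(z),
                    "occupancy": float(atom.get_occupancy() or 1.0),
                    "altloc": atom.get_altloc().strip(),
                    "element": (atom.element or _element_from_name(atom.get_name())),
                    "record": "HETATM" if residue.get_id()[0].strip() else "ATOM",
                })
    if not rows:
        raise StructureError(f"{path}: no atoms in PDB file")
    return StructureModel(atoms=pd.DataFrame(rows, columns=ATOM_COLUMNS),
                          bw_map=dict(bw_map or {}))


@dataclass
class LigandPose:
    """A bound diamine: its atoms and the two labelled amine nitrogens."""

    atoms: pd.DataFrame
    n1_name: str = "N1"
    n2_name: str = "N2"
    resname: str = "LIG"
    charge: int = 2

    def __post_init__(self) -> None:
        names = set(self.atoms["name"])
        if self.n1_name not in names or self.n2_name not in names:
            raise StructureError(
                f"ligand lacks labelled amine nitrogens "
                f"{self.n1_name}/{self.n2_name}"
            )
        if np.linalg.norm(self.n_position(1) - self.n_position(2)) <= 0:
            raise StructureError("ligand N-N distance must be positive")

    @classmethod
    def from_structure(cls, struct: StructureModel, resname: str = "LIG",
                       n1: str = "N1", n2: str = "N2") -> "LigandPose":
        sub = struct.atoms[struct.atoms["resname"] == resname]
        if len(sub) == 0:
            raise StructureError(f"no ligand residue {resname!r} in structure")
        return cls(atoms=sub.reset_index(drop=True), n1_name=n1, n2_name=n2,
                   resname=resname)

    def n_position(self, which: int) -> np.ndarray:
        name = self.n1_name if which == 1 else self.n2_name
        row = self.atoms[self.atoms["name"] == name].iloc[0]
        return row[["x", "y", "z"]].to_numpy(float)

    @property
    def nn_distance(self) -> float:
        return float(np.linalg.norm(self.n_position(1) - self.n_position(2)))

    def heavy_coords(self) -> np.ndarray:
        heavy = self.atoms[self.atoms["element"] != "H"]
        return heavy[["x", "y", "z"]].to_numpy(float)


def _resolve_residue(struct: StructureModel, bw_label: str) -> pd.DataFrame:
    return struct.residue_atoms(struct.resolve_label(bw_label))


def carboxylate_centroid(res: pd.DataFrame, method: str = "oxy_centroid") -> np.ndarray:
    """Representative point of an Asp/Glu carboxyl moiety."""
    resname = res["resname"].iloc[0]
    if resname not in CARBOXYLATE_OXYGENS:
        raise StructureError(
            f"residue {resname}{res['resid'].iloc[0]} is not Asp/Glu"
        )
    if method == "oxy_centroid":
        wanted = CARBOXYLATE_OXYGENS[resname]
        sub = res[res["name"].isin(wanted)]
        if len(sub) != 2:
            raise StructureError(
                f"incomplete carboxylate on {resname}{res['resid'].iloc[0]}: "
                f"expected atoms {wanted}"
            )
        return sub[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    if method == "carbon":
        name = CARBOXYLATE_CARBON[resname]
        sub = res[res["name"] == name]
        if len(sub) != 1:
            raise StructureError(
                f"missing {name} on {resname}{res['resid'].iloc[0]}"
            )
        return sub[["x", "y", "z"]].to_numpy(float)[0]
    raise ValueError(f"unknown carboxylate method {method!r}")


def carboxylate_distance(struct: StructureModel, bw_a: str, bw_b: str,
                         method: str = "oxy_centroid") -> float:
    """Distance (Å) between the carboxyl moieties of two Asp/Glu residues."""
    ca = carboxylate_centroid(_resolve_residue(struct, bw_a), method)
    cb = carboxylate_centroid(_resolve_residue(struct, bw_b), method)
    return float(np.linalg.norm(ca - cb))


@dataclass(frozen=True)
class ContactRecord:
    """A receptor residue within the contact cutoff of the ligand."""

    label: str        # BW label if mapped, else RESNAME+resid
    resid: int
    min_distance: float
    contact_type: str  # "any" | "ionic"


def ligand_contacts(struct: StructureModel, pose: LigandPose,
                    cutoff: float = 3.5) -> list:
    """Receptor residues with any heavy-atom pair closer than ``cutoff`` Å to
    the ligand, sorted by minimum distance."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    lig_xyz = pose.heavy_coords()
    receptor = struct.atoms[
        (struct.atoms["resname"] != pose.resname) & (struct.atoms["element"] != "H")
    ]
    records = []
    for resid, res in receptor.groupby("resid"):
        dmat = cdist(res[["x", "y", "z"]].to_numpy(float), lig_xyz)
        dmin = float(dmat.min())
        if dmin >= cutoff:
            continue
        resname = res["resname"].iloc[0]
        ctype = "any"
        if resname in CARBOXYLATE_OXYGENS:
            onames = CARBOXYLATE_OXYGENS[resname]
            oxy = res[res["name"].isin(onames)]
            nit = pose.atoms[pose.atoms["name"].isin([pose.n1_name, pose.n2_name])]
            if len(oxy) and len(nit):
                dno = cdist(oxy[["x", "y", "z"]].to_numpy(float),
                            nit[["x", "y", "z"]].to_numpy(float))
                if dno.min() < cutoff:
                    ctype = "ionic"
        label = struct.bw_map.get(resid, f"{resname}{resid}")
        records.append(ContactRecord(label=label, resid=int(resid),
                                     min_distance=dmin, contact_type=ctype))
    return sorted(records, key=lambda r: r.min_distance)


@dataclass(frozen=True)
class IonicPair:
    n_name: str       # "N1" or "N2"
    resid: int
    label: str
    o_name: str
    distance: float


@dataclass(frozen=True)
class IonicContacts:
    pairs: tuple
    double_salt_bridge: bool


def ionic_pairs(struct: StructureModel, pose: LigandPose,
                cutoff: float = 4.0) -> IonicContacts:
    """All (amine N, Asp/Glu carboxylate O) pairs below ``cutoff`` Å.

    ``double_salt_bridge`` is set when N1 and N2 each pair with a *distinct*
    acidic residue — the anchoring motif of a pocket-spanning diamine.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    acidic = struct.atoms[
        (struct.atoms["resname"].isin(CARBOXYLATE_OXYGENS))
        & (struct.atoms["resname"] != pose.resname)
    ]
    pairs = []
    partners = {1: set(), 2: set()}
    for which in (1, 2):
        n_xyz = pose.n_position(which)
        for resid, res in acidic.groupby("resid"):
            onames = CARBOXYLATE_OXYGENS[res["resname"].iloc[0]]
            oxy = res[res["name"].isin(onames)]
            for _, orow in oxy.iterrows():
                d = float(np.linalg.norm(
                    orow[["x", "y", "z"]].to_numpy(float) - n_xyz))
                if d < cutoff:
                    label = struct.bw_map.get(resid,
                                              f"{res['resname'].iloc[0]}{resid}")
                    pairs.append(IonicPair(
                        n_name=pose.n1_name if which == 1 else pose.n2_name,
                        resid=int(resid), label=label,
                        o_name=orow["name"], distance=d))
                    partners[which].add(int(resid))
    double = any(
        ra != rb for ra in partners[1] for rb in partners[2]
    )
    return IonicContacts(pairs=tuple(sorted(pairs, key=lambda p: p.distance)),
                         double_salt_bridge=double)
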
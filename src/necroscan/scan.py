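"""Scanning receptor repertoires for the tandem-aspartate diamine signature.

Aminergic class-A GPCRs anchor their ligand's protonated amine on an
aspartate at position 3.32.  Diamine sensors — receptors for the dicationic
decomposition products putrescine and cadaverine — carry a second acidic
residue across the pocket in TM5, at 5.42 (teleost TAAR13c/d) or 5.43
(therian TAAR6/TAAR8).  This module detects that tandem on generically
numbered sequences, profiles the acidic composition of the orthosteric
pocket, and aggregates presence/absence per species.

Sequences whose anchors could not be located are reported as *unscannable*
and never counted as signature-negative, so prevalence estimates are not
deflated by alignment failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .numbering import (
    AnchorConfig,
    DEFAULT_ANCHOR_CONFIG,
    GenericNumbering,
    ReceptorSequence,
    UnanchorableError,
    number_sequence,
    residue_at,
)

__all__ = [
    "ACIDIC",
    "POCKET_LABELS",
    "ACIDIC_CLUSTER_LABELS",
    "SignatureHit",
    "Unscannable",
    "PocketProfile",
    "scan_diamine_signature",
    "scan_many",
    "pocket_profile",
    "summarize_by_taxon",
    "hits_table",
    "read_metadata",
]

#: Negatively charged residues ("acidic" here means Asp or Glu).
ACIDIC = frozenset({"D", "E"})

#: Orthosteric-pocket positions profiled (TM3-TM7 cavity lining).
POCKET_LABELS = (
    "3.32", "3.33", "3.36", "3.40",
    "5.42", "5.43", "5.46", "5.50",
    "6.44", "6.48", "6.51", "6.52", "6.54", "6.58",
    "7.36", "7.43",
)

#: Positions of the conserved Asp/Glu cluster lining the cavity and its
#: extracellular entrance.
ACIDIC_CLUSTER_LABELS = ("3.32", "5.42", "5.43", "6.54", "6.58", "7.36")


@dataclass(frozen=True)
class SignatureHit:
    """Evidence record for the tandem acidic diamine signature."""

    seq_id: str
    pos_3_32: tuple  # (index, aa) or None if 3.32 unnumbered
    tm5_label: str   # "5.42" or "5.43" (the position reported)
    pos_tm5: tuple   # (index, aa) or None
    both_acidic: bool


@dataclass(frozen=True)
class Unscannable:
    """Marker for a sequence whose anchors could not be located."""

    seq_id: str
    reason: str


@dataclass(frozen=True)
class PocketProfile:
    """Residue identities at the named pocket positions of one sequence."""

    seq_id: str
    residues: dict  # bw_label -> aa or None (absent)
    n_acidic: int   # D/E count among ACIDIC_CLUSTER_LABELS


def _pick_tm5(seq, numbering):
    """Choose the TM5 position to report: prefer an acidic residue, 5.43 first
    (the therian register), falling back to whichever position is numbered."""
    at = {lab: residue_at(numbering, seq, lab) for lab in ("5.43", "5.42")}
    for lab in ("5.43", "5.42"):
        if at[lab] is not None and at[lab][1] in ACIDIC:
            return lab, at[lab]
    for lab in ("5.43", "5.42"):
        if at[lab] is not None:
            return lab, at[lab]
    return "5.43", None


def scan_diamine_signature(seq: ReceptorSequence,
                           numbering: GenericNumbering) -> SignatureHit:
    """Scan one numbered sequence for the 3.32 + 5.42/5.43 acidic tandem.

    ``both_acidic`` is true iff the residue at 3.32 is Asp/Glu AND the residue
    at 5.42 or 5.43 is Asp/Glu.  Requires the numbering to cover helices 3
    and 5.
    """
    if not (numbering.covers_helix(3) and numbering.covers_helix(5)):
        raise ValueError(f"{seq.id}: numbering does not cover helices 3 and 5")
    p332 = residue_at(numbering, seq, "3.32")
    tm5_label, ptm5 = _pick_tm5(seq, numbering)
    both = (
        p332 is not None and p332[1] in ACIDIC
        and ptm5 is not None and ptm5[1] in ACIDIC
    )
    return SignatureHit(seq_id=seq.id, pos_3_32=p332, tm5_label=tm5_label,
                        pos_tm5=ptm5, both_acidic=both)


def scan_many(seqs, config: AnchorConfig = DEFAULT_ANCHOR_CONFIG,
              extents: dict = None):
    """Number and scan a batch; returns ``(hits, unscannable)`` lists."""
    hits, failed = [], []
    for seq in seqs:
        try:
            numbering = number_sequence(seq, config, extents)
        except UnanchorableError as exc:
            failed.append(Unscannable(seq_id=seq.id, reason=str(exc)))
            continue
        hits.append(scan_diamine_signature(seq, numbering))
    return hits, failed


def pocket_profile(seq: ReceptorSequence,
                   numbering: GenericNumbering) -> PocketProfile:
    """Resolve every pocket position to its residue and count acidic ones."""
    if not all(numbering.covers_helix(h) for h in (3, 5, 6, 7)):
        raise ValueError(f"{seq.id}: numbering does not cover TM3-TM7")
    residues = {}
    for lab in POCKET_LABELS:
        hit = residue_at(numbering, seq, lab)
        residues[lab] = hit[1] if hit is not None else None
    n_acidic = sum(
        1 for lab in ACIDIC_CLUSTER_LABELS
        if residues.get(lab) is not None and residues[lab] in ACIDIC
    )
    return PocketProfile(seq_id=seq.id, residues=residues, n_acidic=n_acidic)


def read_metadata(path) -> pd.DataFrame:
    """Read the species metadata TSV (seq_id, species, lineage, subtype,
    n_taar_genes).  ``seq_id`` may be empty for species with no scanned
    sequences (they still get a row in the taxon summary)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"seq_id", "species", "lineage", "subtype", "n_taar_genes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing column(s) {sorted(missing)}")
    return df


def summarize_by_taxon(hits, metadata: pd.DataFrame) -> pd.DataFrame:
    """Aggregate signature hits into one row per species.

    Rows are ordered by (lineage, species); ``signature_present`` is true iff
    at least one of the species' sequences carries the acidic tandem, and
    ``subtypes_with_signature`` lists the corresponding receptor subtypes.
    Unscannable sequences should not be passed here.
    """
    by_seq = {}
    for _, row in metadata.iterrows():
        if row["seq_id"]:
            by_seq[row["seq_id"]] = row
    unknown = [h.seq_id for h in hits if h.seq_id not in by_seq]
    if unknown:
        raise KeyError(
            f"hit seq_id(s) not present in metadata: {', '.join(sorted(unknown))}"
        )
    species_rows = {}
    for _, row in metadata.iterrows():
        key = row["species"]
        if key not in species_rows:
            species_rows[key] = {
                "species": key,
                "lineage": row["lineage"],
                "n_taar_genes": row["n_taar_genes"] or "unknown",
                "subtypes": set(),
            }
    for h in hits:
        if h.both_acidic:
            row = by_seq[h.seq_id]
            species_rows[row["species"]]["subtypes"].add(row["subtype"])
    records = []
    for info in species_rows.values():
        subtypes = sorted(info["subtypes"])
        records.append({
            "species": info["species"],
            "lineage": info["lineage"],
            "n_taar_genes": info["n_taar_genes"],
            "subtypes_with_signature": ",".join(subtypes),
            "signature_present": bool(subtypes),
        })
    out = pd.DataFrame(records, columns=[
        "species", "lineage", "n_taar_genes",
        "subtypes_with_signature", "signature_present",
    ])
    return out.sort_values(["lineage", "species"], kind="stable").reset_index(drop=True)


def hits_table(hits, unscannable=()) -> pd.DataFrame:
    """Tabulate scan results; unscannable sequences appear with status
    'unscannable' and empty position columns."""
    rows = []
    for h in hits:
        rows.append({
            "seq_id": h.seq_id,
            "status": "scanned",
            "index_3.32": h.pos_3_32[0] if h.pos_3_32 else "",
            "aa_3.32": h.pos_3_32[1] if h.pos_3_32 else "",
            "tm5_label": h.tm5_label,
            "index_tm5": h.pos_tm5[0] if h.pos_tm5 else "",
            "aa_tm5": h.pos_tm5[1] if h.pos_tm5 else "",
            "both_acidic": h.both_acidic,
        })
    for u in unscannable:
        rows.append({
            "seq_id": u.seq_id, "status": "unscannable",
            "index_3.32": "", "aa_3.32": "", "tm5_label": "",
            "index_tm5": "", "aa_tm5": "", "both_acidic": "",
        })
    return pd.DataFrame(rows, columns=[
        "seq_id", "status", "index_3.32", "aa_3.32",
        "tm5_label", "index_tm5", "aa_tm5", "both_acidic",
    ])
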
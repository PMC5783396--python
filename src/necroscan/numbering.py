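"""Ballesteros–Weinstein (BW) generic numbering for class-A GPCR sequences.

Class-A (rhodopsin-like) receptors share a bundle of seven transmembrane
helices, and each helix carries one highly conserved residue that defines the
helix's reference position X.50: the GN motif in TM1 (N1.50), LAxxD in TM2
(D2.50), the D[R]Y triad in TM3 (R3.50), W4.50 in TM4, P5.50 in TM5, CWxP in
TM6 (P6.50) and NPxxY in TM7 (P7.50).  Once the anchor residue of a helix is
located, every other helical position is numbered by its offset from the
anchor:

    bw_position = 50 + (residue_index - anchor_index)

so that, e.g., the conserved aminergic aspartate eighteen residues N-terminal
of R3.50 is D3.32.  Loops and termini are left unnumbered.

This module finds the anchors by motif search (with relaxed fallback patterns
and disambiguation against reference inter-anchor spacings taken from the
beta-2 adrenergic receptor template), assigns labels within configurable
per-helix extents, and exposes position look-up plus the TM5 single-gap
equivalence rule used to compare the acidic TM5 position of teleost (5.42)
and therian (5.43) trace-amine receptors across species.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReceptorSequence",
    "AnchorHit",
    "MotifAnchors",
    "GenericNumbering",
    "AnchorConfig",
    "FastaError",
    "UnanchorableError",
    "NumberingConfigError",
    "read_fasta",
    "locate_anchors",
    "assign_generic_numbers",
    "number_sequence",
    "residue_at",
    "equivalence_classes",
    "numbering_table",
    "DEFAULT_ANCHOR_CONFIG",
    "DEFAULT_HELIX_EXTENTS",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: 20 standard residues plus X for unknown.
AA_ALPHABET = STANDARD_AA | {"X"}


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


class UnanchorableError(ValueError):
    """Raised when one or more helix anchors cannot be located."""


class NumberingConfigError(ValueError):
    """Raised for inconsistent numbering configuration (e.g. overlapping helices)."""


@dataclass(frozen=True)
class ReceptorSequence:
    """A receptor protein sequence with 1-based residue indexing."""

    id: str
    residues: str
    species: str = ""
    subtype: str = ""
    index_base: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue letter(s) {sorted(bad)} "
                "(expected the 20 standard amino acids or X)"
            )
        if self.index_base != 1:
            raise ValueError("index_base must be 1")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> str:
        """1-based residue lookup."""
        if not 1 <= index <= len(self.residues):
            raise IndexError(f"{self.id}: residue index {index} out of range")
        return self.residues[index - 1]


def read_fasta(path) -> list[ReceptorSequence]:
    """Read receptor sequences from a FASTA file.

    Headers of the form ``id|species|subtype`` are split into the
    corresponding fields; any other header is used verbatim as the id.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise FastaError(f"{path}: empty FASTA input")
    for lineno, line in enumerate(lines, start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FastaError(
                    f"{path}: malformed FASTA, expected '>' header at line {lineno}"
                )
            break
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        if "|" in header:
            parts = [p.strip() for p in header.split("|")]
        else:
            parts = [header.split()[0]]
        rid = parts[0]
        species = parts[1] if len(parts) > 1 else ""
        subtype = parts[2] if len(parts) > 2 else ""
        if rid in seen:
            raise FastaError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        try:
            records.append(
                ReceptorSequence(id=rid, species=species, subtype=subtype,
                                 residues=str(rec.seq).upper())
            )
        except ValueError as exc:
            raise FastaError(str(exc)) from exc
    return records


# ---------------------------------------------------------------------------
# Anchor location
# ---------------------------------------------------------------------------

MOTIF_NAMES = {
    1: "GN (N1.50)",
    2: "LAxxD (D2.50)",
    3: "DRY (R3.50)",
    4: "W4.50",
    5: "P5.50",
    6: "CWxP (P6.50)",
    7: "NPxxY (P7.50)",
}


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor motif patterns and inter-anchor spacing model.

    ``exact``/``relaxed`` map helix -> list of ``(regex, offset)`` where the
    anchor index is ``match_start + offset`` (0-based within the pattern).
    ``ref_spacings`` are the six consecutive anchor-to-anchor spacings of the
    ADRB2 template numbering (N51, D79, R131, W158, P211, P288, P323);
    ``spacing_windows`` are hard plausibility bounds on each spacing.
    """

    exact: dict = field(default_factory=lambda: {
        1: [("GN", 1)],
        2: [("[LIVMF]A..D", 4)],
        3: [("[DE]R[YF]", 1)],
        4: [("W", 0)],
        5: [("P", 0)],
        6: [("CW.P", 3)],
        7: [("NP..Y", 1)],
    })
    relaxed: dict = field(default_factory=lambda: {
        1: [("N", 0)],
        2: [("[ST]..D", 3), ("D", 0)],
        3: [("R", 0)],
        4: [("[FY]", 0)],
        5: [],
        6: [("W.P", 2), ("[FY].P", 2)],
        7: [("P..Y", 0)],
    })
    ref_spacings: tuple = (28, 52, 27, 53, 77, 35)
    spacing_windows: tuple = ((20, 40), (40, 65), (20, 35), (40, 70), (45, 120), (25, 45))
    relaxed_penalty: float = 1000.0
    min_length: int = 250


DEFAULT_ANCHOR_CONFIG = AnchorConfig()


@dataclass(frozen=True)
class AnchorHit:
    helix: int
    index: int  # 1-based index of the X.50 residue
    motif_matched: str
    confidence: str  # "exact" | "relaxed"


@dataclass(frozen=True)
class MotifAnchors:
    """One located anchor per helix 1-7, strictly increasing in sequence."""

    hits: tuple

    def __post_init__(self) -> None:
        if len(self.hits) != 7 or [h.helix for h in self.hits] != list(range(1, 8)):
            raise ValueError("expected exactly one anchor per helix 1..7")
        idx = [h.index for h in self.hits]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("anchor indices must strictly increase with helix number")

    def index(self, helix: int) -> int:
        return self.hits[helix - 1].index

    @property
    def indices(self) -> tuple:
        return tuple(h.index for h in self.hits)


def _candidates(seq: str, patterns) -> list:
    """Overlap-aware regex matches: list of (anchor_index_1based, matched_text)."""
    out = []
    for pat, offset in patterns:
        for m in re.finditer(rf"(?=({pat}))", seq):
            out.append((m.start() + offset + 1, m.group(1)))
    # de-duplicate on anchor index, keep first pattern's match text
    seen = {}
    for idx, txt in out:
        seen.setdefault(idx, txt)
    return sorted(seen.items())


def locate_anchors(seq: ReceptorSequence,
                   config: AnchorConfig = DEFAULT_ANCHOR_CONFIG) -> MotifAnchors:
    """Locate the seven X.50 anchor residues of a class-A receptor sequence.

    Each helix's consensus motif is searched with a strict pattern first and a
    relaxed fallback second.  When several candidate placements exist, the
    combination minimising the total absolute deviation from the reference
    inter-anchor spacings (subject to hard spacing windows) is selected by
    dynamic programming over helices.

    Raises :class:`UnanchorableError` when a helix has no candidate match or
    no spacing-feasible combination exists.
    """
    if len(seq) < config.min_length:
        raise UnanchorableError(
            f"{seq.id}: sequence too short ({len(seq)} < {config.min_length}) "
            "for a seven-helix receptor"
        )
    s = seq.residues
    cands: dict[int, list] = {}
    missing = []
    for helix in range(1, 8):
        exact = _candidates(s, config.exact.get(helix, []))
        if exact:
            cands[helix] = [(i, t, "exact") for i, t in exact]
            continue
        relaxed = _candidates(s, config.relaxed.get(helix, []))
        if relaxed:
            cands[helix] = [(i, t, "relaxed") for i, t in relaxed]
        else:
            missing.append(MOTIF_NAMES[helix])
    if missing:
        raise UnanchorableError(
            f"{seq.id}: no candidate match for motif(s): {', '.join(missing)}"
        )

    # DP over helices: state = candidate chosen for the current helix.
    best: dict[int, tuple] = {}  # cand index in helix h -> (cost, prev_cand)
    for ci, (idx, _, conf) in enumerate(cands[1]):
        best[ci] = ((config.relaxed_penalty if conf == "relaxed" else 0.0), None)
    paths = [best]
    for helix in range(2, 8):
        lo, hi = config.spacing_windows[helix - 2]
        ref = config.ref_spacings[helix - 2]
        nxt: dict[int, tuple] = {}
        for ci, (idx, _, conf) in enumerate(cands[helix]):
            base = config.relaxed_penalty if conf == "relaxed" else 0.0
            for pj, (pcost, _) in paths[-1].items():
                pidx = cands[helix - 1][pj][0]
                spacing = idx - pidx
                if not lo <= spacing <= hi:
                    continue
                cost = pcost + base + abs(spacing - ref)
                if ci not in nxt or cost < nxt[ci][0]:
                    nxt[ci] = (cost, pj)
        paths.append(nxt)
    if not paths[-1]:
        raise UnanchorableError(
            f"{seq.id}: no anchor combination satisfies the inter-anchor "
            "spacing windows"
        )
    # backtrack
    ci = min(paths[-1], key=lambda c: paths[-1][c][0])
    chosen = []
    for helix in range(7, 0, -1):
        idx, txt, conf = cands[helix][ci]
        chosen.append(AnchorHit(helix=helix, index=idx, motif_matched=txt,
                                confidence=conf))
        ci = paths[helix - 1][ci][1]
    return MotifAnchors(hits=tuple(reversed(chosen)))


# ---------------------------------------------------------------------------
# Label assignment
# ---------------------------------------------------------------------------

#: Default helix extents as BW position ranges around each X.50 anchor.
#: Derived from the ADRB2 template helix spans; configurable because helix
#: boundaries are not sharply defined.
DEFAULT_HELIX_EXTENTS = {
    1: (30, 60),
    2: (38, 66),
    3: (22, 56),
    4: (39, 63),
    5: (35, 68),
    6: (28, 61),
    7: (31, 56),
}


@dataclass(frozen=True)
class GenericNumbering:
    """Residue-index <-> BW-label bijection for one sequence."""

    seq_id: str
    index_to_label: dict
    label_to_index: dict
    tm_bounds: dict  # helix -> (start_index, end_index), 1-based inclusive
    anchors: MotifAnchors = None

    def label_of(self, index: int):
        return self.index_to_label.get(index)

    def index_of(self, label: str):
        return self.label_to_index.get(label)

    def covers_helix(self, helix: int) -> bool:
        return helix in self.tm_bounds


_LABEL_RE = re.compile(r"^([1-7])\.(\d{1,3})$")


def parse_label(label: str) -> tuple:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"invalid Ballesteros-Weinstein label {label!r}")
    return int(m.group(1)), int(m.group(2))


def assign_generic_numbers(seq: ReceptorSequence, anchors: MotifAnchors,
                           extents: dict = None) -> GenericNumbering:
    """Assign BW labels to every residue within the configured helix extents.

    Labels follow the offset rule bw = 50 + (index - anchor_index); residues
    outside all extents (loops, termini) stay unnumbered.  Raises
    :class:`NumberingConfigError` if the configured extents make helices
    overlap in sequence space.
    """
    extents = dict(DEFAULT_HELIX_EXTENTS if extents is None else extents)
    index_to_label: dict[int, str] = {}
    label_to_index: dict[str, int] = {}
    tm_bounds: dict[int, tuple] = {}
    prev_end = 0
    for helix in range(1, 8):
        lo_bw, hi_bw = extents[helix]
        if not lo_bw <= 50 <= hi_bw:
            raise NumberingConfigError(
                f"helix {helix} extent ({lo_bw},{hi_bw}) does not include position 50"
            )
        anchor = anchors.index(helix)
        start = max(1, anchor + (lo_bw - 50))
        end = min(len(seq), anchor + (hi_bw - 50))
        if start <= prev_end:
            raise NumberingConfigError(
                f"helix {helix} extent overlaps helix {helix - 1} "
                f"(starts at {start}, previous ends at {prev_end})"
            )
        for idx in range(start, end + 1):
            label = f"{helix}.{50 + idx - anchor}"
            index_to_label[idx] = label
            label_to_index[label] = idx
        tm_bounds[helix] = (start, end)
        prev_end = end
    return GenericNumbering(seq_id=seq.id, index_to_label=index_to_label,
                            label_to_index=label_to_index, tm_bounds=tm_bounds,
                            anchors=anchors)


def number_sequence(seq: ReceptorSequence,
                    config: AnchorConfig = DEFAULT_ANCHOR_CONFIG,
                    extents: dict = None) -> GenericNumbering:
    """Convenience wrapper: locate anchors, then assign generic numbers."""
    return assign_generic_numbers(seq, locate_anchors(seq, config), extents)


def residue_at(numbering: GenericNumbering, seq: ReceptorSequence, bw_label: str):
    """Return ``(index, one_letter)`` of the residue carrying ``bw_label``.

    Returns ``None`` (absent marker) when the label falls outside the numbered
    regions; raises ``ValueError`` only for syntactically invalid labels.
    """
    parse_label(bw_label)
    idx = numbering.index_of(bw_label)
    if idx is None:
        return None
    return idx, seq.residue(idx)


def equivalence_classes(labels, tm5_gap_rule: bool = True) -> list:
    """Partition BW labels into cross-species equivalence classes.

    With the TM5 single-gap rule on, 5.42 and 5.43 — the acidic TM5 position
    of teleost versus therian diamine-sensing receptors, which align through
    one gap — form a single class; every other label is a singleton.
    """
    labels = list(dict.fromkeys(labels))
    for lab in labels:
        parse_label(lab)
    classes = []
    tm5 = [lab for lab in labels if lab in ("5.42", "5.43")]
    if tm5_gap_rule and tm5:
        classes.append(frozenset(tm5))
        labels = [lab for lab in labels if lab not in tm5]
    classes.extend(frozenset([lab]) for lab in labels)
    return classes


def numbering_table(seq: ReceptorSequence, numbering: GenericNumbering) -> pd.DataFrame:
    """Tabulate the numbering as (seq_id, index, aa, bw_label) rows."""
    rows = [
        {"seq_id": seq.id, "index": idx, "aa": seq.residue(idx), "bw_label": lab}
        for idx, lab in sorted(numbering.index_to_label.items())
    ]
    return pd.DataFrame(rows, columns=["seq_id", "index", "aa", "bw_label"])
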
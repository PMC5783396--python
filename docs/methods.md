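# Methods

`necroscan` operationalises a simple structural hypothesis about how
decomposition diamines are smelled: a receptor is a candidate
putrescine/cadaverine sensor when its orthosteric pocket carries *two*
acidic residues facing each other — the canonical aminergic Asp3.32 in TM3
and a second Asp/Glu in TM5 (position 5.42 in teleost TAAR13c/d, 5.43 in
therian TAAR6/TAAR8) — at a separation compatible with a doubly protonated
C4/C5 diamine bridging them by two salt bridges.  The package provides the
sequence annotation needed to ask that question across repertoires, the
geometric observables that test it on structures and trajectories, and
synthetic generators that plant every parameter so the observables can be
validated by round-trip recovery.

## Generic numbering

Anchors are located per helix by motif search: strict patterns
(`GN` → N1.50, `[LIVMF]Axx D` → D2.50, `[DE]R[YF]` → R3.50, `W` → W4.50,
`P` → P5.50, `CWxP` → P6.50, `NPxxY` → P7.50) with documented relaxed
fallbacks (e.g. lone `R` for a degenerate DRY; confidence is then reported
as `relaxed`).  When a pattern matches more than once, the combination of
candidates minimising the total absolute deviation from reference
inter-anchor spacings is chosen by dynamic programming, subject to hard
spacing windows.  The reference spacings (28, 52, 27, 53, 77, 35) are the
consecutive anchor separations of the human beta-2 adrenergic receptor
(N51, D79, R131, W158, P211, P288, P323), the usual class-A template; the
windows are deliberately wide (e.g. 45–120 between P5.50 and P6.50) because
ICL3 length varies strongly across the family.

Labels follow the offset rule `bw = 50 + (index − anchor)`, applied inside
per-helix extents (defaults: 1.30–1.60, 2.38–2.66, 3.22–3.56, 4.39–4.63,
5.35–5.68, 6.28–6.61, 7.31–7.56) chosen to cover every pocket position the
package addresses while never overlapping on a class-A-sized receptor;
extents are configuration, not dogma, and overlapping configurations are
rejected.  Loops and termini stay unnumbered.  Residue indexing is 1-based
on the full precursor sequence, which is why the human TAAR6 pocket reads
D112 (3.32), D202 (5.43), P209 (5.50).

The TM5 register difference between teleost (5.42) and therian (5.43)
diamine receptors — one helix position, historically absorbed by a single
alignment gap — is handled as *metadata*, not renumbering: an equivalence
class {5.42, 5.43} that scanning and reporting respect.  No other bulge or
constriction rule is applied.

## Signature scan

A sequence is signature-positive when the residue at 3.32 **and** the
residue at 5.42 or 5.43 are both in {D, E}.  Glu is accepted alongside Asp
because the physics is the charge, not the side-chain length; residue
identities are reported so a stricter Asp-only filter remains possible
downstream.  Sequences whose anchors cannot be located are reported as
*unscannable* and excluded from denominators rather than counted negative.
The pocket profile resolves sixteen cavity-lining positions
(3.32–3.40, 5.42–5.50, 6.44–6.58, 7.36, 7.43) and counts acidic residues
over the six-position entrance/floor cluster {3.32, 5.42, 5.43, 6.54, 6.58,
7.36}.  Species-level aggregation consumes a user-supplied metadata table
(gene counts are annotations, not computed quantities) and orders rows by
(lineage, species).

## Geometry conventions

* Carboxyl-moiety positions are the centroid of the two carboxylate oxygens
  (OD1/OD2, OE1/OE2); a carboxylate-carbon convention (CG/CD) is available
  because figures rarely state which atoms their dashed lines join.
* Ligand contacts are heavy-atom, any-pair, residue-level, default cutoff
  3.5 Å (3.0 Å is the other conventional choice and is a flag).
* Ionic pairs are amine-N to carboxylate-O under 4.0 Å, a common salt-bridge
  convention; the *double salt bridge* flag requires N1 and N2 to engage
  two distinct acidic residues.
* PDB parsing keeps the first MODEL and the highest-occupancy altloc.

## Trajectory observables

Frame times come from a configured step because multi-model PDB carries
none; the default dt of 1 ns makes a 1000-frame file span the microsecond
scale typical of the simulations this tooling is aimed at.

* **Salt-bridge traces**: per frame, each amine N to each carboxylate-oxygen
  centroid (N-to-centroid rather than N-to-nearest-oxygen; the alternative
  is a config choice that shifts distances by ~0.1 Å and changes no
  conclusion).
* **Flip detection**: per frame the orientation is the amine/aspartate
  pairing with the smaller summed distance; runs shorter than `dwell_min`
  (default 5 ns) are treated as unresolved rattling; an event is a
  transition between consecutive persistent runs of different orientation,
  so consecutive events alternate by construction.  An optional engagement
  cutoff makes unbound frames inherit the previous orientation.
* **RMSD**: least-squares (Kabsch) superposition on a fit selection, RMSD
  reported on a report selection without refitting.
* **Switch dispersion**: `n_snapshots` evenly spaced frames (first and last
  included, indices `round(i·(F−1)/(n−1))`) are superposed on the
  first-frame receptor backbone; per residue the scalar "SD" is the RMS
  Euclidean distance of the C-beta positions from their 3D centroid.  For
  isotropic per-axis jitter of width sigma this converges to sigma·sqrt(3).
  Classification: *fluctuating* iff SD ≥ 1.0 Å (boundary inclusive),
  *stable* otherwise.  Glycine at a switch position is an error, not a
  silent skip.
* **TM3–TM5 contraction**: the per-frame 3.32/5.43 inter-carboxylate
  distance, with mean, minimum and a `min < 10 Å` flag.

## Synthetic generators (what they emulate, and what they do not)

The generators define the regimes the observables are validated under:

* Sequences: backgrounds are i.i.d. draws over the 18 amino acids excluding
  Pro and Trp, with accidental copies of the anchor motifs mutated away.
  This guarantees planted anchors are the unique candidates — a fixture
  property chosen so anchor recovery is exact by construction — at the cost
  of compositional realism.  The bundled hTAAR6/hTAAR8 stand-in layouts
  reproduce the published human residue indexing (lengths 345/342, anchors
  at 50/78/130/157/209/273/307 and 49/77/129/156/208/272/308) and the
  TAAR-like pocket residues; they are synthetic stand-ins, not database
  sequences, and real orthologs will carry noisier motifs than these tests
  exercise.
* Toy complexes: pseudo-residues carrying only the atoms the observables
  read (backbone, C-beta, carboxylates); the 3.32/5.43 oxygen centroids are
  placed exactly at the planted separation (10.2 Å active-like, 11.6 Å
  inactive-like), amine nitrogens at the planted salt-bridge length
  (2.8 Å), planted contact residues with their nearest atom exactly at the
  planted contact distance, everything else ≥ 8 Å away.
* Trajectories: bound amine–carboxylate distances follow a discrete
  Ornstein–Uhlenbeck process (stationary mean 2.8 Å, sigma 0.2 Å, tau 1 ns)
  — the simplest process with a planted stationary mean and width; flips
  are a symmetric two-state Markov process (default rate 0.01/ns in the
  inactive regime, i.e. order ten flips per simulated microsecond, zero in
  the active regime) or explicit planted switch times; switch C-beta atoms
  receive i.i.d. Gaussian jitter (sigma 0.3 Å active / 0.8 Å inactive per
  axis, i.e. dispersions of ~0.52 and ~1.39 Å on either side of the 1 Å
  threshold); pocket contraction is an optional exponential schedule.
  The receptor backbone is otherwise static: superposition is exercised by
  explicit rigid-transform tests, not by the generator.  None of this
  imitates molecular mechanics — no forces, membrane, solvent or coupling
  between observables — so passing tests demonstrate correctness of the
  measurement code and estimators, not realism of any simulation.
* Diamines: all-anti extended conformers from internal coordinates (C–C
  1.53 Å, C–N 1.47 Å, tetrahedral angles, 180° dihedrals).  The C4 and C5
  builds give N–N distances of 6.20 and 7.40 Å.

All generators take explicit integer seeds; there is no global random
state, and identical configs give byte-identical outputs.

## Problem sizes and numerical choices

Default validation sizes — 1000-frame trajectories (10,000 for estimator
convergence checks), 100 dispersion snapshots, 20-seed ensembles for the
Poisson and classification checks — were chosen as the smallest sizes at
which the estimators' sampling error is clearly below the effect sizes
being demonstrated.  Distances are exact float64 arithmetic; planted
toy-geometry tolerances are ±0.05 Å (write/read round trip through PDB's
0.001 Å fixed-point fields); flip dwell comparisons use half-open run
durations measured on the configured time base.

## Known limitations

* Anchor search assumes all seven motifs are at least degenerately present;
  heavily diverged class-A sequences (and non-class-A receptors) will be
  unscannable rather than approximately numbered.
* No bulge/constriction renumbering beyond the TM5 5.42/5.43 equivalence.
* The contact and salt-bridge definitions are geometric only — no
  protonation-state or hydrogen-bond-angle reasoning.
* Multi-model PDB is the only bundled trajectory reader; binary formats
  would slot behind the same `Trajectory` contract but are not wired in.
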
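# Methods

This note records the models, parameter choices and numerical conventions
behind `mutannot`, and what the synthetic test data do and do not show.

## Scope and data model

The pipeline annotates *substitution* mutations given in 1-based query
(UniProt-style) sequence coordinates. Deletions, insertions and frameshifts
are parsed and flagged (`kind` on `MutationRecord`) but not structurally
modelled. Structures are read from PDB files with gemmi; only the first
model is kept, alternate conformations are resolved at parse time (highest
occupancy wins, ties to the alphabetically first altloc), and non-standard
amino acids (e.g. MSE) map to their parent residue for sequence purposes
while keeping their atoms for geometry. Structure residues retain author
numbering everywhere; reports state both coordinate systems.

## Intermolecular contacts

A target-chain residue contacts a partner when the minimum heavy-atom
distance is ≤ 4.0 Å (configurable). Heavy atoms only: crystal structures
generally lack hydrogens, so including them would make the rule depend on a
hydrogen-placement model; the cutoff is interpreted as inclusive. Waters are
always excluded; ions, cryoprotectants and buffer components are excluded by
a configurable deny-list. Ligand selections match het-group names (default:
ATP/ADP/AMP/ANP/ACP/AGS plus the 20 free amino acids); tRNA selections are
chains whose polymer residues are mostly nucleotides; partner-chain
selections are explicit chain ids. The k-d-tree implementation is exact, and
the test suite holds it equal to an O(n²) brute-force oracle on random
structures; contact sets are monotone in the cutoff by construction.

## Solvent accessibility

Per-atom accessible areas use the Shrake–Rupley construction: each atom's
sphere is expanded by the 1.4 Å probe and sampled with a deterministic
golden-section spiral point set (default 960 points; no RNG, so results are
bit-stable), and the accessible fraction is multiplied by 4π(r+probe)².
Radii are a Chothia/NACCESS-style per-element set (C 1.87, N 1.65, O 1.40,
S 1.85, P 1.80 Å ...); hydrogens are ignored; an unknown element is an error
naming the atom. Per-residue area is exactly the sum of its atoms' areas.

RSA = 100 · SA / maxASA(residue type). The normalisation table matters: RSA
shifts by a few points between the empirical Rost & Sander (1994) maxima
(default) and the theoretical Tien et al. (2013) values, so the choice is
explicit in the API and CLI output. Burial is the strict rule
RSA > 20 % ⇒ accessible, else buried (20.0 itself is buried). Values above
100 % can occur at termini and are reported as-is.

Accuracy is pinned by three oracles: the closed form for an isolated atom,
the analytic two-sphere cap solution, and a 10⁴-sample Monte-Carlo
integration on fixtures (agreement within 2 %; quadrature convergence from
960 to 3840 points is better than 1 %).

## Secondary structure

A compact Kabsch–Sander assigner. Amide hydrogens are rebuilt at 1.0 Å from
N along the preceding carbonyl's O→C direction (prolines and segment-initial
residues cannot donate). A hydrogen bond is recorded when
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol; distances
below 0.5 Å are clamped and flagged as clashes. Chains split into segments
wherever the peptide bond C–N exceeds 2.5 Å, and no bond crosses a break.
Two consecutive n-turns make a helix (periods 4 and 5 merge into H, period 3
is G); parallel/antiparallel bridge patterns mark strands, with isolated
bridges merged into E; leftover turn spans are T; a CA-trace kink above 70°
is S; priority H > E > G > T > S. The six-letter reduced alphabet
{H,G,E,T,S,−} matches the annotation tables the classifier consumes, which
key on the broad code rather than exact helix termini — per-residue codes at
element boundaries can differ by one residue between DSSP dialects (the
suite measures ≥ 95 % agreement with mdtraj's independent DSSP
implementation on the generated fixtures).

## Pairwise alignment and site mapping

Query-to-structure mapping uses a true global affine-gap alignment
(Needleman–Wunsch/Gotoh) under BLOSUM62 with EMBOSS-style penalties (open
−10, extend −0.5), end gaps penalised; the first optimal traceback is used,
which is deterministic. Query and structural homologue are expected to be
near-identical, so results are robust to the precise gap model; an identity
below 95 % raises an error (wrong structure supplied). Scores are verified
against exhaustive enumeration of all alignments on short sequences.
NO_COVERAGE distinguishes a gap in the subject sequence from a residue
present in the sequence but unresolved in the crystal (the latter requires
passing the full-length subject sequence) from positions beyond the
alignment; all three routes feed category D but reports keep the reason.

## Conservation

Column profiles count every symbol including gaps and are reported as
integer percents with largest-remainder rounding (sums are exactly 100).
The conservation score is the mean BLOSUM62 score over all unordered
non-gap residue pairs, normalised by the mean self-substitution score of the
column's residues and clamped at zero, times 100 — chosen because it yields
exactly 100 for a fully conserved column and a natural 0–100 scale for the
four bins; the formula is pluggable. Rows are unweighted, so duplicated
sequences count twice (sequence weighting and phylogeny-aware scoring are
out of scope). Bins are [0,40), [40,60), [60,80), [80,100], applying the
lower-limit tie rule uniformly — including at 80, where the published
bin labels are internally tense about openness; the uniform rule is the
package's resolution. The natural-variant flag fires when the mutant
residue occurs at least once in the aligned column.

## Classification

The category is a pure function of the evidence bundle with a fixed
precedence: (1) no structural coverage → D; (2) ATP/amino-acid or tRNA
contact → A; (3) dimer contact → C; (4) unassigned secondary structure → D;
(5) buried → B; (6) otherwise → C. Contacts dominate burial — a buried
interface residue is an interface mutation, not a core one — and an
unassigned-structure site routes to D even when its RSA is defined. Burial
uses the strict >20 % rule even where the published per-mutation letters
disagree with it; the replay test names the five divergent rows
(Cys211Arg, Tyr373Cys, Thr522Asn, Gly110Ser, Leu155Arg) and the classifier
reports rather than fits them — these are internal inconsistencies of the
source tables (e.g. a dimer-contact residue listed under structural
stability). Conservation bins and natural-variant flags are evidence only
and never change the letter, because no conservation-based rule is defined
for the scheme; a configuration switch can demote natural-variant sites to D
for exploratory use.

## Curated tables

The packaged census (63 substitutions, 14 enzymes, cytoplasmic and
mitochondrial compartments) transcribes the published per-mutation feature
values verbatim: homologue residue spreads, secondary-structure code, RSA to
one decimal with the published bold/buried flag, interaction tag and domain.
Spread columns depend on a 2014 sequence-database snapshot and are shipped
as historical data, never recomputed. Known discrepancies are carried in
`note` columns rather than silently resolved: the GRS Pro298Leu row is
absent from the mutation-list table but present in the feature table and the
14-mutation GRS census (kept); one ERS row is printed as Lys167Tyr in one
table and Cys167Tyr in another (the feature-table spelling is used); one RRS
row is printed as Trp421Arg where text and category table read Trp241Arg
(241 is used). A SHA-256 manifest guards the packaged files; load fails on
any mismatch. The packaged GRS query sequence is a synthetic stand-in
(correct length, correct wild-type residue at every curated mutation
position, deterministic filler elsewhere) — sufficient for validation and
mapping tests without shipping a database entry.

## Synthetic fixtures

Generators build poly-alanine backbones from internal coordinates (bonds
1.33/1.46/1.52 Å, ideal angles, ω = 180°): an ideal α-helix (φ/ψ −57/−47),
a β-hairpin (strands −139/135 with a type II′ turn), a translated two-helix
dimer whose minimum inter-chain distance is solved to the requested
separation (±0.1 Å), and a helix–ATP complex with an exact nearest-atom
pocket distance. MSAs are sampled i.i.d. per column from given symbol
distributions with a fixed seed. These fixtures exercise geometry, H-bond
patterns, contact logic and profile recovery, but they are idealised: no
side chains beyond Cβ, no crystallographic noise, no missing atoms or
alternate conformations, and no real evolutionary correlation structure —
passing tests demonstrate algorithmic correctness, not robustness to
real-data pathologies. Problem sizes in the tests and the acceptance script
(12-residue fixtures, 100 random contact structures, 10⁴ Monte-Carlo
samples per atom, 30 enumeration-checked alignment pairs) were chosen as the
smallest sizes at which each oracle is informative.

## Known limitations

* The contact rule is purely geometric; no interaction energies, hydrogen-
  bond geometry or buried-surface-area interface definitions.
* DSSP proper computes accessibility with a slice algorithm; areas here are
  Shrake–Rupley, so RSA values can differ from DSSP-derived ones by a few
  percentage points on top of the max-ASA table choice (the real-structure
  comparison targets ±3 points).
* The assigner omits π-helix as a separate class, β-bulges and PP-II.
* mmCIF input, NMR ensembles and symmetry-generated assemblies are not
  supported; dimers must be present in the coordinate file.
* Homologue discovery, structure superposition and MSA construction are
  upstream of the package: it consumes a provided structure and MSA.
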
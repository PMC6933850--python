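# Methods

This note documents the models, parameters and numerical choices behind
`pdblists`, and what the synthetic-fixture tests do and do not demonstrate
about real archive data.

## Coordinate model

Parsing of classic PDB and mmCIF is delegated to gemmi; the package layers
its own uniform model on top.  Alternate locations are collapsed to the
highest-occupancy alternate (ties broken by file order) — deterministic, and
it never changes the residue count.  The first MODEL is used for all derived
computations; multi-model entries are rejected by the acceptance gate
anyway, but diagnostics still need a model to look at.  Hydrogens are
ignored everywhere except H-bond evaluation, where the amide hydrogen is
always rebuilt (uniform behaviour across X-ray entries that mostly lack
hydrogens).  Occupancies are clamped to [0, 1].

Residues are classified as amino acid / nucleotide / water / ion / ligand /
unknown from a bundled component table; a residue is *intact* when every
heavy atom of the bundled reference topology for its name is present exactly
once (OXT and hydrogens ignored), and *Cα-only* when the α-carbon is the
only backbone heavy atom present.  UNK and other unknown names are "not
evaluable" and feed the unknown-topology penalty of the usability grade.

### Anomaly flags

Consecutive C(i)–N(i+1) distances above 5.0 Å are flagged as long bonds; the
peptide bond is ~1.33 Å and a chain break detected at 2.5 Å, so 5.0 Å
separates breaks from formatting damage cleanly.  If negating one coordinate
with magnitude above 9.999 restores a bondable distance, the flag is
upgraded to `lost_minus_sign` — the classic truncation where a coordinate
written with two characters before the decimal point drops its sign.
Deposited secondary-structure records are checked for intervals spanning
chains, byte-identical duplicates, and references to residues absent from
the coordinates.

## Torsions

Dihedrals use the cross-product/atan2 formulation, stable near 0° and 180°,
with the IUPAC sign convention; signs were verified against an independent
implementation (mdtraj) on fixture helices.  Note the IUPAC torsion is
*symmetric* under reading the four atoms backwards and changes sign under
mirror reflection.  φ/ψ/Ω follow the usual quadruples; Ω(i) is assigned to
residue i (the Cα(i−1)–C(i−1)–N(i)–Cα(i) angle), a convention this package
fixes and documents because output layouts differ on it.  Chain breaks
(C–N > 2.5 Å) and termini yield the sentinel −999.9, which is also the
rendered missing value in every output file.  χ1–χ5 atom quadruples ship as
data (YAML), not code, so they can be inspected or overridden; ARG defines
χ1–χ5, LYS χ1–χ4, GLY/ALA none.

## Secondary structure

The Kabsch–Sander cascade with the canonical constants: coupling
27.888 kcal·Å/mol, bond criterion E < −0.5 kcal/mol (configurable, to probe
cutoff sensitivity: a 0.02 Å change in an N–O distance can move one helix
end by one residue), energies clamped at −9.9, at most two partners per
donor and per acceptor, candidate pairs screened at Cα–Cα < 9 Å (the screen
is a superset of every bondable pair, so results equal the all-pairs
computation).  The amide hydrogen is placed 1.0 Å from N along the previous
residue's O→C direction; chain-starting residues and prolines never donate.
n-turns (n = 3, 4, 5) with two consecutive turns yield G/H/I; the two bridge
patterns yield parallel/antiparallel bridges; bridges in runs of at least
two form ladders and are labelled E, an isolated bridge stays B.  β-bulge
ladder fusion is deliberately not implemented: a simple sequence-gap
heuristic wrongly fuses the two strands of a hairpin across its turn
(the reference implementation assigns T there), and none of the fixtures
exercise true bulges.  Bend (S) uses the 70° kink of the
Cα(i−2)/Cα(i)/Cα(i+2) trace.  Priority: H > E/B > G > I > T > S.  Chains
shorter than three residues are all loop.  The reduced alphabet folds
G, I into H, keeps E as S(trand) and T, and sends B, S and blank to loop.
The rare "two helices fused by a shared H-bonding glycine" situation is not
special-cased; only manual annotation can resolve it.

On all bundled fixtures the assignment agrees residue-for-residue with
mdtraj's DSSP implementation (the suite requires ≥ 95% 8-state identity and
100% after reduction).

## Accessibility

Shrake–Rupley style sampling with a deterministic golden-spiral point set:
a point on the expanded sphere (vdW + probe) is buried when strictly inside
any neighbour's expanded sphere.  Defaults: probe 1.4 Å, 960 points per atom
(doubling the density changes fixture totals by < 1%).  vdW radii ship as
data (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80 Å, default 1.70).  Waters
never occlude.  `acc` is computed in protein-only context, `asa` in
full-entry context (ligands, ions and nucleic acids occlude); the two
databases must differ by *something*, and context is the one distinction
that is well-defined from coordinates alone — this reading is an explicit
design choice isolated behind the `variant` switch.  Translation invariance
is exact; rotation equivariance holds only to sampling resolution (the
point set is fixed in the laboratory frame), about 1% on totals at the
default density — a property shared by any fixed-grid sampler.

## Contacts

All distance-map cutoffs are strict (`< cutoff`) as printed in the database
definitions; bridge criteria use `≤`.  Sequence neighbours (i, i±1 on author
numbering within a chain) are excluded from the cc families — trivially-true
contacts carry no information for structure prediction; the exclusion width
is configurable.  "Residue spheres closer than X" is read as the surface gap
between the residues' smallest enclosing spheres (Welzl's algorithm, exact,
expanded so each atom's vdW sphere fits); this interpretation distinguishes
the sphere rows from the explicit atom-pair rows and is flagged here as an
interpretation.  Disulfides: SG–SG ≤ 2.5 Å, each SG in at most one bridge,
greedily matched by ascending distance.  Salt bridges: any acidic-O
(Asp OD1/OD2, Glu OE1/OE2, C-terminal OXT) to basic-N (Lys NZ,
Arg NE/NH1/NH2, N-terminal N, plus His ND1/NE2 when histidine is taken as
positive) pair ≤ 4.0 Å, one record per residue pair.  Ion contacts use a
bundled formal-charge table; `iod` reports the nearest *positive* ion per
residue.  Every family is contract-tested against a brute-force all-pairs
oracle on fuzzed fixtures.

## Acceptance gate and WHY_NOT

Checks run in fixed order, first failure wins: multi-model → not X-ray →
too many residues (> 10,000) → too few (< 30) → too few intact (< 25) →
too many bad residues → bad fraction > 20% → Cα-only fraction > 5%.
Database-specific preconditions run first (`cys`: no cysteines / no
bridges).  The numeric thresholds are configuration with the defaults above;
the reason strings are fixed verbatim (ASCII hyphens).  A rejection is a
value, not an error: it becomes a one-entry `.whynot` file (reason line,
then `DATABASE,entry`), and the invariant enforced by tests is that every
(entry, database) pair yields exactly one of data file or `.whynot` file.

## The usability grade

Base 10.0; administrative penalties: low resolution (> 3.0 Å, −2.0), longest
contiguous chain < 50 aa (−3.0), per-UNK −0.5 (cap 3.0), per-Cα-only −0.1
(cap 3.0), per-missing-atom-residue −0.05 (cap 3.0), per-unknown-component
−1.0 (cap 3.0).  Only if the subtotal is positive are the quality terms
evaluated: the Ramachandran term maps the favored-region fraction linearly
onto [0, 2.0] (regions ship as coarse rectangular φ/ψ masks for
general/Gly/Pro; fewer than 20 evaluable residues → 0, flagged), and the
packing term maps the deviation of the mean Cβ-within-8-Å neighbour count
from a reference mean (12.5 ± 4.0, measured on the compact globule fixture
family) onto [0, 2.0].  The final grade is clamped to [0.0, 10.0].  The
penalty sizes are configuration, not claims about any other program's
internals; the packing term is a neighbour-count proxy isolated behind an
interface so a full contact-based statistical potential could be plugged in.

## Homolog inclusion

The length-dependent identity threshold is max(290.15·L^−0.562, 25) + 5 —
the original homology-modelling curve with its 25% plateau, plus the 5
percentage points added over the full length, so no alignment below 30%
identity is ever accepted; additionally the alignment must cover more than
75% of the full sequence length.  Both comparisons are strict.

## Output formats

Per-residue lines carry five identifier columns (sequential number, residue
type, author number + insertion code, chain, reduced secondary structure)
then fixed-width 8.1f numerics; pair databases write both residues'
identifier columns and the distance/gap to two decimals; `ion` groups
contact lines under one header per ion; `sco` is one line per entry.
Missing numerics render as −999.9; non-intact residues render the literal
`Residue is not intact`.  Output is ASCII and byte-stable (same input →
identical bytes), and a bundled reader round-trips every written file.  The
entry summary is an indentation-structured key/value document (child keys
one space deep) with per-chain sequence and DSSP strings and helix/strand
fractions; fractions can be compressed to a 0–9 digit with
half-away-from-zero rounding.

## Synthetic fixtures

Chains are grown from internal coordinates (NeRF placement) with standard
backbone geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; angles
111.2/116.6/121.7°), so recovered torsions are exact self-consistency
checks.  Side-chain templates cover 18 amino-acid types (no Pro ring
closure, no Trp).  Kinds: ideal α-helix (−57/−47/180), β-hairpin
(strands −139/+135 with a tuned two-residue turn — a rigid flip-and-translate
of two twisted strands cannot satisfy the bridge H-bond patterns, a hairpin
can, and it is how antiparallel sheets actually occur), extended chain
(−120/+120), a cubic-lattice "globule" of alanines (4.7 Å spacing) for
packing and burial, disulfide and salt-bridge pairs with planted distances,
Zn/Cl ion sites, a small synthetic ligand at a planted vdW gap, multi-MODEL
ensembles, Cα-only traces, and the lost-minus-sign defect (helix shifted to
x < −9.999 with one residue's signs stripped).  Identical seeds give
byte-identical PDB text; noise jitters coordinates without changing
topology.

What fixtures do not show: real entries have heterogeneous B-factors and
occupancies, alternate conformers, chain gaps with annotation mismatches,
modified residues, and far messier metadata.  Passing the fixture suite
demonstrates algorithmic correctness (oracle equality, planted-truth
recovery, format stability), not robustness to every archive idiosyncrasy.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
contact-oracle checks use ≤ 64-residue models, SASA oracle checks compare
960 against 9,600 points per atom on ~135-atom clusters, and the grade fuzz
uses 10,000 randomized entry summaries.  These sizes were chosen so the
whole suite runs in well under a minute while every code path is exercised.
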
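# pdblists

Derived per-residue databases from macromolecular coordinate entries, for
protein structure bioinformatics (PSB) work that should not have to start
with yet another PDB parser.

Given a coordinate entry (classic PDB or mmCIF), the toolkit computes and
writes easy-to-parse flat files, one quantity per database:

| group | databases | content |
|---|---|---|
| geometry | `chi`, `tau` | backbone/side-chain torsions (φ, ψ, Ω, χ1–5), the N–Cα–C angle τ |
| accessibility | `acc`, `asa` | solvent-accessible area per residue (protein-only / full-entry context) |
| secondary structure | `dsp` | 8-state Kabsch–Sander assignment plus the reduced {H, S, T, loop} alphabet |
| contacts | `cc1`–`cc9`, `cli`, `cnu` | Cα/Cβ distance maps, van-der-Waals-gap bumps, residue-sphere proximities, ligand and nucleic-acid contacts |
| bridges & ions | `cys`, `sbr`, `sbh`, `iod`, `ion` | disulfides, salt bridges (optionally protonated His), residue–ion distances |
| selection | `sco` | a 0.0–10.0 "bioinformatics usability" grade per entry |

Entries that are useless for automated studies (multi-model, non-X-ray, too
small, too broken, Cα-only, ...) are rejected by a fixed-order acceptance
gate; every rejection leaves a `.whynot` file with a verbatim machine-readable
reason, so that for every (entry, database) pair exactly one artifact exists.

The secondary-structure assignment implements the Kabsch–Sander cascade: the
electrostatic H-bond proxy energy

    E = 27.888 · (1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN))  kcal/mol

(with the amide hydrogen rebuilt from the preceding C=O), a bond below
−0.5 kcal/mol, n-turns → 3₁₀/α/π helices, bridge patterns → ladders/sheets,
and bend detection on the Cα trace.  The usability grade starts at 10.0,
subtracts administrative penalties (resolution worse than 3.0 Å, longest
chain < 50 aa, UNK / Cα-only / incomplete residues, unknown components) and,
only if the subtotal stays positive, adds Ramachandran and packing quality
terms before clamping to [0, 10] — Dutch school grading, 6.0 is just a pass.

Everything is testable offline: a fixture generator grows synthetic entries
from internal coordinates (ideal helices, β-hairpins, disulfide and
salt-bridge pairs, ion/ligand sites, Cα-only traces, multi-model ensembles,
and the classic "lost minus sign" coordinate-truncation defect) together
with ground-truth sidecars.

## Worked example

```sh
$ python - <<'EOF'
from pdblists.fixtures import FixtureSpec, build_fixture
from pathlib import Path
fx = build_fixture(FixtureSpec("ideal_helix", length=60, noise=0.02, seed=7))
Path("1hlx.pdb").write_text(fx.pdb_text)
EOF
$ pdblists derive --db chi,acc,sco --in 1hlx.pdb --out lists
$ head -4 lists/chi/1hlx.chi
#ID 1hlx
   1  ALA      1  A     -999.9   -48.9  -999.9  -999.9  -999.9  -999.9  -999.9  -999.9
   2  ALA      2  A  H   -53.0   -52.1   179.2  -999.9  -999.9  -999.9  -999.9  -999.9
   3  ALA      3  A  H   -55.9   -47.4  -178.1  -999.9  -999.9  -999.9  -999.9  -999.9
```

Columns: sequential residue number, residue type, author residue number,
chain, reduced secondary structure, then φ, ψ, Ω, χ1–χ5 in degrees.  The
N-terminal residue has no φ/Ω (sentinel −999.9), interior residues recover
the planted helix torsions (−57, −47, 180) up to the 0.02 Å jitter, and
alanine has no rotatable side chain, so all χ columns are −999.9.  A residue
with missing side-chain atoms would print `Residue is not intact` instead of
values.

```sh
$ pdblists score --in 1hlx.pdb
1hlx 10.0
  bonus packing +0.79
  bonus ramachandran +2.00
```

No administrative penalty fires (2.0 Å resolution, one intact 60-residue
chain), every φ/ψ pair sits in the favored helical region (full +2.0), and
the helix is thinner than a well-packed globular core, so the packing term
adds only +0.79; the grade clamps at 10.0.

Rejections are values, not errors:

```sh
$ pdblists derive --db chi --in multi_model.pdb --out lists
$ cat lists/chi/nmr0.whynot
COMMENT: MODEL records found
CHI,nmr0
```

Other commands: `pdblists ssdiff` (diff the computed assignment against
deposited HELIX/SHEET records), `pdblists whynot --report <dir>` (aggregate
rejection reasons), `pdblists fixtures --suite <dir>` (write the synthetic
fixture suite).

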
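"""Reading coordinate entries into a uniform in-memory model.

Parsing of classic PDB and mmCIF is delegated to :mod:`gemmi`; on top of that
this module collapses alternate locations, classifies residues
(amino acid / nucleotide / water / ion / ligand), checks side-chain
intactness against the bundled reference topology, and flags known archive
pathologies such as deposited secondary-structure records that span chains
and the classic "lost minus sign" coordinate truncation that shows up as
absurdly long backbone bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import chemdata

MISSING = -999.9

#: consecutive C(i)-N(i+1) distance beyond which a bond is "long" and a
#: sign-loss candidate; a peptide bond is ~1.33 A, a sign-stripped
#: coordinate shifts an atom by >= ~20 A.
LONG_BOND_THRESHOLD = 5.0

#: C(i)-N(i+1) distance beyond which the chain is considered broken for
#: torsion and secondary-structure purposes.
CHAIN_BREAK_THRESHOLD = 2.5


class StructureError(Exception):
    """Problem reading or interpreting a coordinate entry."""


class EmptyEntryError(StructureError):
    """The source contained no ATOM/HETATM records."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    alt_loc: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    vdw_radius: float = 1.70

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Residue:
    name: str
    seq_num: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    category: str = "unknown"
    intact: bool = False
    ca_only: bool = False
    missing_atoms: list[str] = field(default_factory=list)
    unknown_topology: bool = False
    #: 1-based sequential index within the chain (set after parsing)
    seq_index: int = 0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.position

    def heavy_atom_names(self) -> set[str]:
        return {a.name for a in self.atoms if not a.is_hydrogen}

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name} {self.seq_num}{self.icode}".rstrip()

    def __hash__(self) -> int:  # identity semantics; residues are mutable
        return id(self)

    def __eq__(self, other) -> bool:
        return self is other


@dataclass
class SSInterval:
    """One deposited HELIX or SHEET interval, retained verbatim for diffing."""

    kind: str               # 'helix' or 'sheet'
    chain_start: str
    start_seq: int
    start_icode: str
    chain_end: str
    end_seq: int
    end_icode: str
    ss_class: int = 1

    def key(self) -> tuple:
        return (self.kind, self.chain_start, self.start_seq, self.start_icode,
                self.chain_end, self.end_seq, self.end_icode, self.ss_class)

    def normalized(self) -> "SSInterval":
        if (self.chain_start == self.chain_end
                and (self.start_seq, self.start_icode) > (self.end_seq, self.end_icode)):
            return SSInterval(self.kind, self.chain_end, self.end_seq,
                              self.end_icode, self.chain_start, self.start_seq,
                              self.start_icode, self.ss_class)
        return self


@dataclass
class AnomalyFlag:
    kind: str     # lost_minus_sign | long_bond | cross_chain_ss | duplicate_ss | ss_for_missing_residue
    locus: str
    detail: str = ""


@dataclass
class StructureEntry:
    entry_id: str
    models: list[list[Residue]]
    experiment_method: str = ""
    resolution: float | None = None
    helix_records: list[SSInterval] = field(default_factory=list)
    sheet_records: list[SSInterval] = field(default_factory=list)
    anomalies: list[AnomalyFlag] = field(default_factory=list)
    parse_errors: list[str] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def first_model(self) -> list[Residue]:
        return self.models[0]

    def chains(self, model_index: int = 0) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for res in self.models[model_index]:
            out.setdefault(res.chain_id, []).append(res)
        return out


# ---------------------------------------------------------------------------
# classification / intactness

def classify_residue(residue: Residue) -> str:
    """Assign one of amino_acid/nucleotide/water/ion/ligand/unknown."""
    name = residue.name.upper()
    if name in chemdata.AMINO_ACID_LIKE:
        return "amino_acid"
    if name in chemdata.WATER_NAMES:
        return "water"
    heavy = [a for a in residue.atoms if not a.is_hydrogen]
    if name in chemdata.ion_charges() and len(heavy) == 1:
        return "ion"
    if name in chemdata.NUCLEOTIDES:
        return "nucleotide"
    if residue.atoms:
        return "ligand"
    return "unknown"


def check_intact(residue: Residue) -> tuple[bool, list[str], bool]:
    """Compare heavy atoms against the reference topology.

    Returns ``(intact, missing_atoms, ca_only)``.  OXT and hydrogens are
    ignored.  Unknown residue names (e.g. UNK) are not evaluable and are
    reported as unknown topology.
    """
    present = residue.heavy_atom_names() - {"OXT"}
    backbone_present = present & {"N", "C", "O"}
    ca_only = "CA" in present and not backbone_present
    topo = chemdata.residue_topology().get(residue.name.upper())
    if topo is None:
        residue.unknown_topology = True
        return False, [], ca_only
    missing = [a for a in topo if a not in present]
    return (not missing), missing, ca_only


def _finalize_residue(res: Residue) -> None:
    res.category = classify_residue(res)
    if res.category == "amino_acid":
        res.intact, res.missing_atoms, res.ca_only = check_intact(res)
    for a in res.atoms:
        a.vdw_radius = chemdata.vdw_radius(a.element or "C")
        a.occupancy = min(1.0, max(0.0, a.occupancy))


# ---------------------------------------------------------------------------
# reading

def _collapse_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep, per atom name, the highest-occupancy alternate (ties: first)."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def _from_gemmi(st: gemmi.Structure, entry_id: str | None = None) -> StructureEntry:
    models: list[list[Residue]] = []
    for model in st:
        residues: list[Residue] = []
        for chain in model:
            idx = 0
            for gres in chain:
                atoms = [
                    Atom(serial=a.serial, name=a.name,
                         element=a.element.name.upper(),
                         alt_loc=a.altloc if a.altloc != "\x00" else "",
                         position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                         occupancy=a.occ, b_factor=a.b_iso)
                    for a in gres
                ]
                res = Residue(name=gres.name, seq_num=gres.seqid.num,
                              icode=gres.seqid.icode.strip(), chain_id=chain.name,
                              atoms=_collapse_altlocs(atoms))
                idx += 1
                res.seq_index = idx
                _finalize_residue(res)
                residues.append(res)
        models.append(residues)
    if not models or not any(m for m in models):
        raise EmptyEntryError("no ATOM/HETATM records found")

    helices = []
    for h in st.helices:
        helices.append(SSInterval(
            "helix", h.start.chain_name, h.start.res_id.seqid.num,
            h.start.res_id.seqid.icode.strip(), h.end.chain_name,
            h.end.res_id.seqid.num, h.end.res_id.seqid.icode.strip(),
            getattr(h.pdb_helix_class, "value", 1) or 1))
    sheets = []
    for sh in st.sheets:
        for strand in sh.strands:
            sheets.append(SSInterval(
                "sheet", strand.start.chain_name, strand.start.res_id.seqid.num,
                strand.start.res_id.seqid.icode.strip(), strand.end.chain_name,
                strand.end.res_id.seqid.num, strand.end.res_id.seqid.icode.strip()))

    method = st.info["_exptl.method"] if "_exptl.method" in st.info else ""
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    eid = entry_id or st.info["_entry.id"].lower() if "_entry.id" in st.info \
        else entry_id or "xxxx"
    if not eid or eid == "string":
        eid = "xxxx"
    return StructureEntry(entry_id=eid, models=models,
                          experiment_method=method, resolution=resolution,
                          helix_records=[h.normalized() for h in helices],
                          sheet_records=[s.normalized() for s in sheets])


def _sniff_dialect(text: str) -> str:
    head = text[:20000]
    if "_atom_site." in head or head.lstrip().startswith("data_"):
        return "mmcif"
    return "pdb"


def read_structure(source, dialect: str = "auto") -> StructureEntry:
    """Read a PDB or mmCIF coordinate file (path or text) into a StructureEntry.

    ``dialect='auto'`` sniffs by content.  Alt-locs are collapsed to the
    highest-occupancy alternate; metadata (method, resolution) is populated
    when present; deposited HELIX/SHEET intervals are retained for diffing.
    """
    entry_id = None
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        if not path.exists():
            raise StructureError(f"cannot read {source}")
        entry_id = path.stem.lower()
        text = path.read_text()
    elif isinstance(source, bytes):
        text = source.decode()
    elif hasattr(source, "read"):
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    else:
        text = str(source)

    if dialect == "auto":
        dialect = _sniff_dialect(text)
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb_string(text)
        elif dialect == "mmcif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        else:
            raise StructureError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"unparseable {dialect} input: {exc}") from exc
    st.setup_entities()
    entry = _from_gemmi(st, entry_id)
    entry.anomalies = detect_anomalies(entry)
    return entry


# ---------------------------------------------------------------------------
# anomaly detection

def _sign_fix_recovers(c_pos: np.ndarray, n_pos: np.ndarray) -> bool:
    """Would negating one coordinate with |value| > 9.999 restore the bond?"""
    for pos, other in ((c_pos, n_pos), (n_pos, c_pos)):
        for k in range(3):
            if pos[k] > 9.999:
                fixed = pos.copy()
                fixed[k] = -fixed[k]
                if np.linalg.norm(fixed - other) < CHAIN_BREAK_THRESHOLD:
                    return True
    return False


def detect_anomalies(entry: StructureEntry) -> list[AnomalyFlag]:
    flags: list[AnomalyFlag] = []

    # (a) long backbone bonds / lost-minus-sign candidates
    for chain_id, residues in entry.chains(0).items():
        aa = [r for r in residues if r.category == "amino_acid"]
        for r1, r2 in zip(aa, aa[1:]):
            if r2.seq_num - r1.seq_num != 1 and not (
                    r2.seq_num == r1.seq_num and r2.icode != r1.icode):
                continue  # numbering gap: a genuine missing stretch, not a bond
            c, n = r1.coord("C"), r2.coord("N")
            if c is None or n is None:
                continue
            d = float(np.linalg.norm(c - n))
            if d > LONG_BOND_THRESHOLD:
                kind = ("lost_minus_sign" if _sign_fix_recovers(c, n)
                        else "long_bond")
                flags.append(AnomalyFlag(
                    kind, locus=f"{r1.label}..{r2.label}",
                    detail=f"C-N bond {d:.2f} A"))

    # (b) deposited SS spanning chains, (c) duplicates, (d) missing residues
    present = {(r.chain_id, r.seq_num, r.icode) for r in entry.first_model}
    seen: set[tuple] = set()
    for iv in entry.helix_records + entry.sheet_records:
        locus = (f"{iv.kind} {iv.chain_start}{iv.start_seq}"
                 f"-{iv.chain_end}{iv.end_seq}")
        if iv.chain_start != iv.chain_end:
            flags.append(AnomalyFlag("cross_chain_ss", locus,
                                     "interval spans multiple chains"))
        if iv.key() in seen:
            flags.append(AnomalyFlag("duplicate_ss", locus,
                                     "byte-identical deposited record"))
        seen.add(iv.key())
        for chain, seq, icode in ((iv.chain_start, iv.start_seq, iv.start_icode),
                                  (iv.chain_end, iv.end_seq, iv.end_icode)):
            if (chain, seq, icode) not in present:
                flags.append(AnomalyFlag(
                    "ss_for_missing_residue", locus,
                    f"residue {chain}{seq}{icode} absent from coordinates"))
    return flags


# ---------------------------------------------------------------------------
# writing (normalized PDB, used by the fixture generator and round-trips)

def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16; element right-justified in 13-14 for 1-letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(entry: StructureEntry) -> str:
    """Serialize an entry back to classic PDB text (normalized subset)."""
    lines: list[str] = []
    lines.append(f"HEADER    {'SYNTHETIC FIXTURE':<40s}"
                 f"01-JAN-00   {entry.entry_id.upper()[:4]:<4s}")
    if entry.experiment_method:
        lines.append(f"EXPDTA    {entry.experiment_method}")
    if entry.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {entry.resolution:7.2f} ANGSTROMS.")
    for i, h in enumerate(entry.helix_records, start=1):
        length = h.end_seq - h.start_seq + 1
        lines.append(
            f"HELIX  {i:3d} {i:3d} {'RES':>3s} {h.chain_start:1s} "
            f"{h.start_seq:4d}{h.start_icode or ' '} {'RES':>3s} "
            f"{h.chain_end:1s} {h.end_seq:4d}{h.end_icode or ' '}"
            f"{h.ss_class:2d}{'':30s}{length:6d}")
    for i, s in enumerate(entry.sheet_records, start=1):
        lines.append(
            f"SHEET  {i:3d}   A 1 {'RES':>3s} {s.chain_start:1s}"
            f"{s.start_seq:4d}{s.start_icode or ' '} {'RES':>3s} "
            f"{s.chain_end:1s}{s.end_seq:4d}{s.end_icode or ' '}  0")
    multi = entry.n_models > 1
    serial = 0
    for m_idx, model in enumerate(entry.models, start=1):
        if multi:
            lines.append(f"MODEL     {m_idx:4d}")
        last_chain = None
        for res in model:
            record = "ATOM  " if res.category == "amino_acid" else "HETATM"
            if res.category in ("water", "ion", "ligand", "nucleotide",
                                "unknown") and res.name in chemdata.AMINO_ACIDS_3:
                record = "ATOM  "
            if last_chain is not None and res.chain_id != last_chain:
                lines.append("TER")
            last_chain = res.chain_id
            for a in res.atoms:
                serial += 1
                x, y, z = a.position
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(a.name, a.element)}"
                    f"{a.alt_loc or ' '}{res.name:>3s} {res.chain_id:1s}"
                    f"{res.seq_num:4d}{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}"
                    f"{a.b_factor:6.2f}          {a.element:>2s}")
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
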
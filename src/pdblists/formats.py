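"""Writers (and a round-trip reader) for the per-residue record layout, the
key/value entry summary, and WHY_NOT files.

Per-residue lines carry five identifier columns — sequential residue number,
residue type, author residue number, chain, reduced secondary structure —
followed by the database's numeric fields (angles in degrees, areas in A^2,
distances in A).  Missing numerics render as -999.9; residues that are not
completely intact render the literal text "Residue is not intact" instead of
values.  Output is ASCII and bit-stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .structure_io import MISSING, Residue, StructureEntry
from . import chemdata
from .selection_scoring import WhyNotRecord

#: databases handled by the toolkit
DATABASES = ("chi", "tau", "acc", "asa", "dsp",
             "cc1", "cc2", "cc3", "cc4", "cc5", "cc6", "cc7", "cc8", "cc9",
             "cli", "cnu", "iod", "ion", "cys", "sbr", "sbh", "sco")

PER_RESIDUE_DBS = {"chi": 8, "tau": 1, "acc": 1, "asa": 1, "iod": 1}
PAIR_DBS = {"cc1", "cc2", "cc3", "cc4", "cc5", "cc6", "cc7", "cc8", "cc9",
            "cli", "cnu", "cys", "sbr", "sbh"}

NOT_INTACT_TEXT = "Residue is not intact"


@dataclass
class DerivedRecord:
    seq_index: int
    res_name: str
    author_num: str          # author number + insertion code
    chain_id: str
    reduced_ss: str
    values: list[float] = field(default_factory=list)
    not_intact: bool = False
    text_values: list[str] = field(default_factory=list)


def record_for(residue: Residue, reduced_ss: str = " ",
               values=(), not_intact: bool | None = None,
               text_values=()) -> DerivedRecord:
    return DerivedRecord(
        seq_index=residue.seq_index,
        res_name=residue.name,
        author_num=f"{residue.seq_num}{residue.icode}",
        chain_id=residue.chain_id,
        reduced_ss=reduced_ss,
        values=list(values),
        not_intact=(not residue.intact) if not_intact is None else not_intact,
        text_values=list(text_values))


def _id_cols(rec: DerivedRecord) -> str:
    return (f"{rec.seq_index:4d} {rec.res_name:>4s} {rec.author_num:>6s} "
            f"{rec.chain_id:>2s}  {rec.reduced_ss:1s}")


def _fmt_value(v: float) -> str:
    return f"{v:8.1f}"


def write_lists(database_name: str, entry_id: str, records) -> str:
    """Serialize one entry's records for one database to fixed-width text."""
    if database_name not in DATABASES:
        raise ValueError(f"unknown Lists database {database_name!r}")
    lines = [f"#ID {entry_id}"]
    if database_name in PER_RESIDUE_DBS or database_name == "dsp":
        for rec in records:
            head = _id_cols(rec)
            if rec.not_intact:
                lines.append(f"{head}  {NOT_INTACT_TEXT}")
            elif database_name == "dsp":
                lines.append(f"{head}  {rec.text_values[0]:1s}")
            else:
                lines.append(head + "".join(_fmt_value(v)
                                            for v in rec.values))
    elif database_name in PAIR_DBS:
        # records: iterable of (DerivedRecord, DerivedRecord, metric)
        for rec_a, rec_b, metric in records:
            lines.append(f"{_id_cols(rec_a)}   {_id_cols(rec_b)} "
                         f"{metric:8.2f}")
    elif database_name == "ion":
        # records: iterable of (ion_label, [(DerivedRecord, distance), ...])
        for ion_label, hits in records:
            lines.append(f"ION {ion_label}")
            for rec, d in hits:
                lines.append(f" {_id_cols(rec)} {d:8.2f}")
    elif database_name == "sco":
        for eid, score in records:
            lines.append(f"{eid} {score:.1f}")
    return "\n".join(lines) + "\n"


def read_lists(database_name: str, text: str):
    """Parse a written Lists document back (round-trip contract)."""
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#ID")]

    def parse_id(chunk: str):
        return DerivedRecord(
            seq_index=int(chunk[0:4]), res_name=chunk[5:9].strip(),
            author_num=chunk[10:16].strip(), chain_id=chunk[17:19].strip(),
            reduced_ss=chunk[21:22])

    out = []
    if database_name in PER_RESIDUE_DBS or database_name == "dsp":
        for ln in lines:
            rec = parse_id(ln)
            rest = ln[22:]
            if NOT_INTACT_TEXT in rest:
                rec.not_intact = True
            elif database_name == "dsp":
                rec.text_values = [rest[2:3] or " "]
            else:
                rec.values = [float(rest[i:i + 8])
                              for i in range(0, len(rest.rstrip("\n")), 8)
                              if rest[i:i + 8].strip()]
            out.append(rec)
    elif database_name in PAIR_DBS:
        for ln in lines:
            a = parse_id(ln[0:22])
            b = parse_id(ln[25:47])
            out.append((a, b, float(ln[47:56])))
    elif database_name == "sco":
        for ln in lines:
            eid, score = ln.rsplit(" ", 1)
            out.append((eid, float(score)))
    elif database_name == "ion":
        current = None
        for ln in lines:
            if ln.startswith("ION "):
                current = (ln[4:].strip(), [])
                out.append(current)
            else:
                current[1].append((parse_id(ln[1:23]), float(ln[24:32])))
    return out


# ---------------------------------------------------------------------------
# entry summary (key/value, child keys indented one step)

def scale_to_digit(value: float) -> int:
    """Map a fraction in [0, 1] to the nearest integer on a 0..9 scale,
    rounding halves away from zero."""
    if not (0.0 <= value <= 1.0):
        raise ValueError("value must lie in [0, 1]")
    return int(math.floor(value * 9.0 + 0.5))


def write_pdbfinder(entry: StructureEntry, annotation=None) -> str:
    """Key/value summary of one entry (metadata + per-chain derived strings)."""
    lines = [f"ID           : {entry.entry_id.upper()}"]
    if entry.experiment_method:
        lines.append(f"Exp-Method   : {entry.experiment_method}")
    if entry.resolution is not None:
        lines.append(f"Resolution   : {entry.resolution:.2f}")
    for chain_id, residues in entry.chains(0).items():
        aa = [r for r in residues if r.category == "amino_acid"]
        if not aa:
            continue
        seq = "".join(chemdata.THREE_TO_ONE.get(r.name.upper(), "X")
                      for r in aa)
        lines.append(f"Chain        : {chain_id}")
        lines.append(f" Amino-Acids : {len(aa)}")
        lines.append(f" Sequence    : {seq}")
        if annotation is not None:
            states = [annotation.states[annotation.residues.index(r)]
                      if r in annotation.residues else " " for r in aa]
            dssp = "".join(states)
            lines.append(f" DSSP        : {dssp}")
            n = len(states)
            helix_frac = sum(s in "HGI" for s in states) / n
            sheet_frac = sum(s == "E" for s in states) / n
            lines.append(f" T-Frac-Helix: {helix_frac:.2f}")
            lines.append(f" T-Frac-Sheet: {sheet_frac:.2f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# WHY_NOT files

def write_whynot(record: WhyNotRecord) -> str:
    """One rejection file: the verbatim reason, then DATABASE,entry."""
    return (f"{record.reason}\n"
            f"{record.database_name.upper()},{record.entry_id}\n")
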
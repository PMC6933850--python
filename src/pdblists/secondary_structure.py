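"""Kabsch-Sander secondary-structure assignment and annotation diffing.

The assignment follows the classic cascade: backbone H-bonds are scored with
the electrostatic proxy energy

    E = 27.888 * (1/r(ON) + 1/r(CH) - 1/r(OH) - 1/r(CN))   [kcal/mol]

with the amide hydrogen rebuilt from the previous residue's C=O direction; a
bond exists below -0.5 kcal/mol.  n-turns (n = 3, 4, 5) yield 3-10/alpha/pi
helices from two consecutive turns, the two bridge H-bond patterns yield
parallel/antiparallel bridges, ladders and sheets (E) or isolated bridges
(B), unextended turns give T and a >70 degree Calpha kink gives S.

The reduced 4-letter alphabet folds 3-10 and pi helices into H, keeps
H-bonded strands as S(trand), keeps T, and calls everything else (including
isolated bridges) loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import angle, is_bonded
from .structure_io import Residue, SSInterval, StructureEntry

#: f * q1 * q2 in kcal*A/mol for the Kabsch-Sander electrostatic model
HB_COUPLING = 27.888
#: a hydrogen bond exists below this energy
HB_CUTOFF = -0.5
#: energies are clamped below at this floor
HB_FLOOR = -9.9
#: Calpha kink angle above which a bend (S) is assigned
BEND_THRESHOLD = 70.0
#: donor/acceptor pairs farther apart than this (Calpha) are not evaluated
CA_SCREEN = 9.0

N_H_BOND = 1.0  # length of the rebuilt N-H bond, A

REDUCTION = {"H": "H", "G": "H", "I": "H", "E": "S", "B": " ",
             "T": "T", "S": " ", " ": " "}


@dataclass
class HBond:
    donor: int      # indices into the assignment's residue list
    acceptor: int
    energy: float


@dataclass
class SSAnnotation:
    residues: list[Residue]
    states: list[str]                 # 8-state, one per residue
    reduced: list[str] = field(default_factory=list)
    source: str = "computed"
    hbonds: list[HBond] = field(default_factory=list)

    def state_of(self, residue: Residue) -> str:
        return self.states[self.residues.index(residue)]

    def string(self, chain_id: str | None = None) -> str:
        return "".join(
            s for r, s in zip(self.residues, self.states)
            if chain_id is None or r.chain_id == chain_id)


@dataclass
class HelixDiff:
    helix_id: int
    n_term_delta: int
    c_term_delta: int


def reduce_alphabet(states) -> list[str]:
    """Fold the 8-state alphabet to {H, S, T, ' '}."""
    out = []
    for s in states:
        if s not in REDUCTION:
            raise ValueError(f"unknown secondary-structure symbol {s!r}")
        out.append(REDUCTION[s])
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds

def hbond_energy(donor: Residue, acceptor: Residue,
                 h_position: np.ndarray | None = None) -> float | None:
    """Kabsch-Sander N-H...O=C energy in kcal/mol, or None if not evaluable.

    ``h_position`` is the rebuilt amide hydrogen of the donor; if omitted the
    donor must carry an H atom (rare in X-ray entries, so callers normally
    reconstruct it).
    """
    n = donor.coord("N")
    c, o = acceptor.coord("C"), acceptor.coord("O")
    h = h_position if h_position is not None else donor.coord("H")
    if n is None or c is None or o is None or h is None:
        return None
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
        return None
    e = HB_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, HB_FLOOR)


def _protein_residues(model: list[Residue]) -> list[Residue]:
    return [r for r in model
            if r.category == "amino_acid"
            and r.coord("N") is not None and r.coord("CA") is not None
            and r.coord("C") is not None and r.coord("O") is not None]


def _rebuild_hydrogens(residues, prev_bonded) -> list[np.ndarray | None]:
    """Amide H = N + unit(O_prev -> C_prev); PRO and chain starts never donate."""
    hs: list[np.ndarray | None] = []
    for i, res in enumerate(residues):
        if res.name == "PRO" or prev_bonded[i] is None:
            hs.append(None)
            continue
        prev = residues[prev_bonded[i]]
        c, o = prev.coord("C"), prev.coord("O")
        v = c - o
        hs.append(res.coord("N") + v / np.linalg.norm(v) * N_H_BOND)
    return hs


def compute_hbonds(residues: list[Residue],
                   cutoff: float = HB_CUTOFF) -> tuple[dict, list[HBond]]:
    """All backbone H-bonds below ``cutoff``.

    Returns ``(bond_set, bonds)`` where ``bond_set`` maps
    (acceptor_index, donor_index) -> energy, keeping at most the two best
    acceptors per donor and two best donors per acceptor.
    """
    n = len(residues)
    prev_bonded: list[int | None] = [None] * n
    for i in range(1, n):
        if (residues[i - 1].chain_id == residues[i].chain_id
                and is_bonded(residues[i - 1], residues[i])):
            prev_bonded[i] = i - 1
    hs = _rebuild_hydrogens(residues, prev_bonded)
    cas = np.array([r.coord("CA") for r in residues])

    candidates: list[HBond] = []
    from scipy.spatial import cKDTree
    tree = cKDTree(cas)
    for i, j in tree.query_pairs(CA_SCREEN):
        for acc, don in ((i, j), (j, i)):
            if hs[don] is None or don == acc:
                continue
            e = hbond_energy(residues[don], residues[acc], hs[don])
            if e is not None and e < cutoff:
                candidates.append(HBond(donor=don, acceptor=acc, energy=e))

    # keep the two best partners on each side
    by_donor: dict[int, list[HBond]] = {}
    by_acceptor: dict[int, list[HBond]] = {}
    for hb in sorted(candidates, key=lambda b: b.energy):
        d_list = by_donor.setdefault(hb.donor, [])
        a_list = by_acceptor.setdefault(hb.acceptor, [])
        if len(d_list) < 2 and len(a_list) < 2:
            d_list.append(hb)
            a_list.append(hb)
    kept = [hb for lst in by_donor.values() for hb in lst]
    bond_set = {(hb.acceptor, hb.donor): hb.energy for hb in kept}
    return bond_set, kept


# ---------------------------------------------------------------------------
# the assignment cascade

def assign_secondary_structure(model: list[Residue],
                               cutoff: float = HB_CUTOFF) -> SSAnnotation:
    """Assign 8-state secondary structure to the protein residues of a model.

    Residues lacking a full backbone (including Ca-only stretches) are
    reported as loop.  Priority: H > B/E > G > I > T > S.
    """
    residues = _protein_residues(model)
    n = len(residues)
    all_protein = [r for r in model if r.category == "amino_acid"]

    if n < 3:
        ann_states = {id(r): " " for r in residues}
        states = [ann_states.get(id(r), " ") for r in all_protein]
        return SSAnnotation(all_protein, states,
                            reduce_alphabet(states), "computed", [])

    bond_set, bonds = compute_hbonds(residues, cutoff)

    def hbond(i: int, j: int) -> bool:
        """CO of residue i accepts from NH of residue j."""
        return (i, j) in bond_set

    # chain continuity between sequence-adjacent residues
    contig = [residues[i].chain_id == residues[i + 1].chain_id
              and is_bonded(residues[i], residues[i + 1])
              for i in range(n - 1)]

    def no_break(i: int, j: int) -> bool:
        return 0 <= i and j < n and all(contig[k] for k in range(i, j))

    # n-turns: CO(i) -> NH(i+n)
    turn = {m: [False] * n for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(n - m):
            if no_break(i, i + m) and hbond(i, i + m):
                turn[m][i] = True

    # minimal helices: two consecutive turns
    helix = {m: [False] * n for m in (3, 4, 5)}
    for m in (3, 4, 5):
        for i in range(1, n - m):
            if turn[m][i - 1] and turn[m][i]:
                for k in range(i, i + m):
                    helix[m][k] = True

    # bridges
    parallel = [[] for _ in range(n)]
    antiparallel = [[] for _ in range(n)]
    bridge_partner: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if not (no_break(i - 1, i + 1) and no_break(j - 1, j + 1)):
                continue
            if ((hbond(i - 1, j) and hbond(j, i + 1))
                    or (hbond(j - 1, i) and hbond(i, j + 1))):
                bridge_partner[i].append((j, "P"))
                bridge_partner[j].append((i, "P"))
            if ((hbond(i, j) and hbond(j, i))
                    or (hbond(i - 1, j + 1) and hbond(j - 1, i + 1))):
                bridge_partner[i].append((j, "A"))
                bridge_partner[j].append((i, "A"))

    # ladders: consecutive bridges of the same type; single bridge -> B
    in_ladder = [False] * n
    is_bridge = [bool(bridge_partner[i]) for i in range(n)]
    for i in range(n):
        for j, kind in bridge_partner[i]:
            if j < i:
                continue
            nxt = j + 1 if kind == "P" else j - 1
            if i + 1 < n and (nxt, kind) in bridge_partner[i + 1]:
                for k in (i, i + 1, j, nxt):
                    in_ladder[k] = True

    # residues in ladders (>= 2 consecutive bridges) are strand (E);
    # a lone bridge stays B
    extended = in_ladder

    # turns (T): interior residues of an unextended n-turn
    is_turn = [False] * n
    for m in (3, 4, 5):
        for i in range(n - m):
            if turn[m][i]:
                for k in range(i + 1, i + m):
                    is_turn[k] = True

    # bends (S): kink of the Calpha trace
    is_bend = [False] * n
    for i in range(2, n - 2):
        if no_break(i - 2, i + 2):
            v1 = residues[i].coord("CA") - residues[i - 2].coord("CA")
            v2 = residues[i + 2].coord("CA") - residues[i].coord("CA")
            try:
                kink = angle(residues[i - 2].coord("CA") + v2,
                             residues[i - 2].coord("CA"),
                             residues[i - 2].coord("CA") + v1)
            except ValueError:
                continue
            if kink > BEND_THRESHOLD:
                is_bend[i] = True

    states_core = []
    for i in range(n):
        if helix[4][i]:
            s = "H"
        elif extended[i]:
            s = "E"
        elif is_bridge[i]:
            s = "B"
        elif helix[3][i]:
            s = "G"
        elif helix[5][i]:
            s = "I"
        elif is_turn[i]:
            s = "T"
        elif is_bend[i]:
            s = "S"
        else:
            s = " "
        states_core.append(s)

    by_id = {id(r): s for r, s in zip(residues, states_core)}
    states = [by_id.get(id(r), " ") for r in all_protein]
    return SSAnnotation(all_protein, states, reduce_alphabet(states),
                        "computed", bonds)


# ---------------------------------------------------------------------------
# run extraction and diffing against deposited annotations

def _runs(residues, states, symbols) -> list[tuple[int, int]]:
    """Maximal [start, end] index runs whose state is in ``symbols``."""
    runs = []
    start = None
    for i, s in enumerate(states):
        same_chain = (start is not None and
                      residues[i].chain_id == residues[start].chain_id)
        if s in symbols and start is None:
            start = i
        elif start is not None and (s not in symbols or not same_chain):
            runs.append((start, i - 1))
            start = i if s in symbols else None
    if start is not None:
        runs.append((start, len(states) - 1))
    return runs


def _interval_indices(annotation: SSAnnotation, iv: SSInterval) -> list[int]:
    out = []
    for idx, r in enumerate(annotation.residues):
        if r.chain_id != iv.chain_start:
            continue
        if ((iv.start_seq, iv.start_icode) <= (r.seq_num, r.icode)
                <= (iv.end_seq, iv.end_icode or "~")):
            out.append(idx)
    return out


def diff_deposited(entry: StructureEntry, computed: SSAnnotation) -> dict:
    """Compare deposited HELIX/SHEET intervals against a computed assignment.

    Returns overassigned-helix and unassigned-strand residue counts plus
    per-helix N-/C-end deltas (negative delta: computed run is shorter).
    """
    helix_states = {"H", "G", "I"}
    overassigned = 0
    missing_ss = 0
    helix_diffs: list[HelixDiff] = []
    for hid, iv in enumerate(entry.helix_records, start=1):
        idxs = _interval_indices(computed, iv)
        if not idxs:
            missing_ss += 1
            continue
        overassigned += sum(1 for i in idxs
                            if computed.states[i] not in helix_states)
        runs = _runs(computed.residues, computed.states, helix_states)
        overlap = [(s, e) for s, e in runs
                   if s <= idxs[-1] and e >= idxs[0]
                   and computed.residues[s].chain_id == iv.chain_start]
        if overlap:
            s, e = max(overlap, key=lambda r: min(r[1], idxs[-1]) - max(r[0], idxs[0]))
            helix_diffs.append(HelixDiff(hid, n_term_delta=idxs[0] - s,
                                         c_term_delta=e - idxs[-1]))
        else:
            helix_diffs.append(HelixDiff(hid, 0, 0))

    sheet_covered = set()
    for iv in entry.sheet_records:
        sheet_covered.update(_interval_indices(computed, iv))
    unassigned_strand = sum(1 for i, s in enumerate(computed.states)
                            if s == "E" and i not in sheet_covered)
    return {"overassigned_helix_count": overassigned,
            "unassigned_strand_count": unassigned_strand,
            "helix_diffs": helix_diffs,
            "ss_for_missing_residues": missing_ss}


def helix_end_comparison(annotation_a: SSAnnotation, annotation_b: SSAnnotation,
                         min_length: int = 6) -> dict:
    """Tally N-/C-end length differences of helices between two annotations.

    For every helix of at least ``min_length`` residues in ``annotation_b``,
    the overlapping helix (H/G/I run) in ``annotation_a`` is found and the
    signed end deltas are tallied in bins |delta| in {0, 1, 2, 3, >3},
    split by direction (a longer / a shorter).  Unmatched helices are counted.
    """
    helix_states = {"H", "G", "I"}
    runs_a = _runs(annotation_a.residues, annotation_a.states, helix_states)
    runs_b = [r for r in _runs(annotation_b.residues, annotation_b.states,
                               helix_states)
              if r[1] - r[0] + 1 >= min_length]
    bins = {"0": 0, "1": 0, "2": 0, "3": 0, ">3": 0}
    tallies = {"n_term": {"longer": dict(bins), "shorter": dict(bins)},
               "c_term": {"longer": dict(bins), "shorter": dict(bins)},
               "unmatched": 0, "compared": 0}

    def _bin(delta: int) -> str:
        return str(abs(delta)) if abs(delta) <= 3 else ">3"

    for sb, eb in runs_b:
        overlaps = [(sa, ea) for sa, ea in runs_a if sa <= eb and ea >= sb]
        if not overlaps:
            tallies["unmatched"] += 1
            continue
        sa, ea = max(overlaps, key=lambda r: min(r[1], eb) - max(r[0], sb))
        tallies["compared"] += 1
        # positive: annotation_a extends further than annotation_b
        n_delta = sb - sa
        c_delta = ea - eb
        for delta, term in ((n_delta, "n_term"), (c_delta, "c_term")):
            if delta == 0:
                tallies[term]["longer"]["0"] += 0  # zero deltas counted below
                tallies[term]["shorter"]["0"] += 0
            side = "longer" if delta > 0 else "shorter"
            if delta == 0:
                tallies[term]["longer"]["0"] += 1
            else:
                tallies[term][side][_bin(delta)] += 1
    return tallies
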
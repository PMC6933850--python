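"""Pairwise-contact databases: CA/CB distance maps, vdW-gap bumps,
residue-sphere proximities, ligand and nucleic-acid contacts, disulfide and
salt bridges, and residue-ion distances.

All Table-style cutoffs are strict ("< cutoff"); bridge criteria use "<=".
Sequence neighbours (i, i+-1 within a chain) are excluded from the cc
families.  The production path may use spatial indexing but is contractually
equal to the all-pairs computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chemdata
from .structure_io import MISSING, Residue

log = logging.getLogger(__name__)

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

CC_FAMILIES = {
    # family: (kind, parameters)
    "cc1": ("point", {"atom_name": "CA", "cutoff": 12.5}),
    "cc2": ("gap", {"scope": "residue_sphere", "gap_cutoff": 0.25}),
    "cc3": ("gap", {"scope": "residue_sphere", "gap_cutoff": 2.5}),
    "cc4": ("gap", {"scope": "any_atom", "gap_cutoff": 0.25}),
    "cc5": ("gap", {"scope": "any_atom", "gap_cutoff": 2.5}),
    "cc6": ("gap", {"scope": "sidechain_atom", "gap_cutoff": 0.25}),
    "cc7": ("gap", {"scope": "sidechain_atom", "gap_cutoff": 2.5}),
    "cc8": ("gap", {"scope": "sidechain_atom", "gap_cutoff": 2.5,
                    "interchain_only": True}),
    "cc9": ("point", {"atom_name": "CB", "cutoff": 12.5}),
}

DISULFIDE_CUTOFF = 2.5
SALT_BRIDGE_CUTOFF = 4.0
ION_SHORT_CUTOFF = 4.0

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
HIS_BASIC_ATOMS = ("ND1", "NE2")


@dataclass
class ContactPair:
    residue_a: Residue
    residue_b: Residue
    metric: float
    family: str


@dataclass
class BridgeRecord:
    kind: str  # disulfide | salt_bridge | salt_bridge_his
    residue_a: Residue
    residue_b: Residue
    distance: float


@dataclass
class IonContact:
    residue: Residue
    ion: Residue
    distance: float


# ---------------------------------------------------------------------------
# helpers

def protein_residues(model: list[Residue]) -> list[Residue]:
    return [r for r in model if r.category == "amino_acid"]


def _are_sequence_neighbors(a: Residue, b: Residue,
                            exclusion: int = 1) -> bool:
    """i, i+-exclusion within a chain, judged on author numbering."""
    return (a.chain_id == b.chain_id
            and abs(a.seq_num - b.seq_num) <= exclusion)


def enclosing_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing sphere (Welzl's algorithm)."""
    pts = [np.asarray(p, dtype=float) for p in points]

    def sphere_from(boundary):
        if not boundary:
            return np.zeros(3), 0.0
        if len(boundary) == 1:
            return boundary[0], 0.0
        if len(boundary) == 2:
            c = (boundary[0] + boundary[1]) / 2.0
            return c, float(np.linalg.norm(boundary[0] - c))
        # 3 or 4 points: solve |x - p_i|^2 equal via linear system
        p0 = boundary[0]
        a_rows, b_vals = [], []
        for p in boundary[1:]:
            a_rows.append(2.0 * (p - p0))
            b_vals.append(np.dot(p, p) - np.dot(p0, p0))
        a = np.array(a_rows)
        b = np.array(b_vals)
        try:
            c, *_ = np.linalg.lstsq(a, b, rcond=None)
        except np.linalg.LinAlgError:
            return p0, 0.0
        return c, float(np.linalg.norm(p0 - c))

    def welzl(p, boundary):
        if not p or len(boundary) == 4:
            return sphere_from(boundary)
        q = p[0]
        c, r = welzl(p[1:], boundary)
        if np.linalg.norm(q - c) <= r + 1e-9:
            return c, r
        return welzl(p[1:], boundary + [q])

    import random
    rnd = random.Random(0)
    pts_shuffled = pts[:]
    rnd.shuffle(pts_shuffled)
    return welzl(pts_shuffled, [])


def residue_sphere(residue: Residue) -> tuple[np.ndarray, float]:
    """Smallest sphere enclosing the residue's heavy-atom vdW spheres."""
    heavy = [a for a in residue.atoms if not a.is_hydrogen]
    center, r = enclosing_sphere(np.array([a.position for a in heavy]))
    # expand so every atom's vdW sphere fits
    r = max(float(np.linalg.norm(a.position - center)) + a.vdw_radius
            for a in heavy)
    return center, r


def _scoped_atoms(residue: Residue, scope: str):
    heavy = [a for a in residue.atoms if not a.is_hydrogen]
    if scope == "any_atom":
        return heavy
    if scope == "sidechain_atom":
        return [a for a in heavy if a.name not in BACKBONE_NAMES]
    raise ValueError(f"unknown scope {scope!r}")


def _min_vdw_gap(atoms_a, atoms_b) -> float:
    pa = np.array([a.position for a in atoms_a])
    pb = np.array([a.position for a in atoms_b])
    ra = np.array([a.vdw_radius for a in atoms_a])
    rb = np.array([a.vdw_radius for a in atoms_b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    gaps = d - ra[:, None] - rb[None, :]
    return float(gaps.min())


# ---------------------------------------------------------------------------
# cc families

def point_contacts(model: list[Residue], atom_name: str = "CA",
                   cutoff: float = 12.5, exclusion: int = 1,
                   family: str | None = None) -> list[ContactPair]:
    """CA-CA (cc1) or CB-CB (cc9) center-distance contacts below ``cutoff``."""
    residues = [r for r in protein_residues(model)
                if r.coord(atom_name) is not None
                and not (atom_name == "CB" and r.name == "GLY")]
    family = family or ("cc1" if atom_name == "CA" else "cc9")
    coords = np.array([r.coord(atom_name) for r in residues])
    out = []
    for i in range(len(residues)):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        for off in np.nonzero(d < cutoff)[0]:
            j = i + 1 + off
            if _are_sequence_neighbors(residues[i], residues[j], exclusion):
                continue
            out.append(ContactPair(residues[i], residues[j], float(d[off]),
                                   family))
    return out


def gap_contacts(model: list[Residue], scope: str, gap_cutoff: float,
                 interchain_only: bool = False, exclusion: int = 1,
                 family: str | None = None) -> list[ContactPair]:
    """vdW-gap (or enclosing-sphere-gap) contacts below ``gap_cutoff``."""
    residues = protein_residues(model)
    family = family or scope
    if scope == "residue_sphere":
        spheres = [residue_sphere(r) if r.atoms else None for r in residues]
    out = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            a, b = residues[i], residues[j]
            if interchain_only and a.chain_id == b.chain_id:
                continue
            if _are_sequence_neighbors(a, b, exclusion):
                continue
            if scope == "residue_sphere":
                (ca, ra), (cb, rb) = spheres[i], spheres[j]
                gap = float(np.linalg.norm(ca - cb)) - ra - rb
            else:
                atoms_a = _scoped_atoms(a, scope)
                atoms_b = _scoped_atoms(b, scope)
                if not atoms_a or not atoms_b:
                    continue
                gap = _min_vdw_gap(atoms_a, atoms_b)
            if gap < gap_cutoff:
                out.append(ContactPair(a, b, gap, family))
    return out


def cc_family(model: list[Residue], family: str,
              exclusion: int = 1) -> list[ContactPair]:
    """Dispatch one of the cc1..cc9 contact families."""
    kind, params = CC_FAMILIES[family]
    if kind == "point":
        return point_contacts(model, exclusion=exclusion, family=family,
                              **params)
    return gap_contacts(model, exclusion=exclusion, family=family, **params)


# ---------------------------------------------------------------------------
# hetero contacts

def hetero_contacts(model: list[Residue], partner_category: str,
                    gap_cutoff: float = 1.0) -> list[ContactPair]:
    """Residues near ligands (vdW atom gap, 'cli') or nucleic acids
    (enclosing-sphere gap, 'cnu')."""
    residues = protein_residues(model)
    partners = [r for r in model if r.category == partner_category]
    family = "cli" if partner_category == "ligand" else "cnu"
    out = []
    for res in residues:
        best, best_partner = None, None
        for p in partners:
            if partner_category == "nucleotide":
                (c1, r1) = residue_sphere(res)
                (c2, r2) = residue_sphere(p)
                gap = float(np.linalg.norm(c1 - c2)) - r1 - r2
            else:
                atoms_a = [a for a in res.atoms if not a.is_hydrogen]
                atoms_b = [a for a in p.atoms if not a.is_hydrogen]
                gap = _min_vdw_gap(atoms_a, atoms_b)
            if best is None or gap < best:
                best, best_partner = gap, p
        if best is not None and best < gap_cutoff:
            out.append(ContactPair(res, best_partner, best, family))
    return out


# ---------------------------------------------------------------------------
# bridges

def cys_bridges(model: list[Residue],
                cutoff: float = DISULFIDE_CUTOFF) -> list[BridgeRecord]:
    """Disulfide bridges: SG-SG <= cutoff, each SG in at most one bridge
    (greedy by ascending distance)."""
    cys = []
    for r in protein_residues(model):
        if r.name != "CYS":
            continue
        if r.coord("SG") is None:
            log.warning("CYS %s lacks SG; skipped for bridge search", r.label)
            continue
        cys.append(r)
    pairs = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = float(np.linalg.norm(cys[i].coord("SG") - cys[j].coord("SG")))
            if d <= cutoff:
                pairs.append((d, cys[i], cys[j]))
    pairs.sort(key=lambda t: t[0])
    used: set[int] = set()
    out = []
    for d, a, b in pairs:
        if id(a) in used or id(b) in used:
            continue
        used.update((id(a), id(b)))
        out.append(BridgeRecord("disulfide", a, b, d))
    return out


def _charged_atoms(residues, his_positive: bool):
    acidic, basic = [], []
    for i, r in enumerate(residues):
        for name in ACIDIC_ATOMS.get(r.name, ()):
            a = r.atom(name)
            if a is not None:
                acidic.append((r, a))
        oxt = r.atom("OXT")
        if oxt is not None:
            acidic.append((r, oxt))
        for name in BASIC_ATOMS.get(r.name, ()):
            a = r.atom(name)
            if a is not None:
                basic.append((r, a))
        if his_positive and r.name == "HIS":
            for name in HIS_BASIC_ATOMS:
                a = r.atom(name)
                if a is not None:
                    basic.append((r, a))
        # N-terminal amine: first residue of each chain
        if i == 0 or residues[i - 1].chain_id != r.chain_id:
            a = r.atom("N")
            if a is not None:
                basic.append((r, a))
    return acidic, basic


def salt_bridges(model: list[Residue], his_positive: bool = False,
                 cutoff: float = SALT_BRIDGE_CUTOFF) -> list[BridgeRecord]:
    """Salt bridges: any acidic-O / basic-N pair <= cutoff; one record per
    residue pair.  ``his_positive`` adds HIS ND1/NE2 to the basic set."""
    residues = protein_residues(model)
    acidic, basic = _charged_atoms(residues, his_positive)
    kind = "salt_bridge_his" if his_positive else "salt_bridge"
    best: dict[tuple[int, int], tuple[float, Residue, Residue]] = {}
    for ra, aa in acidic:
        for rb, ab in basic:
            if ra is rb:
                continue
            d = float(np.linalg.norm(aa.position - ab.position))
            if d <= cutoff:
                key = tuple(sorted((id(ra), id(rb))))
                if key not in best or d < best[key][0]:
                    best[key] = (d, ra, rb)
    return [BridgeRecord(kind, ra, rb, d) for d, ra, rb in best.values()]


# ---------------------------------------------------------------------------
# ions

def ion_contacts(model: list[Residue],
                 short_cutoff: float = ION_SHORT_CUTOFF) -> dict:
    """Residue-ion proximity.

    Returns ``{"iod": {residue: distance-to-nearest-positive-ion or MISSING},
    "ion": {ion residue: [IonContact...]}}``.
    """
    residues = protein_residues(model)
    ions = [r for r in model if r.category == "ion"]
    charges = chemdata.ion_charges()
    positive = [r for r in ions if charges.get(r.name.upper(), 0) > 0]

    iod: dict[Residue, float] = {}
    for res in residues:
        pos = np.array([a.position for a in res.atoms if not a.is_hydrogen])
        best = MISSING
        for ion in positive:
            d = float(np.linalg.norm(pos - ion.atoms[0].position,
                                     axis=1).min())
            if best == MISSING or d < best:
                best = d
        iod[res] = best

    grouped: dict[Residue, list[IonContact]] = {}
    for ion in ions:
        hits = []
        for res in residues:
            pos = np.array([a.position for a in res.atoms if not a.is_hydrogen])
            d = float(np.linalg.norm(pos - ion.atoms[0].position, axis=1).min())
            if d <= short_cutoff:
                hits.append(IonContact(res, ion, d))
        grouped[ion] = sorted(hits, key=lambda c: c.distance)
    return {"iod": iod, "ion": grouped}
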
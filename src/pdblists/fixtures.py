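"""Programmatic synthetic coordinate fixtures.

Chains are grown from internal coordinates (NeRF-style) with standard bond
geometry (N-CA 1.458, CA-C 1.525, C-N 1.329 A; angles 111.2/116.6/121.7 deg),
so planted torsions are recovered exactly by the geometry module on
zero-noise fixtures.  Each fixture is emitted as classic PDB text plus a
ground-truth sidecar recording what was planted (torsions, expected
secondary-structure runs, bridges, contacts, defects).

Same spec + seed always yields byte-identical PDB text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Atom, Residue, SSInterval, StructureEntry, write_pdb

# backbone internal coordinates
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.6, 121.7, 120.8

HELIX_PHI, HELIX_PSI, HELIX_OMEGA = -57.0, -47.0, 180.0
STRAND_PHI, STRAND_PSI = -120.0, 120.0

# Antiparallel-sheet fixture: a beta hairpin with near-ideal antiparallel
# strand torsions and a two-residue turn whose torsions were chosen so the
# inter-strand H-bond ladder forms cleanly.
SHEET_PHI, SHEET_PSI = -139.0, 135.0
SHEET_TURN = ((60.0, 20.0), (140.0, -20.0))

KINDS = (
    "ideal_helix", "ideal_sheet", "extended_chain", "globule",
    "disulfide_pair", "salt_bridge_pair", "ion_site", "ligand_site",
    "multi_model", "ca_only_chain", "lost_minus_sign", "mixed_cohort",
)


@dataclass
class FixtureSpec:
    kind: str
    length: int = 12
    noise: float = 0.0
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class Fixture:
    spec: FixtureSpec
    entry_id: str
    pdb_text: str
    truth: dict


class FixtureError(ValueError):
    """Unsatisfiable fixture specification."""


# ---------------------------------------------------------------------------
# NeRF atom placement

def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Place a new atom at the given internal coordinates relative to a-b-c.

    The new atom D satisfies |D-c| = bond, angle(b,c,D) = angle_deg and
    dihedral(a,b,c,D) = torsion_deg under the IUPAC sign convention.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(tau),
                  bond * math.sin(theta) * math.sin(tau)])
    return c + d[0] * bc + d[1] * m + d[2] * n


# Side-chain templates: atom -> (ref_a, ref_b, ref_c, bond, angle, torsion).
# A torsion may be a number or ("chi", k, offset) meaning chi_k + offset.
_SC = {
    "ALA": [],
    "GLY": None,  # no CB
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi", 1, 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi", 1, 0.0))],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, 120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.527, 110.5, ("chi", 1, -122.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi", 1, 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi", 1, -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.9, ("chi", 2, 0.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi", 2, 122.0))],
    "MET": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi", 3, 0.0))],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 0.0)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi", 2, 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi", 1, 0.0)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi", 2, 0.0)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi", 2, 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 0.0)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi", 3, 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi", 2, 0.0)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi", 3, 0.0)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi", 3, 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi", 3, 0.0)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi", 4, 0.0))],
    "ARG": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi", 1, 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi", 2, 0.0)),
            ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi", 3, 0.0)),
            ("CZ", "CG", "CD", "NE", 1.329, 124.2, ("chi", 4, 0.0)),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, ("chi", 5, 0.0)),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, ("chi", 5, 180.0))],
    "HIS": [("CG", "N", "CA", "CB", 1.497, 113.8, ("chi", 1, 0.0)),
            ("ND1", "CA", "CB", "CG", 1.378, 122.7, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.354, 129.7, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.321, 109.0, 180.0),
            ("NE2", "CG", "ND1", "CE1", 1.321, 108.5, 0.0)],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.382, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi", 1, 0.0)),
            ("CD1", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 0.0)),
            ("CD2", "CA", "CB", "CG", 1.384, 120.8, ("chi", 2, 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.382, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.382, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.382, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.376, 119.9, 180.0)],
}

DEFAULT_CHI = 180.0


def _resolve_torsion(spec, chi: dict[int, float]) -> float:
    if isinstance(spec, tuple):
        _, k, offset = spec
        return chi.get(k, DEFAULT_CHI) + offset
    return float(spec)


def build_chain(sequence: list[str], phi: list[float], psi: list[float],
                omega: list[float], chi: dict[int, float] | None = None,
                chain_id: str = "A", start_seq: int = 1,
                ca_only: bool = False) -> list[Residue]:
    """Grow a peptide chain from internal coordinates.

    ``phi[0]`` and ``omega[0]`` are unused (no preceding residue); ``psi`` of
    the last residue only orients its carbonyl oxygen.
    """
    n = len(sequence)
    if n < 1:
        raise FixtureError("need at least one residue")
    chi = chi or {}
    coords: list[dict[str, np.ndarray]] = []
    for i, name in enumerate(sequence):
        if name not in _SC and name != "GLY":
            raise FixtureError(f"no side-chain template for {name}")
        pos: dict[str, np.ndarray] = {}
        if i == 0:
            pos["N"] = np.zeros(3)
            pos["CA"] = np.array([B_N_CA, 0.0, 0.0])
            t = math.radians(A_N_CA_C)
            pos["C"] = pos["CA"] + B_CA_C * np.array([-math.cos(t), math.sin(t), 0.0])
        else:
            prev = coords[i - 1]
            pos["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                  B_C_N, A_CA_C_N, psi[i - 1])
            pos["CA"] = place_atom(prev["CA"], prev["C"], pos["N"],
                                   B_N_CA, A_C_N_CA, omega[i])
            pos["C"] = place_atom(prev["C"], pos["N"], pos["CA"],
                                  B_CA_C, A_N_CA_C, phi[i])
        pos["O"] = place_atom(pos["N"], pos["CA"], pos["C"],
                              B_C_O, A_CA_C_O, psi[i] + 180.0)
        if name != "GLY":
            pos["CB"] = place_atom(pos["C"], pos["N"], pos["CA"],
                                   1.530, 110.4, 122.5)
            for aname, ra, rb, rc, bond, ang, tors in _SC[name]:
                pos[aname] = place_atom(pos[ra], pos[rb], pos[rc], bond, ang,
                                        _resolve_torsion(tors, chi))
        coords.append(pos)

    residues = []
    for i, (name, pos) in enumerate(zip(sequence, coords)):
        atoms = []
        for aname, xyz in pos.items():
            if ca_only and aname != "CA":
                continue
            atoms.append(Atom(serial=0, name=aname, element=aname[0],
                              alt_loc="", position=xyz))
        res = Residue(name=name, seq_num=start_seq + i, icode="",
                      chain_id=chain_id, atoms=atoms, seq_index=i + 1)
        residues.append(res)
    return residues


def _jitter(residues: list[Residue], noise: float, rng: np.random.Generator):
    if noise <= 0:
        return
    for res in residues:
        for a in res.atoms:
            a.position = a.position + rng.normal(0.0, noise, 3)


def _transform(residues: list[Residue], rot: np.ndarray | None = None,
               shift=(0.0, 0.0, 0.0)) -> None:
    shift = np.asarray(shift, dtype=float)
    for res in residues:
        for a in res.atoms:
            p = a.position
            if rot is not None:
                p = rot @ p
            a.position = p + shift


def _rot(axis: str, deg: float) -> np.ndarray:
    t = math.radians(deg)
    c, s = math.cos(t), math.sin(t)
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def _finalize(residues):
    from .structure_io import _finalize_residue
    for r in residues:
        _finalize_residue(r)
    return residues


def _entry(entry_id: str, models: list[list[Residue]],
           method: str = "X-RAY DIFFRACTION", resolution: float | None = 2.0,
           helix_records=(), sheet_records=()) -> StructureEntry:
    for model in models:
        _finalize(model)
    return StructureEntry(entry_id=entry_id, models=models,
                          experiment_method=method, resolution=resolution,
                          helix_records=list(helix_records),
                          sheet_records=list(sheet_records))


def _hetero_residue(name: str, chain: str, seq: int,
                    atoms: list[tuple[str, str, np.ndarray]]) -> Residue:
    return Residue(name=name, seq_num=seq, icode="", chain_id=chain,
                   atoms=[Atom(serial=0, name=an, element=el, alt_loc="",
                               position=np.asarray(p, dtype=float))
                          for an, el, p in atoms])


# ---------------------------------------------------------------------------
# fixture kinds

def _helix_chain(length, chain_id="A", start_seq=1, sequence=None,
                 ca_only=False):
    seq = sequence or ["ALA"] * length
    n = len(seq)
    return build_chain(seq, [HELIX_PHI] * n, [HELIX_PSI] * n,
                       [HELIX_OMEGA] * n, chain_id=chain_id,
                       start_seq=start_seq, ca_only=ca_only)


def _strand_chain(length, chain_id="A", start_seq=1):
    return build_chain(["ALA"] * length, [STRAND_PHI] * length,
                       [STRAND_PSI] * length, [180.0] * length,
                       chain_id=chain_id, start_seq=start_seq)


def _build_ideal_helix(spec, rng):
    res = _helix_chain(spec.length)
    _jitter(res, spec.noise, rng)
    helices = []
    dep = spec.params.get("deposited_helix")
    if dep:
        helices.append(SSInterval("helix", "A", dep[0], "", "A", dep[1], ""))
    entry = _entry(f"hlx{spec.seed % 10}", [res], helix_records=helices,
                   method=spec.params.get("method", "X-RAY DIFFRACTION"),
                   resolution=spec.params.get("resolution", 2.0))
    truth = {"phi": HELIX_PHI, "psi": HELIX_PSI, "omega": HELIX_OMEGA,
             "expected_ss_interior": "H",
             "interior_range": (2, spec.length - 2)}
    return entry, truth


def _build_ideal_sheet(spec, rng):
    length = spec.length
    n = 2 * length + 2
    phi, psi = [SHEET_PHI] * n, [SHEET_PSI] * n
    phi[length], psi[length] = SHEET_TURN[0]
    phi[length + 1], psi[length + 1] = SHEET_TURN[1]
    res = build_chain(["ALA"] * n, phi, psi, [180.0] * n)
    _jitter(res, spec.noise, rng)
    entry = _entry(f"sht{spec.seed % 10}", [res])
    truth = {"phi": SHEET_PHI, "psi": SHEET_PSI,
             "expected_ss_interior": "E", "strand_length": length,
             "strand1": (1, length), "strand2": (length + 3, n)}
    return entry, truth


def _build_extended_chain(spec, rng):
    res = _strand_chain(spec.length)
    _jitter(res, spec.noise, rng)
    return _entry(f"ext{spec.seed % 10}", [res]), {"expected_ss": "no E no B"}


def _build_globule(spec, rng):
    side = max(2, round(spec.length ** (1.0 / 3.0)))
    spacing = spec.params.get("spacing", 4.7)
    residues = []
    seq = 1
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                r = build_chain(["ALA"], [0.0], [120.0], [180.0],
                                start_seq=seq)[0]
                r.chain_id = "A"
                shift = spacing * np.array([ix, iy, iz], dtype=float)
                for a in r.atoms:
                    a.position = a.position + shift
                residues.append(r)
                seq += 1
    _jitter(residues, spec.noise, rng)
    center_index = (side // 2) * (side * side + side + 1)
    entry = _entry(f"glb{spec.seed % 10}", [residues])
    return entry, {"n_residues": side ** 3, "buried_index": center_index,
                   "spacing": spacing}


def _two_group_fixture(res_a, res_b, anchor_a, anchor_b, distance):
    """Place res_b so that atom anchor_b sits `distance` from anchor_a along
    the direction pointing away from res_a's backbone."""
    pa = res_a.coord(anchor_a)
    u = pa - res_a.coord("CA")
    u = u / np.linalg.norm(u)
    _transform([res_b], rot=_rot("z", 180.0))
    pb = res_b.coord(anchor_b)
    _transform([res_b], shift=pa + distance * u - pb)
    return [res_a, res_b]


def _build_disulfide_pair(spec, rng):
    c1 = build_chain(["CYS"], [0.0], [120.0], [180.0], {1: -60.0},
                     start_seq=1)[0]
    c2 = build_chain(["CYS"], [0.0], [120.0], [180.0], {1: -60.0},
                     start_seq=10)[0]
    d = spec.params.get("sg_distance", 2.05)
    residues = _two_group_fixture(c1, c2, "SG", "SG", d)
    _jitter(residues, spec.noise, rng)
    entry = _entry(f"ssb{spec.seed % 10}", [residues])
    truth = {"bridges": [(1, 10)] if d <= 2.5 else [], "sg_distance": d}
    return entry, truth


def _build_salt_bridge_pair(spec, rng):
    acidic = spec.params.get("acidic", "ASP")
    basic = spec.params.get("basic", "LYS")
    d = spec.params.get("distance", 3.0)
    r1 = build_chain([acidic], [0.0], [120.0], [180.0], start_seq=1)[0]
    r2 = build_chain([basic], [0.0], [120.0], [180.0], start_seq=10)[0]
    acid_atom = {"ASP": "OD1", "GLU": "OE1"}[acidic]
    base_atom = {"LYS": "NZ", "ARG": "NH1", "HIS": "NE2"}[basic]
    residues = _two_group_fixture(r1, r2, acid_atom, base_atom, d)
    _jitter(residues, spec.noise, rng)
    entry = _entry(f"slt{spec.seed % 10}", [residues])
    truth = {"pair": (1, 10), "distance": d, "acidic": acidic, "basic": basic,
             "requires_his_positive": basic == "HIS"}
    return entry, truth


def _build_ion_site(spec, rng):
    his = build_chain(["HIS"], [0.0], [120.0], [180.0], start_seq=1)[0]
    ne2 = his.coord("NE2")
    u = ne2 - his.coord("CA")
    u = u / np.linalg.norm(u)
    d = spec.params.get("distance", 2.1)
    zn = _hetero_residue("ZN", "A", 101, [("ZN", "ZN", ne2 + d * u)])
    residues = [his, zn]
    if spec.params.get("with_chloride", True):
        cl = _hetero_residue("CL", "A", 102,
                             [("CL", "CL", ne2 + np.array([0.0, 0.0, 8.0]))])
        residues.append(cl)
    _jitter([residues[0]], spec.noise, rng)
    entry = _entry(f"ion{spec.seed % 10}", [residues])
    return entry, {"ion": "ZN", "his_distance": d}


def _build_ligand_site(spec, rng):
    lys = build_chain(["LYS"], [0.0], [120.0], [180.0], start_seq=1)[0]
    nz = lys.coord("NZ")
    u = nz - lys.coord("CA")
    u = u / np.linalg.norm(u)
    gap = spec.params.get("gap", 0.5)
    # vdW radii: N 1.55, C 1.70 -> center distance = gap + 3.25
    base = nz + (1.55 + 1.70 + gap) * u
    # further ligand atoms strictly on the far side, so the planted NZ-C1
    # gap is the minimum over all atom pairs
    lig = _hetero_residue("LIG", "A", 201, [
        ("C1", "C", base),
        ("C2", "C", base + 1.5 * u),
        ("O1", "O", base + 1.2 * u + 0.8 * np.cross(u, [0.0, 0.0, 1.0])),
    ])
    entry = _entry(f"lig{spec.seed % 10}", [[lys, lig]])
    return entry, {"gap": gap, "ligand": "LIG"}


def _build_multi_model(spec, rng):
    m1 = _helix_chain(spec.length)
    m2 = _helix_chain(spec.length)
    _jitter(m2, max(spec.noise, 0.1), rng)
    entry = _entry(f"nmr{spec.seed % 10}", [m1, m2],
                   method=spec.params.get("method", "X-RAY DIFFRACTION"),
                   resolution=spec.params.get("resolution", 2.0))
    return entry, {"n_models": 2}


def _build_ca_only(spec, rng):
    res = _helix_chain(spec.length, ca_only=True)
    _jitter(res, spec.noise, rng)
    return _entry(f"cao{spec.seed % 10}", [res]), {"ca_only": spec.length}


def _build_lost_minus_sign(spec, rng):
    res = _helix_chain(spec.length)
    # shift the helix into x < 0 so that several coordinates drop below
    # -9.999, then strip the minus sign on one residue (the Fig-style
    # two-characters-before-the-decimal truncation)
    _transform(res, shift=(-16.0, 0.0, 0.0))
    k = spec.params.get("defect_index", spec.length // 2)
    for a in res[k].atoms:
        if a.position[0] < -9.999:
            a.position[0] = abs(a.position[0])
    entry = _entry(f"lms{spec.seed % 10}", [res])
    return entry, {"defect_residue": res[k].seq_num}


_BUILDERS = {
    "ideal_helix": _build_ideal_helix,
    "ideal_sheet": _build_ideal_sheet,
    "extended_chain": _build_extended_chain,
    "globule": _build_globule,
    "disulfide_pair": _build_disulfide_pair,
    "salt_bridge_pair": _build_salt_bridge_pair,
    "ion_site": _build_ion_site,
    "ligand_site": _build_ligand_site,
    "multi_model": _build_multi_model,
    "ca_only_chain": _build_ca_only,
    "lost_minus_sign": _build_lost_minus_sign,
}


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Build one synthetic entry; returns PDB text plus the planted truth."""
    if spec.length < 1 or spec.noise < 0:
        raise FixtureError("length must be >= 1 and noise >= 0")
    if spec.kind == "mixed_cohort":
        raise FixtureError("use build_cohort() for mixed_cohort")
    try:
        builder = _BUILDERS[spec.kind]
    except KeyError:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}") from None
    rng = np.random.default_rng(spec.seed)
    entry, truth = builder(spec, rng)
    if "entry_id" in spec.params:
        entry.entry_id = spec.params["entry_id"]
    truth["kind"] = spec.kind
    truth["seed"] = spec.seed
    return Fixture(spec=spec, entry_id=entry.entry_id,
                   pdb_text=write_pdb(entry), truth=truth)


def truth_to_text(truth: dict) -> str:
    """Serialize a ground-truth sidecar as simple key/value text."""
    lines = []
    for key in sorted(truth):
        lines.append(f"{key}: {truth[key]!r}")
    return "\n".join(lines) + "\n"


def random_entry_summaries(n: int, seed: int = 0):
    """Randomized entry summaries spanning all penalty and bonus combinations.

    Used to fuzz the usability grade: resolutions from excellent to poor,
    chain lengths across the short-chain threshold, UNK / Ca-only /
    missing-atom / unknown-component counts from zero upward, and
    Ramachandran/packing inputs across their full ranges.
    """
    from .selection_scoring import EntrySummary
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        n_res = int(rng.integers(1, 400))
        out.append(EntrySummary(
            entry_id="fuzz",
            n_models=1,
            experiment_method="X-RAY DIFFRACTION",
            resolution=float(rng.uniform(0.8, 6.0)) if rng.random() < 0.9
            else None,
            n_residues=n_res,
            n_intact=int(rng.integers(0, n_res + 1)),
            n_ca_only=int(rng.integers(0, 60)) if rng.random() < 0.5 else 0,
            n_unk=int(rng.integers(0, 15)) if rng.random() < 0.5 else 0,
            n_missing_atom_residues=int(rng.integers(0, 120))
            if rng.random() < 0.5 else 0,
            n_unknown_components=int(rng.integers(0, 8))
            if rng.random() < 0.5 else 0,
            longest_chain=int(rng.integers(1, 400)),
            rama_fraction=float(rng.uniform(0.0, 1.0)),
            n_rama_residues=int(rng.integers(0, n_res + 1)),
            neighbor_counts=list(rng.integers(
                0, 25, int(rng.integers(0, 120)))),
        ))
    return out


# ---------------------------------------------------------------------------
# cohorts

def build_cohort(n: int, seed: int = 0) -> list[Fixture]:
    """A mixed cohort of n entries spanning accepted and rejected kinds.

    Entries cycle through clean helices/sheets, multi-model entries,
    non-X-ray entries, short peptides, Ca-only traces and disulfide pairs so
    that acceptance bookkeeping can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    out: list[Fixture] = []
    recipes = [
        ("clean_helix", None), ("clean_sheet", None), ("multi_model", None),
        ("nmr", None), ("short", None), ("ca_only", None), ("disulfide", None),
    ]
    for i in range(n):
        kind, _ = recipes[i % len(recipes)]
        sub = int(rng.integers(0, 2 ** 31 - 1))
        eid = f"s{i:03d}"
        if kind == "clean_helix":
            fx = build_fixture(FixtureSpec("ideal_helix", length=60,
                                           noise=0.02, seed=sub,
                                           params={"entry_id": eid}))
        elif kind == "clean_sheet":
            fx = build_fixture(FixtureSpec("ideal_sheet", length=30,
                                           noise=0.02, seed=sub,
                                           params={"entry_id": eid}))
        elif kind == "multi_model":
            fx = build_fixture(FixtureSpec("multi_model", length=40, seed=sub,
                                           params={"entry_id": eid}))
        elif kind == "nmr":
            fx = build_fixture(FixtureSpec(
                "ideal_helix", length=40, seed=sub,
                params={"method": "SOLUTION NMR", "resolution": None,
                        "entry_id": eid}))
        elif kind == "short":
            fx = build_fixture(FixtureSpec("ideal_helix", length=8, seed=sub,
                                           params={"entry_id": eid}))
        elif kind == "ca_only":
            fx = build_fixture(FixtureSpec("ca_only_chain", length=60,
                                           seed=sub,
                                           params={"entry_id": eid}))
        else:
            fx = build_fixture(FixtureSpec("disulfide_pair", seed=sub,
                                           params={"entry_id": eid}))
        out.append(fx)
    return out
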
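"""Backbone and side-chain geometry: dihedrals, phi/psi/omega, chi1-5, tau.

Angles are reported in degrees.  Torsions lie in (-180, 180] with the IUPAC
sign convention (clockwise positive looking from the second to the third
atom); the planar tau angle lies in (0, 180).  A value that cannot be
computed (chain terminus, chain break, missing atom, undefined chi for the
residue type) is the sentinel ``MISSING`` (-999.9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .structure_io import CHAIN_BREAK_THRESHOLD, MISSING, Residue

log = logging.getLogger(__name__)


class GeometryError(ValueError):
    """Degenerate point configuration (coincident or collinear points)."""


@dataclass
class TorsionSet:
    phi: float = MISSING
    psi: float = MISSING
    omega: float = MISSING
    chi: list[float] = field(default_factory=lambda: [MISSING] * 5)
    tau: float = MISSING
    intact: bool = True


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) over four points.

    Computed from the cross products of the two bond-plane normals with an
    atan2 formulation, which is stable near 0 and 180 degrees.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise GeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear points: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def angle(p1, p2, p3) -> float:
    """Planar angle at p2, degrees in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1, v2 = p1 - p2, p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("coincident points")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def is_bonded(prev: Residue, curr: Residue,
              threshold: float = CHAIN_BREAK_THRESHOLD) -> bool:
    """Peptide continuity test on the C(i)-N(i+1) distance."""
    c, n = prev.coord("C"), curr.coord("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c - n)) <= threshold


def _try_dihedral(*points) -> float:
    if any(p is None for p in points):
        return MISSING
    try:
        return dihedral(*points)
    except GeometryError as exc:
        log.warning("degenerate dihedral geometry: %s", exc)
        return MISSING


def backbone_torsions(residues: list[Residue]) -> list[TorsionSet]:
    """phi/psi/omega per residue for one chain, in order.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i).  Termini and residues flanking a
    chain break get MISSING for the affected angles.
    """
    out = []
    n = len(residues)
    for i, res in enumerate(residues):
        ts = TorsionSet(intact=res.intact)
        prev_ok = i > 0 and is_bonded(residues[i - 1], res)
        next_ok = i < n - 1 and is_bonded(res, residues[i + 1])
        if prev_ok:
            p = residues[i - 1]
            ts.phi = _try_dihedral(p.coord("C"), res.coord("N"),
                                   res.coord("CA"), res.coord("C"))
            ts.omega = _try_dihedral(p.coord("CA"), p.coord("C"),
                                     res.coord("N"), res.coord("CA"))
        if next_ok:
            ts.psi = _try_dihedral(res.coord("N"), res.coord("CA"),
                                   res.coord("C"), residues[i + 1].coord("N"))
        ts.tau = tau_angle(res)
        ts.chi = sidechain_chis(res)
        out.append(ts)
    return out


def sidechain_chis(residue: Residue) -> list[float]:
    """chi1..chi5 for an intact residue; undefined levels are MISSING."""
    chis = [MISSING] * 5
    defs = chemdata.chi_definitions()
    for k in range(5):
        quad = defs[f"chi{k + 1}"].get(residue.name.upper())
        if quad is None:
            continue
        points = [residue.coord(a) for a in quad]
        chis[k] = _try_dihedral(*points)
    return chis


def tau_angle(residue: Residue) -> float:
    """Backbone N-CA-C angle at the alpha carbon, degrees."""
    n, ca, c = residue.coord("N"), residue.coord("CA"), residue.coord("C")
    if n is None or ca is None or c is None:
        return MISSING
    try:
        return angle(n, ca, c)
    except GeometryError:
        return MISSING
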
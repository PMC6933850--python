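"""Bundled chemistry tables (van der Waals radii, residue topologies, chi
definitions, ion charges, Ramachandran region masks).

All tables ship as YAML under ``pdblists/data`` so they can be inspected and
overridden without touching code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
# UNK is an amino-acid record with unknown topology.
AMINO_ACID_LIKE = AMINO_ACIDS_3 | {"UNK", "MSE"}

NUCLEOTIDES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DI", "DU", "N"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "UNK": "X",
}


def _load_yaml(name: str) -> dict:
    with resources.files("pdblists.data").joinpath(name).open("r") as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=None)
def vdw_radii() -> dict:
    """Element symbol -> vdW radius in Angstrom, plus a 'default' key."""
    return {str(k).upper() if k != "default" else k: float(v)
            for k, v in _load_yaml("vdw_radii.yaml").items()}


def vdw_radius(element: str) -> float:
    table = vdw_radii()
    return table.get(element.upper(), table["default"])


@lru_cache(maxsize=None)
def residue_topology() -> dict:
    """3-letter residue name -> list of reference heavy-atom names."""
    return {k: list(v) for k, v in _load_yaml("topology.yaml").items()}


@lru_cache(maxsize=None)
def chi_definitions() -> dict:
    """chi level ('chi1'..'chi5') -> {residue name -> 4 atom names}."""
    return _load_yaml("chi_definitions.yaml")


@lru_cache(maxsize=None)
def ion_charges() -> dict:
    """Monatomic-ion residue name -> formal charge."""
    return {str(k).upper(): int(v) for k, v in _load_yaml("ions.yaml").items()}


@lru_cache(maxsize=None)
def rama_regions() -> dict:
    """Class ('general'|'glycine'|'proline') -> list of favored phi/psi boxes."""
    return _load_yaml("rama_regions.yaml")


def rama_class(res_name: str) -> str:
    if res_name == "GLY":
        return "glycine"
    if res_name == "PRO":
        return "proline"
    return "general"


def rama_favored(res_name: str, phi: float, psi: float) -> bool:
    """True when (phi, psi) lies in a favored region for this residue class."""
    for lo_phi, hi_phi, lo_psi, hi_psi in rama_regions()[rama_class(res_name)]:
        if lo_phi <= phi <= hi_phi and lo_psi <= psi <= hi_psi:
            return True
    return False
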
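"""Dataset-culling gate, WHY_NOT reasons, the 0-10 usability grade, and the
homolog-inclusion threshold curve.

The acceptance gate rejects entries that are useless for structure
bioinformatics (multi-model, non-X-ray, too small, too broken ...) with a
fixed-order, first-failure-wins check list; every rejection is a value, not
an error, carrying a verbatim reason string from the registry.

The usability grade starts every entry at 10.0 points, subtracts
administrative penalties (bad resolution, short chains, UNK / Ca-only /
incomplete residues, unknown components), and only if the subtotal is still
positive adds Ramachandran and packing quality terms before clamping to
[0, 10] — Dutch school grading, where 6.0 is just a pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemdata
from .structure_io import StructureEntry, Residue
from .geometry import MISSING, TorsionSet, is_bonded

# WHY_NOT reason registry (verbatim strings; ASCII hyphens)
R_MODEL = "COMMENT: MODEL records found"
R_NOT_XRAY = "COMMENT: Not an X-ray structure"
R_TOO_MANY = "COMMENT: Too many residues"
R_TOO_FEW = "COMMENT: Not enough residues"
R_FEW_INTACT = "COMMENT: Not enough intact residues"
R_MANY_BAD = "COMMENT: Too many bad residues"
R_BAD_FRACTION = "COMMENT: Percentage bad residues too high"
R_CA_ONLY = "COMMENT: Too many C-alpha-only residues"
R_NO_CYS = "COMMENT: Contains no cysteines"
R_NO_CYS_BRIDGE = "COMMENT: Contains no cysteine bridges"

REASON_REGISTRY = (
    R_MODEL, R_NOT_XRAY, R_TOO_MANY, R_TOO_FEW, R_FEW_INTACT, R_MANY_BAD,
    R_BAD_FRACTION, R_CA_ONLY, R_NO_CYS, R_NO_CYS_BRIDGE,
)


@dataclass
class WhyNotRecord:
    entry_id: str
    database_name: str
    reason: str

    def __post_init__(self):
        if self.reason not in REASON_REGISTRY:
            raise ValueError(f"unregistered WHY_NOT reason {self.reason!r}")


@dataclass
class SelectionConfig:
    max_residues: int = 10000
    min_residues: int = 30
    min_intact_residues: int = 25
    max_bad_residues: int = 2000
    max_bad_fraction: float = 0.2
    max_ca_only_fraction: float = 0.05


@dataclass
class ScoreConfig:
    resolution_limit: float = 3.0
    low_resolution_penalty: float = 2.0
    short_chain_length: int = 50
    short_chain_penalty: float = 3.0
    unk_penalty: float = 0.5
    unk_cap: float = 3.0
    ca_only_penalty: float = 0.1
    ca_only_cap: float = 3.0
    missing_atoms_penalty: float = 0.05
    missing_atoms_cap: float = 3.0
    unknown_topology_penalty: float = 1.0
    unknown_topology_cap: float = 3.0
    rama_max_points: float = 2.0
    packing_max_points: float = 2.0
    min_rama_residues: int = 20
    min_packing_residues: int = 20
    packing_radius: float = 8.0
    # reference neighbour-count statistics of a well-packed core
    packing_reference_mean: float = 12.5
    packing_reference_sd: float = 4.0


@dataclass
class EntrySummary:
    """The entry-level facts the acceptance gate and the grade consume."""
    entry_id: str = "xxxx"
    n_models: int = 1
    experiment_method: str = "X-RAY DIFFRACTION"
    resolution: float | None = 2.0
    n_residues: int = 0
    n_intact: int = 0
    n_ca_only: int = 0
    n_unk: int = 0
    n_missing_atom_residues: int = 0
    n_unknown_components: int = 0
    longest_chain: int = 0
    has_cys: bool = False
    has_cys_bridge: bool = False
    rama_fraction: float | None = None
    n_rama_residues: int = 0
    neighbor_counts: list[int] = field(default_factory=list)


def summarize_entry(entry: StructureEntry,
                    torsions: dict[Residue, TorsionSet] | None = None,
                    cys_bridge_count: int | None = None) -> EntrySummary:
    """Condense a parsed entry into the facts used by gate and grade."""
    model = entry.first_model
    protein = [r for r in model if r.category == "amino_acid"]
    ca_only = [r for r in protein if r.ca_only]
    unk = [r for r in protein if r.name.upper() == "UNK"]
    missing = [r for r in protein
               if not r.intact and not r.ca_only and not r.unknown_topology]
    unknown_comp = len({r.name for r in model
                        if r.category in ("ligand", "unknown")}) + \
        len({r.name for r in protein if r.unknown_topology and r.name != "UNK"})

    longest = 0
    for residues in entry.chains(0).values():
        aa = [r for r in residues if r.category == "amino_acid"]
        run = 0
        for i, r in enumerate(aa):
            if i > 0 and is_bonded(aa[i - 1], r):
                run += 1
            else:
                run = 1
            longest = max(longest, run)

    rama_fraction = None
    n_rama = 0
    if torsions:
        evaluable = [(r, t) for r, t in torsions.items()
                     if t.phi != MISSING and t.psi != MISSING]
        n_rama = len(evaluable)
        if n_rama:
            favored = sum(chemdata.rama_favored(r.name, t.phi, t.psi)
                          for r, t in evaluable)
            rama_fraction = favored / n_rama

    cys = [r for r in protein if r.name == "CYS"]
    if cys_bridge_count is None:
        from .contacts import cys_bridges
        cys_bridge_count = len(cys_bridges(model)) if cys else 0

    return EntrySummary(
        entry_id=entry.entry_id,
        n_models=entry.n_models,
        experiment_method=entry.experiment_method,
        resolution=entry.resolution,
        n_residues=len(protein),
        n_intact=sum(r.intact for r in protein),
        n_ca_only=len(ca_only),
        n_unk=len(unk),
        n_missing_atom_residues=len(missing),
        n_unknown_components=unknown_comp,
        longest_chain=longest,
        has_cys=bool(cys),
        has_cys_bridge=cys_bridge_count > 0,
        rama_fraction=rama_fraction,
        n_rama_residues=n_rama,
        neighbor_counts=_neighbor_counts(model),
    )


def _neighbor_counts(model: list[Residue],
                     radius: float = 8.0) -> list[int]:
    """Per-residue CB (CA for GLY) neighbour counts within ``radius``."""
    pts = []
    for r in model:
        if r.category != "amino_acid":
            continue
        p = r.coord("CA") if r.name == "GLY" else r.coord("CB")
        if p is None:
            p = r.coord("CA")
        if p is not None:
            pts.append(p)
    if not pts:
        return []
    pts = np.array(pts)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return list((np.sum(d < radius, axis=1) - 1).astype(int))


# ---------------------------------------------------------------------------
# acceptance gate

def lists_acceptance(summary: EntrySummary, database: str = "chi",
                     config: SelectionConfig | None = None):
    """Return ``"accepted"`` or a :class:`WhyNotRecord`.

    Database-specific preconditions (cys needs cysteine bridges) are applied
    before the generic checks; generic checks run in fixed order with the
    first failure winning.
    """
    cfg = config or SelectionConfig()

    def reject(reason):
        return WhyNotRecord(summary.entry_id, database, reason)

    if database == "cys":
        if not summary.has_cys:
            return reject(R_NO_CYS)
        if not summary.has_cys_bridge:
            return reject(R_NO_CYS_BRIDGE)

    n = summary.n_residues
    bad = n - summary.n_intact
    if summary.n_models > 1:
        return reject(R_MODEL)
    if "X-RAY" not in summary.experiment_method.upper():
        return reject(R_NOT_XRAY)
    if n > cfg.max_residues:
        return reject(R_TOO_MANY)
    if n < cfg.min_residues:
        return reject(R_TOO_FEW)
    if summary.n_intact < cfg.min_intact_residues:
        return reject(R_FEW_INTACT)
    if bad > cfg.max_bad_residues:
        return reject(R_MANY_BAD)
    if n and bad / n > cfg.max_bad_fraction:
        return reject(R_BAD_FRACTION)
    if n and summary.n_ca_only / n > cfg.max_ca_only_fraction:
        return reject(R_CA_ONLY)
    return "accepted"


# ---------------------------------------------------------------------------
# the usability grade

@dataclass
class UsabilityScore:
    base: float
    penalties: dict[str, float]
    quality_bonus: dict[str, float]
    final: float

    @property
    def administrative_subtotal(self) -> float:
        return self.base - sum(self.penalties.values())


def ramachandran_term(rama_fraction: float | None, n_rama_residues: int,
                      config: ScoreConfig | None = None) -> float:
    """Favored-fraction of phi/psi pairs mapped linearly to [0, max_points].

    Fewer than ``min_rama_residues`` evaluable residues yields 0 points.
    """
    cfg = config or ScoreConfig()
    if rama_fraction is None or n_rama_residues < cfg.min_rama_residues:
        return 0.0
    return cfg.rama_max_points * float(np.clip(rama_fraction, 0.0, 1.0))


def packing_term(neighbor_counts, config: ScoreConfig | None = None) -> float:
    """Neighbour-count packing proxy mapped to [0, max_points].

    The per-residue CB-within-8A count is converted to a z-like deviation
    from the bundled reference mean; the mean absolute deviation maps
    linearly (1 - dev/2, clipped) onto the points scale.  Entries with fewer
    than ``min_packing_residues`` residues get 0 points.
    """
    cfg = config or ScoreConfig()
    counts = np.asarray(list(neighbor_counts), dtype=float)
    if counts.size < cfg.min_packing_residues:
        return 0.0
    z = (counts.mean() - cfg.packing_reference_mean) / cfg.packing_reference_sd
    dev = abs(float(z))
    return cfg.packing_max_points * float(np.clip(1.0 - dev / 2.0, 0.0, 1.0))


def sco_score(summary: EntrySummary,
              config: ScoreConfig | None = None) -> UsabilityScore:
    """The 0.0-10.0 bioinformatics-usability grade for one entry."""
    cfg = config or ScoreConfig()
    pen: dict[str, float] = {}
    if summary.resolution is not None and summary.resolution > cfg.resolution_limit:
        pen["low_resolution"] = cfg.low_resolution_penalty
    if summary.longest_chain < cfg.short_chain_length:
        pen["short_chain"] = cfg.short_chain_penalty
    if summary.n_unk:
        pen["unk_residues"] = min(cfg.unk_cap,
                                  cfg.unk_penalty * summary.n_unk)
    if summary.n_ca_only:
        pen["ca_only"] = min(cfg.ca_only_cap,
                             cfg.ca_only_penalty * summary.n_ca_only)
    if summary.n_missing_atom_residues:
        pen["missing_atoms"] = min(
            cfg.missing_atoms_cap,
            cfg.missing_atoms_penalty * summary.n_missing_atom_residues)
    if summary.n_unknown_components:
        pen["unknown_topology"] = min(
            cfg.unknown_topology_cap,
            cfg.unknown_topology_penalty * summary.n_unknown_components)

    subtotal = 10.0 - sum(pen.values())
    bonus: dict[str, float] = {}
    if subtotal > 0:
        bonus["ramachandran"] = ramachandran_term(
            summary.rama_fraction, summary.n_rama_residues, cfg)
        bonus["packing"] = packing_term(summary.neighbor_counts, cfg)
        final = subtotal + sum(bonus.values())
    else:
        final = 0.0
    final = float(np.clip(final, 0.0, 10.0))
    return UsabilityScore(10.0, pen, bonus, final)


# ---------------------------------------------------------------------------
# homolog inclusion (threshold curve + sequence filter)

#: original length-dependent identity curve constants; the plateau of 25%
#: plus the added 5% gives the 30% floor
HSSP_A = 290.15
HSSP_B = -0.562
HSSP_PLATEAU = 25.0
HSSP_OFFSET = 5.0
COVERAGE_MIN = 0.75


def hssp_threshold(alignment_length: float) -> float:
    """Minimum percent identity for including a homolog, as a function of
    alignment length: max(290.15 * L^-0.562, 25) + 5."""
    if alignment_length < 1:
        raise ValueError("alignment length must be >= 1")
    return max(HSSP_A * alignment_length ** HSSP_B, HSSP_PLATEAU) + HSSP_OFFSET


def sequence_accept(identity: float, alignment_length: float,
                    coverage: float) -> bool:
    """True iff identity clears the threshold curve and the alignment covers
    more than 75% of the full length."""
    if not (0.0 <= identity <= 100.0):
        raise ValueError("identity must be a percentage in [0, 100]")
    if not (0.0 <= coverage <= 1.0):
        raise ValueError("coverage must be a fraction in [0, 1]")
    return (identity > hssp_threshold(alignment_length)
            and coverage > COVERAGE_MIN)
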
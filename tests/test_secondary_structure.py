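"""Kabsch-Sander assignment, the reduced alphabet, and annotation diffing."""

import numpy as np
import pytest

from pdblists import read_structure
from pdblists.fixtures import FixtureSpec, build_fixture
from pdblists.secondary_structure import (HB_COUPLING, SSAnnotation,
                                          assign_secondary_structure,
                                          compute_hbonds, diff_deposited,
                                          hbond_energy, helix_end_comparison,
                                          reduce_alphabet)
from pdblists.structure_io import SSInterval


def direct_energy(n, h, c, o):
    """Single-expression oracle for the electrostatic H-bond energy."""
    dist = np.linalg.norm
    return HB_COUPLING * (1 / dist(o - n) + 1 / dist(c - h)
                          - 1 / dist(o - h) - 1 / dist(c - n))


class TestHBondEnergy:
    def test_equal_distances_cancel(self):
        # degenerate symmetric square: all four distances equal -> E = 0
        from pdblists.structure_io import Atom, Residue
        donor = Residue("ALA", 1, "", "A", [
            Atom(1, "N", "N", "", np.array([0.0, 0.0, 0.0]))])
        acceptor = Residue("ALA", 5, "", "A", [
            Atom(2, "C", "C", "", np.array([3.0, 3.0, 0.0])),
            Atom(3, "O", "O", "", np.array([0.0, 3.0, 0.0]))])
        h = np.array([3.0, 0.0, 0.0])
        # r(ON)=3, r(CH)=3, r(OH)=sqrt(18), r(CN)=sqrt(18): terms cancel pairwise
        e = hbond_energy(donor, acceptor, h_position=h)
        assert e == pytest.approx(
            HB_COUPLING * (2 / 3.0 - 2 / np.sqrt(18.0)))

    def test_helix_i_to_i4_bond_matches_oracle(self, helix_entry):
        entry, _ = helix_entry
        res = entry.first_model
        bond_set, bonds = compute_hbonds(res)
        i4 = [b for b in bonds if b.donor - b.acceptor == 4]
        assert i4, "alpha helix must form i->i-4 H-bonds"
        for b in i4:
            donor, acceptor = res[b.donor], res[b.acceptor]
            prev = res[b.donor - 1]
            v = prev.coord("C") - prev.coord("O")
            h = donor.coord("N") + v / np.linalg.norm(v)
            expect = direct_energy(donor.coord("N"), h,
                                   acceptor.coord("C"), acceptor.coord("O"))
            assert b.energy == pytest.approx(max(expect, -9.9), abs=1e-9)
            assert b.energy < -0.5

    def test_distant_pair_is_weak(self):
        from pdblists.structure_io import Atom, Residue
        donor = Residue("ALA", 1, "", "A", [
            Atom(1, "N", "N", "", np.array([20.0, 0.0, 0.0]))])
        acceptor = Residue("ALA", 9, "", "A", [
            Atom(2, "C", "C", "", np.zeros(3)),
            Atom(3, "O", "O", "", np.array([0.0, 1.23, 0.0]))])
        e = hbond_energy(donor, acceptor,
                         h_position=np.array([19.0, 0.0, 0.0]))
        assert abs(e) < 0.5


class TestAssignment:
    def test_ideal_helix_interior_H(self, helix_entry):
        entry, truth = helix_entry
        ann = assign_secondary_structure(entry.first_model)
        interior = ann.states[2:-2]
        assert set(interior) == {"H"}
        assert all(s in (" ", "T", "G", "H") for s in ann.states)

    def test_antiparallel_sheet_interiors_E(self, sheet_entry):
        entry, truth = sheet_entry
        ann = assign_secondary_structure(entry.first_model)
        states = "".join(ann.states)
        runs = [r for r in states.split() if "E" in r]
        assert states.count("E") >= 2 * (truth["strand_length"] - 2)

    def test_isolated_strand_has_no_E_or_B(self, extended_entry):
        entry, _ = extended_entry
        ann = assign_secondary_structure(entry.first_model)
        assert "E" not in ann.states and "B" not in ann.states

    def test_every_residue_gets_exactly_one_state(self, sheet_entry):
        entry, _ = sheet_entry
        ann = assign_secondary_structure(entry.first_model)
        protein = [r for r in entry.first_model if r.category == "amino_acid"]
        assert len(ann.states) == len(protein)
        assert all(s in "HGIEBTS " for s in ann.states)

    def test_short_chain_is_all_loop(self):
        fx = build_fixture(FixtureSpec("ideal_helix", length=2))
        entry = read_structure(fx.pdb_text)
        ann = assign_secondary_structure(entry.first_model)
        assert set(ann.states) <= {" "}

    def test_rigid_motion_invariance(self, helix_entry):
        import copy
        from scipy.spatial.transform import Rotation
        entry, _ = helix_entry
        base = assign_secondary_structure(entry.first_model).states
        moved = copy.deepcopy(entry.first_model)
        rot = Rotation.random(random_state=3).as_matrix()
        for r in moved:
            for a in r.atoms:
                a.position = rot @ a.position + np.array([30.0, -12.0, 7.0])
        assert assign_secondary_structure(moved).states == base

    def test_cutoff_sensitivity_at_criterion(self, helix_entry):
        # an energy criterion eps away from a real bond's energy flips the
        # assignment of at least one residue (the 3.51 vs 3.49 A situation)
        entry, _ = helix_entry
        _, bonds = compute_hbonds(entry.first_model, cutoff=0.0)
        i4 = sorted((b for b in bonds if b.donor - b.acceptor == 4),
                    key=lambda b: b.energy)
        pivot = i4[len(i4) // 2].energy
        loose = assign_secondary_structure(entry.first_model,
                                           cutoff=pivot + 0.01)
        tight = assign_secondary_structure(entry.first_model,
                                           cutoff=pivot - 0.01)
        assert loose.states != tight.states


class TestReferenceAgreement:
    @pytest.mark.parametrize("kind,length,noise", [
        ("ideal_helix", 12, 0.0),
        ("ideal_helix", 30, 0.05),
        ("ideal_sheet", 6, 0.0),
        ("ideal_sheet", 8, 0.03),
        ("extended_chain", 12, 0.0),
    ])
    def test_agreement_with_reference_dssp(self, tmp_path, kind, length, noise):
        mdtraj = pytest.importorskip("mdtraj")
        fx = build_fixture(FixtureSpec(kind, length=length, noise=noise,
                                       seed=11))
        p = tmp_path / "fx.pdb"
        p.write_text(fx.pdb_text)
        ref = list(mdtraj.compute_dssp(mdtraj.load(str(p)),
                                       simplified=False)[0])
        ref = [" " if s in ("", "C", "NA") else s for s in ref]
        entry = read_structure(fx.pdb_text)
        ours = assign_secondary_structure(entry.first_model)
        same = np.mean([a == b for a, b in zip(ours.states, ref)])
        assert same >= 0.95
        assert ours.reduced == reduce_alphabet(ref)


class TestReduceAlphabet:
    @pytest.mark.parametrize("full,reduced", [
        ("H", "H"), ("G", "H"), ("I", "H"),
        ("E", "S"), ("B", " "), ("T", "T"), ("S", " "), (" ", " "),
    ])
    def test_mapping(self, full, reduced):
        assert reduce_alphabet([full]) == [reduced]

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError):
            reduce_alphabet(["X"])

    def test_idempotent_on_reduced_symbols(self):
        # H, T and ' ' are fixed points; reduced 'S' means strand only as
        # output, so idempotence is checked on the fixed-point subset
        for s in ("H", "T", " "):
            assert reduce_alphabet([s]) == [s]


def _annotation_from_states(entry, states):
    protein = [r for r in entry.first_model if r.category == "amino_acid"]
    return SSAnnotation(protein, list(states),
                        reduce_alphabet(states), "deposited")


class TestDiffDeposited:
    def test_exact_coverage_counts_zero(self, helix_entry):
        entry, _ = helix_entry
        ann = assign_secondary_structure(entry.first_model)
        h_idx = [i for i, s in enumerate(ann.states) if s == "H"]
        start = ann.residues[h_idx[0]].seq_num
        end = ann.residues[h_idx[-1]].seq_num
        entry = read_structure(entry and build_fixture(
            FixtureSpec("ideal_helix", length=12,
                        params={"deposited_helix": (start, end)})).pdb_text)
        ann = assign_secondary_structure(entry.first_model)
        diff = diff_deposited(entry, ann)
        assert diff["overassigned_helix_count"] == 0
        assert diff["helix_diffs"][0].n_term_delta == 0
        assert diff["helix_diffs"][0].c_term_delta == 0

    def test_overlong_deposited_helix(self, helix_entry):
        # computed H run at residues 3..8; deposited interval 3..10 extends
        # two residues past the computed C-end
        entry, _ = helix_entry
        states = [" ", " "] + ["H"] * 6 + [" "] * 4
        ann = _annotation_from_states(entry, states)
        entry.helix_records = [SSInterval("helix", "A", 3, "", "A", 10, "")]
        diff = diff_deposited(entry, ann)
        assert diff["helix_diffs"][0].c_term_delta == -2
        assert diff["helix_diffs"][0].n_term_delta == 0
        assert diff["overassigned_helix_count"] == 2
        entry.helix_records = []

    def test_unassigned_strands_counted(self, sheet_entry):
        entry, _ = sheet_entry
        ann = assign_secondary_structure(entry.first_model)
        diff = diff_deposited(entry, ann)  # fixture deposits no SHEET records
        assert diff["unassigned_strand_count"] == ann.states.count("E")


class TestHelixEndComparison:
    def test_identical_annotations_all_zero(self, long_helix_entry):
        entry, _ = long_helix_entry
        ann = assign_secondary_structure(entry.first_model)
        t = helix_end_comparison(ann, ann, min_length=6)
        assert t["compared"] >= 1 and t["unmatched"] == 0
        assert t["n_term"]["longer"]["0"] == t["compared"]
        for side in ("longer", "shorter"):
            for b in ("1", "2", "3", ">3"):
                assert t["n_term"][side][b] == 0
                assert t["c_term"][side][b] == 0

    def test_planted_end_deltas_tallied(self, long_helix_entry):
        entry, _ = long_helix_entry
        ann = assign_secondary_structure(entry.first_model)
        states_b = list(ann.states)
        # trim one residue from the C-end of the (single) helix run
        h_idx = [i for i, s in enumerate(states_b) if s == "H"]
        states_b[h_idx[-1]] = " "
        ann_b = _annotation_from_states(entry, states_b)
        t = helix_end_comparison(ann, ann_b, min_length=6)
        # annotation_a extends one residue beyond annotation_b at the C-end
        assert t["c_term"]["longer"]["1"] == 1
        assert t["n_term"]["longer"]["0"] == 1
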
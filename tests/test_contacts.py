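"""Contact families, bridges and ion proximities against brute-force
all-pairs oracles."""

import numpy as np
import pytest

from pdblists import read_structure
from pdblists.contacts import (BACKBONE_NAMES, CC_FAMILIES, cc_family,
                               cys_bridges, gap_contacts, hetero_contacts,
                               ion_contacts, point_contacts, residue_sphere,
                               salt_bridges)
from pdblists.fixtures import (FixtureSpec, build_chain, build_fixture,
                               _transform)
from pdblists.structure_io import MISSING, _finalize_residue


def res_key(r):
    return (r.chain_id, r.seq_num, r.icode)


def pair_set(pairs):
    return {tuple(sorted((res_key(p.residue_a), res_key(p.residue_b))))
            for p in pairs}


def oracle_pairs(model, family):
    """Plain double-loop reference for every cc family."""
    kind, params = CC_FAMILIES[family]
    protein = [r for r in model if r.category == "amino_acid"]
    order = {}
    counters = {}
    for r in protein:
        order[res_key(r)] = (r.chain_id, counters.get(r.chain_id, 0))
        counters[r.chain_id] = counters.get(r.chain_id, 0) + 1
    out = set()
    for i in range(len(protein)):
        for j in range(i + 1, len(protein)):
            a, b = protein[i], protein[j]
            ca, ia = order[res_key(a)]
            cb, ib = order[res_key(b)]
            if ca == cb and abs(ia - ib) <= 1:
                continue
            if kind == "point":
                name = params["atom_name"]
                if name == "CB" and (a.name == "GLY" or b.name == "GLY"):
                    continue
                pa, pb = a.coord(name), b.coord(name)
                if pa is None or pb is None:
                    continue
                if np.linalg.norm(pa - pb) < params["cutoff"]:
                    out.add(tuple(sorted((res_key(a), res_key(b)))))
                continue
            if params.get("interchain_only") and a.chain_id == b.chain_id:
                continue
            scope = params["scope"]
            if scope == "residue_sphere":
                (c1, r1), (c2, r2) = residue_sphere(a), residue_sphere(b)
                gap = np.linalg.norm(c1 - c2) - r1 - r2
            else:
                atoms_a = [x for x in a.atoms if not x.is_hydrogen]
                atoms_b = [x for x in b.atoms if not x.is_hydrogen]
                if scope == "sidechain_atom":
                    atoms_a = [x for x in atoms_a if x.name not in BACKBONE_NAMES]
                    atoms_b = [x for x in atoms_b if x.name not in BACKBONE_NAMES]
                if not atoms_a or not atoms_b:
                    continue
                gap = min(np.linalg.norm(x.position - y.position)
                          - x.vdw_radius - y.vdw_radius
                          for x in atoms_a for y in atoms_b)
            if gap < params["gap_cutoff"]:
                out.add(tuple(sorted((res_key(a), res_key(b)))))
    return out


@pytest.fixture(scope="module")
def fuzzed_model():
    """A two-chain, ~56-residue jittered model with mixed residue types."""
    seq = (["ALA", "SER", "LEU", "ASP", "LYS", "PHE", "GLY"] * 4)
    c1 = build_chain(seq, [-57.0] * len(seq), [-47.0] * len(seq),
                     [180.0] * len(seq), {1: -60.0, 2: 180.0, 3: 180.0,
                                          4: 180.0},
                     chain_id="A")
    c2 = build_chain(seq, [-139.0] * len(seq), [135.0] * len(seq),
                     [180.0] * len(seq), {1: -60.0, 2: 180.0, 3: 180.0,
                                          4: 180.0},
                     chain_id="B")
    _transform(c2, shift=(4.0, 6.0, -2.0))
    model = c1 + c2
    rng = np.random.default_rng(77)
    for r in model:
        _finalize_residue(r)
        for a in r.atoms:
            a.position = a.position + rng.normal(0, 0.05, 3)
    return model


class TestPointContacts:
    def _two_ca(self, d):
        c1 = build_chain(["ALA"], [0.0], [120.0], [180.0], start_seq=1)
        c2 = build_chain(["ALA"], [0.0], [120.0], [180.0], start_seq=5)
        _transform(c2, shift=(d, 11.0, 0.0))
        # place so CA-CA distance is exactly computable
        shift = c2[0].coord("CA") - c1[0].coord("CA")
        _transform(c2, shift=-shift + np.array([d, 0.0, 0.0]))
        model = c1 + c2
        for r in model:
            _finalize_residue(r)
        return model

    def test_just_below_cutoff_present(self):
        pairs = point_contacts(self._two_ca(12.4), "CA", 12.5)
        assert len(pairs) == 1 and pairs[0].metric == pytest.approx(12.4)

    def test_just_above_cutoff_absent(self):
        assert point_contacts(self._two_ca(12.6), "CA", 12.5) == []

    def test_strictness_at_cutoff(self):
        assert point_contacts(self._two_ca(12.5), "CA", 12.5) == []

    def test_sequence_neighbors_excluded(self, fuzzed_model):
        pairs = point_contacts(fuzzed_model, "CA", 12.5)
        for p in pairs:
            if p.residue_a.chain_id == p.residue_b.chain_id:
                assert abs(p.residue_a.seq_num - p.residue_b.seq_num) > 1


class TestOracleEquality:
    @pytest.mark.parametrize("family", sorted(CC_FAMILIES))
    def test_family_equals_brute_force(self, fuzzed_model, family):
        assert pair_set(cc_family(fuzzed_model, family)) == \
            oracle_pairs(fuzzed_model, family)

    def test_mirror_symmetry(self, fuzzed_model):
        import copy
        mirrored = copy.deepcopy(fuzzed_model)
        for r in mirrored:
            for a in r.atoms:
                a.position = a.position * np.array([-1.0, 1.0, 1.0])
        for family in ("cc1", "cc5", "cc7"):
            assert pair_set(cc_family(fuzzed_model, family)) == \
                pair_set(cc_family(mirrored, family))

    def test_cutoff_monotonicity(self, fuzzed_model):
        cc4 = pair_set(cc_family(fuzzed_model, "cc4"))
        cc5 = pair_set(cc_family(fuzzed_model, "cc5"))
        cc6 = pair_set(cc_family(fuzzed_model, "cc6"))
        cc7 = pair_set(cc_family(fuzzed_model, "cc7"))
        cc8 = pair_set(cc_family(fuzzed_model, "cc8"))
        assert cc4 <= cc5 and cc6 <= cc7 and cc8 <= cc7


class TestGapArithmetic:
    def _two_carbon_residues(self, d):
        from pdblists.structure_io import Atom, Residue
        a = Residue("ALA", 1, "", "A", [
            Atom(1, "CB", "C", "", np.zeros(3))])
        b = Residue("ALA", 5, "", "A", [
            Atom(2, "CB", "C", "", np.array([d, 0.0, 0.0]))])
        for r in (a, b):
            r.category = "amino_acid"
        return [a, b]

    def test_bump_below_quarter_angstrom(self):
        model = self._two_carbon_residues(3.60)  # gap 0.20
        pairs = gap_contacts(model, "any_atom", 0.25)
        assert len(pairs) == 1
        assert pairs[0].metric == pytest.approx(0.20)

    def test_gap_between_thresholds(self):
        model = self._two_carbon_residues(3.70)  # gap 0.30
        assert gap_contacts(model, "any_atom", 0.25) == []
        assert len(gap_contacts(model, "any_atom", 2.5)) == 1


class TestHeteroContacts:
    def test_ligand_contact_present(self):
        fx = build_fixture(FixtureSpec("ligand_site", params={"gap": 0.5}))
        entry = read_structure(fx.pdb_text)
        hits = hetero_contacts(entry.first_model, "ligand", 1.0)
        assert [h.residue_a.name for h in hits] == ["LYS"]
        assert hits[0].metric == pytest.approx(0.5, abs=0.05)

    def test_ligand_too_far_absent(self):
        fx = build_fixture(FixtureSpec("ligand_site", params={"gap": 1.5}))
        entry = read_structure(fx.pdb_text)
        assert hetero_contacts(entry.first_model, "ligand", 1.0) == []

    def test_nucleic_contacts_match_oracle(self):
        from pdblists.structure_io import Atom, Residue
        chain = build_chain(["ALA"] * 6, [-57.0] * 6, [-47.0] * 6,
                            [180.0] * 6)
        for r in chain:
            _finalize_residue(r)
        na = []
        for k, base in enumerate((chain[1].coord("CA"),
                                  chain[4].coord("CA"))):
            res = Residue("DA", 100 + k, "", "B", [
                Atom(0, "P", "P", "", base + np.array([4.0, 1.0, 0.0])),
                Atom(0, "C1'", "C", "", base + np.array([5.2, 1.5, 0.0])),
                Atom(0, "N9", "N", "", base + np.array([6.0, 0.2, 0.5]))])
            _finalize_residue(res)
            na.append(res)
        model = chain + na
        got = {res_key(h.residue_a) for h in
               hetero_contacts(model, "nucleotide", 1.0)}
        expect = set()
        for r in chain:
            for p in na:
                (c1, r1), (c2, r2) = residue_sphere(r), residue_sphere(p)
                if np.linalg.norm(c1 - c2) - r1 - r2 < 1.0:
                    expect.add(res_key(r))
        assert got == expect and expect  # non-empty by construction


class TestBridges:
    def test_canonical_disulfide(self):
        fx = build_fixture(FixtureSpec("disulfide_pair"))
        entry = read_structure(fx.pdb_text)
        br = cys_bridges(entry.first_model)
        assert [(b.residue_a.seq_num, b.residue_b.seq_num) for b in br] == \
            [tuple(fx.truth["bridges"][0])]
        assert br[0].distance == pytest.approx(2.05, abs=0.01)

    def test_long_sg_pair_is_no_bridge(self):
        fx = build_fixture(FixtureSpec("disulfide_pair",
                                       params={"sg_distance": 3.5}))
        entry = read_structure(fx.pdb_text)
        assert cys_bridges(entry.first_model) == []

    def test_greedy_uniqueness_three_in_a_row(self):
        import copy
        base = build_chain(["CYS"], [0.0], [120.0], [180.0], {1: -60.0})[0]
        _finalize_residue(base)
        sg = base.coord("SG")
        model = []
        for k in range(3):
            r = copy.deepcopy(base)
            r.seq_num = 1 + 4 * k
            shift = k * 2.05 * np.array([1.0, 0.0, 0.0])
            for a in r.atoms:
                a.position = a.position + shift
            model.append(r)
        # SG(1)-SG(2) = SG(2)-SG(3) = 2.05: the middle SG may pair only once
        br = cys_bridges(model)
        assert len(br) == 1
        used = [br[0].residue_a.seq_num, br[0].residue_b.seq_num]
        assert 5 in used  # middle residue is in the one bridge

    def test_salt_bridge_asp_lys(self):
        fx = build_fixture(FixtureSpec("salt_bridge_pair"))
        entry = read_structure(fx.pdb_text)
        sbr = salt_bridges(entry.first_model, his_positive=False)
        sbh = salt_bridges(entry.first_model, his_positive=True)
        assert len(sbr) >= 1 and len(sbh) >= len(sbr)
        best = min(sbr, key=lambda b: b.distance)
        assert best.distance == pytest.approx(3.0, abs=0.01)

    def test_histidine_only_positive_on_request(self):
        fx = build_fixture(FixtureSpec("salt_bridge_pair",
                                       params={"acidic": "GLU",
                                               "basic": "HIS"}))
        entry = read_structure(fx.pdb_text)
        plain = salt_bridges(entry.first_model, his_positive=False)
        his = salt_bridges(entry.first_model, his_positive=True)
        keys = {(b.residue_a.name, b.residue_b.name) for b in his}
        assert ("GLU", "HIS") in keys or ("HIS", "GLU") in keys
        assert not any({"GLU", "HIS"} ==
                       {b.residue_a.name, b.residue_b.name} for b in plain)

    def test_distant_charges_give_nothing(self):
        fx = build_fixture(FixtureSpec("salt_bridge_pair",
                                       params={"distance": 9.0}))
        entry = read_structure(fx.pdb_text)
        bridges = salt_bridges(entry.first_model)
        assert all(b.distance <= 4.0 for b in bridges)
        assert not any({b.residue_a.seq_num, b.residue_b.seq_num} == {1, 10}
                       for b in bridges)


class TestIons:
    def test_no_ions_all_missing(self, helix_entry):
        entry, _ = helix_entry
        iod = ion_contacts(entry.first_model)["iod"]
        assert all(v == MISSING for v in iod.values())

    def test_zinc_site_grouping(self):
        fx = build_fixture(FixtureSpec("ion_site"))
        entry = read_structure(fx.pdb_text)
        result = ion_contacts(entry.first_model)
        zn = next(i for i in result["ion"] if i.name == "ZN")
        assert [c.residue.name for c in result["ion"][zn]] == ["HIS"]
        assert result["ion"][zn][0].distance == pytest.approx(2.1, abs=0.01)

    def test_iod_ignores_anions(self):
        fx = build_fixture(FixtureSpec("ion_site"))
        entry = read_structure(fx.pdb_text)
        result = ion_contacts(entry.first_model)
        his = next(r for r in result["iod"])
        # nearest positive ion is the zinc at 2.1 A, not the closer-to-
        # nothing chloride
        assert result["iod"][his] == pytest.approx(2.1, abs=0.01)

    def test_two_ion_grouping_matches_oracle(self):
        fx = build_fixture(FixtureSpec("ion_site"))
        entry = read_structure(fx.pdb_text)
        result = ion_contacts(entry.first_model, short_cutoff=10.0)
        for ion, hits in result["ion"].items():
            for c in hits:
                d = min(np.linalg.norm(a.position - ion.atoms[0].position)
                        for a in c.residue.atoms)
                assert c.distance == pytest.approx(d)
                assert d <= 10.0
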
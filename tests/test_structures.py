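"""Complex structures: parsing, filtering, contacts, pockets, superposition."""

import numpy as np
import pytest

from lrrpockets.simulate import SimConfig, generate_toy_complex
from lrrpockets.structures import (
    ContactRecord,
    Residue,
    StructureModel,
    call_pockets,
    consensus_pockets,
    filter_models,
    find_contacts,
    hydrogen_bonds,
    parse_structure,
    superpose,
    superpose_models,
)
from tests.conftest import ROLES
from tests.test_simulate import brute_force_contacts


def _mini_model(pairs, rec_atom="OG", pep_atom="OG", rec_extra=None,
                pep_extra=None):
    """Tiny hand-built two-chain model: one receptor and one peptide
    residue per requested (distance, ...) pair."""
    residues = []
    for k, dist in enumerate(pairs):
        rnum, pnum = 10 + k, 1 + k
        shift = np.array([0, 0, 100.0 * k])
        rec_atoms = {rec_atom: np.array([0.0, 0.0, 100.0 * k])}
        if rec_extra:
            rec_atoms.update({n: np.array(x) + shift
                              for n, x in rec_extra.items()})
        residues.append(Residue("A", rnum, "SER", rec_atoms,
                                {a: a[0] for a in rec_atoms}))
        pep_atoms = {pep_atom: np.array([dist, 0.0, 100.0 * k])}
        if pep_extra:
            pep_atoms.update({n: np.array(x) + shift
                              for n, x in pep_extra.items()})
        residues.append(Residue("B", pnum, "SER", pep_atoms,
                                {a: a[0] for a in pep_atoms}))
    return StructureModel("mini", {"A": "receptor", "B": "peptide"},
                          residues, iptm=0.9)


class TestParse:
    def test_roundtrip_coordinates_stable(self, toy_complex):
        m1 = parse_structure(toy_complex.pdb, ROLES, model_id="m")
        import gemmi

        st = gemmi.read_pdb_string(toy_complex.pdb)
        again = st.make_pdb_string()
        m2 = parse_structure(again, ROLES, model_id="m")
        for r1, r2 in zip(m1.residues, m2.residues):
            for a in r1.atoms:
                assert np.allclose(r1.atoms[a], r2.atoms[a])

    def test_unknown_role_chain_raises(self, toy_complex):
        with pytest.raises(KeyError, match="role chains"):
            parse_structure(toy_complex.pdb, {"Z": "receptor"})

    def test_pdb_and_mmcif_agree(self, toy_complex):
        m1 = parse_structure(toy_complex.pdb, ROLES, model_id="m")
        m2 = parse_structure(toy_complex.mmcif(), ROLES, model_id="m",
                             fmt="cif")
        key = lambda m: {(r.chain, r.number, a) for r in m.residues
                         for a in r.atoms}
        assert key(m1) == key(m2)
        ca1 = np.array([r.atoms["CA"] for r in m1.residues])
        ca2 = np.array([r.atoms["CA"] for r in m2.residues])
        assert np.allclose(ca1, ca2, atol=1e-3)

    def test_missing_sidecar_score_flags_model(self, toy_complex):
        m = parse_structure(toy_complex.pdb, ROLES, sidecar={},
                            model_id="m")
        assert m.iptm is None
        confident, gray, rejected = filter_models([m], "afm")
        assert rejected == [m]


class TestFilterModels:
    @pytest.mark.parametrize("iptm,scheme,bucket", [
        (0.85, "afm", "confident"),
        (0.84, "afm", "rejected"),        # strict inequality at threshold
        (0.90, "af3", "confident"),
        (0.81, "af3", "confident"),
        (0.80, "af3", "gray"),            # strict at the upper bound too
        (0.70, "af3", "gray"),
        (0.60, "af3", "rejected"),
        (0.30, "af3", "rejected"),
    ])
    def test_threshold_buckets(self, iptm, scheme, bucket):
        m = StructureModel("m", {}, [], iptm=iptm)
        confident, gray, rejected = filter_models([m], scheme)
        got = ("confident" if m in confident else
               "gray" if m in gray else "rejected")
        assert got == bucket

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            filter_models([StructureModel("m", {}, [], iptm=0.9)], "x")


class TestContacts:
    def test_pair_inside_cutoff_found(self):
        m = _mini_model([3.0])
        contacts = find_contacts(m, cutoff=4.0)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.0)

    def test_pair_outside_cutoff_ignored(self):
        assert find_contacts(_mini_model([4.5]), cutoff=4.0) == []

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_equals_brute_force_oracle_on_toy_complexes(self, seed):
        sim = generate_toy_complex(SimConfig(seed=seed))
        m = parse_structure(sim.pdb, ROLES, model_id="m")
        got = {(c.receptor_residue[1], c.peptide_position)
               for c in find_contacts(m)}
        assert got == brute_force_contacts(sim.pdb)


class TestHydrogenBonds:
    def test_planted_geometry_detected(self, toy_complex, cfg):
        m = parse_structure(toy_complex.pdb, ROLES, model_id="m")
        hb = {(c.receptor_residue[1], c.peptide_position)
              for c in hydrogen_bonds(m) if c.hbond}
        assert hb == set(cfg.planted_contacts)

    def test_pair_beyond_dmax_is_not_hbond(self):
        m = _mini_model([3.8])
        out = hydrogen_bonds(m, d_max=3.5, contacts=find_contacts(m, 4.0))
        assert all(not c.hbond for c in out)

    def test_carbon_pair_is_contact_but_never_hbond(self):
        m = _mini_model([2.9], rec_atom="CB", pep_atom="CB")
        contacts = find_contacts(m, 4.0)
        assert len(contacts) == 1
        out = hydrogen_bonds(m, contacts=contacts)
        assert all(not c.hbond for c in out)

    def test_donor_angle_rejects_blocked_geometry(self):
        # both antecedents on the partner side: angle ~ 0 for both
        # donor orientations, so no hydrogen bond
        m = _mini_model([3.0], rec_extra={"CB": (1.2, 0.0, 0.0)},
                        pep_extra={"CB": (1.8, 0.3, 0.0)})
        out = hydrogen_bonds(m, contacts=find_contacts(m, 4.0))
        assert all(not c.hbond for c in out)
        # antecedents pointing away: angles ~ 180, accepted
        m2 = _mini_model([3.0], rec_extra={"CB": (-1.5, 0.0, 0.0)},
                         pep_extra={"CB": (4.5, 0.0, 0.0)})
        out2 = hydrogen_bonds(m2, contacts=find_contacts(m2, 4.0))
        assert any(c.hbond for c in out2)


class TestPockets:
    def test_toy_pockets_match_planted_truth(self, toy_complex, cfg):
        m = parse_structure(toy_complex.pdb, ROLES, model_id="m")
        call = call_pockets(hydrogen_bonds(m))
        want5 = {r for r, p in cfg.planted_contacts if p == 5}
        want7 = {r for r, p in cfg.planted_contacts if p == 7}
        assert call.pockets[5] == want5
        assert call.pockets[7] == want7

    def test_no_contacts_give_empty_pocket(self):
        call = call_pockets([], positions_of_interest=(5, 7))
        assert call.pockets == {5: set(), 7: set()}

    def test_empty_positions_give_empty_call(self):
        c = ContactRecord(("A", 246, "SER"), 5, 3.0, hbond=True,
                          donor="OG", acceptor="OG")
        assert call_pockets([c], positions_of_interest=()).pockets == {}


def _contactset(residues_at_5):
    return [ContactRecord(("A", r, "SER"), 5, 3.0, hbond=True,
                          donor="OG", acceptor="OG")
            for r in residues_at_5]


class TestConsensus:
    def test_unanimous_residues_kept_with_full_support(self):
        models = [_contactset({246, 268}) for _ in range(12)]
        call = consensus_pockets(models, positions_of_interest=(5,))
        assert call.pockets[5] == {246, 268}
        assert call.support[(5, 246)] == 12
        assert call.n_models == 12

    def test_minority_residue_dropped(self):
        models = [_contactset({246})] * 3 + [_contactset({246, 400})]
        call = consensus_pockets(models, positions_of_interest=(5,),
                                 min_support=0.5)
        assert call.pockets[5] == {246}

    def test_disjoint_models_at_full_support_empty(self):
        models = [_contactset({246}), _contactset({300})]
        call = consensus_pockets(models, positions_of_interest=(5,),
                                 min_support=1.0)
        assert call.pockets[5] == set()

    def test_monotone_in_min_support(self):
        models = [_contactset({246, 268}), _contactset({246}),
                  _contactset({246, 300}), _contactset({246, 268})]
        prev = None
        for s in (0.25, 0.5, 0.75, 1.0):
            got = consensus_pockets(models, positions_of_interest=(5,),
                                    min_support=s).pockets[5]
            if prev is not None:
                assert got <= prev
            prev = got


class TestSuperpose:
    def test_identical_coordinates_zero_rmsd(self):
        xyz = np.random.default_rng(0).normal(size=(10, 3))
        _, _, rmsd = superpose(xyz, xyz)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(30, 3))
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = (rot @ xyz.T).T + np.array([3.0, -2.0, 7.0])
        r, t, rmsd = superpose(xyz, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert np.linalg.det(r) == pytest.approx(1.0)

    def test_symmetric_rmsd(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 3))
        b = a + rng.normal(scale=0.3, size=(12, 3))
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2])

    def test_three_point_planar_fit_matches_angle_grid_oracle(self):
        # planar triangles: brute-force over rotation angle, refined
        a = np.array([[0, 0, 0], [2, 0, 0], [0, 1, 0.0]])
        b = np.array([[0.1, 0, 0], [2, 0.2, 0], [-0.1, 1.1, 0.0]])
        best = np.inf
        ca, cb = a.mean(0), b.mean(0)
        for ang in np.linspace(0, 2 * np.pi, 200001):
            rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                            [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
            moved = ((rot @ (b - cb).T).T + ca)
            best = min(best, np.sqrt(((moved - a) ** 2).sum(-1).mean()))
        assert superpose(a, b)[2] == pytest.approx(best, abs=1e-6)

    def test_matches_scipy_rotation_alignment(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        a = rng.normal(size=(15, 3))
        b = a + rng.normal(scale=0.2, size=(15, 3))
        rot, _, rmsd = superpose(a, b)
        r_sci, rssd = Rotation.align_vectors(a - a.mean(0), b - b.mean(0))
        assert np.allclose(rot, r_sci.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-8)

    def test_model_level_superposition(self, parsed_ensemble):
        confident = [m for m in parsed_ensemble if m.iptm and m.iptm > 0.84]
        _, _, rmsd = superpose_models(confident[0], confident[1])
        assert 0 <= rmsd < 1.0          # jittered replicates nearly align

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="equal"):
            superpose(np.zeros((3, 3)), np.zeros((4, 3)))
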
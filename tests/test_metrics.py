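"""Structure metrics: superposition, SASA/BSA, contacts, dihedrals."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from neomhc.geometry import build_backbone, rotation_matrix
from neomhc.metrics import (Selection, atom_displacement, buried_surface_area,
                            classify_310, contact_counts, contacts,
                            kabsch_superpose, phi_psi, sasa,
                            sasa_from_arrays, select_atoms, selection_rmsd)
from neomhc.sidechain import build_residue
from neomhc.structure import Atom, Chain, Residue, StructureModel


def rigid(coords, axis, angle, shift):
    rot = rotation_matrix(axis, angle)
    return coords @ rot.T + shift


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_superposes_exactly(self):
        pts = np.random.default_rng(2).normal(size=(8, 3))
        moved = rigid(pts, [1, 2, 3], 53.0, [4, -1, 2])
        sup = kabsch_superpose(pts, moved)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_four_point_configuration_matches_numeric_oracle(self):
        move = np.array([[0.0, 0, 0], [2, 0, 0], [0, 1.5, 0], [0.4, 0.3, 2]])
        ref = np.array([[0.2, 0.1, 0], [1.8, 0.4, 0.3], [0.3, 1.9, -0.2],
                        [0.5, 0.2, 1.7]])
        sup = kabsch_superpose(move, ref)

        def rmsd_of(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            moved = move @ rot.T + params[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            (minimize(rmsd_of, np.concatenate([rv, tv]), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12,
                               "maxiter": 20000}).fun
             for rv in (np.zeros(3), np.array([0.3, -0.2, 0.1]),
                        np.array([-1.0, 1.0, 0.5]))
             for tv in (np.zeros(3), ref.mean(0) - move.mean(0))))
        assert sup.rmsd == pytest.approx(best, abs=1e-5)

    def test_rmsd_invariant_under_shared_rigid_motion(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        b = a + rng.normal(scale=0.3, size=(7, 3))
        base = kabsch_superpose(a, b).rmsd
        a2 = rigid(a, [0, 0, 1], 40.0, [1, 1, 1])
        b2 = rigid(b, [0, 0, 1], 40.0, [1, 1, 1])
        assert kabsch_superpose(a2, b2).rmsd == pytest.approx(base)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestSelectionRMSD:
    def test_frame_equals_measure_equals_kabsch(self, micro_groove):
        rot = rotation_matrix([1, 1, 0], 25.0)
        moved = micro_groove.copy()
        for _, _, a in moved.iter_atoms():
            a.coord = rot @ a.coord + np.array([3.0, -2.0, 1.0])
        sel = Selection("C")
        assert selection_rmsd(micro_groove, moved, sel, sel) == \
            pytest.approx(0.0, abs=1e-9)

    def test_displaced_selection_measured_without_refit(self, micro_groove):
        moved = micro_groove.copy()
        for r in moved.chain("C").residues:
            for a in r.atoms:
                a.coord = a.coord + np.array([0.0, 0.0, 2.0])
        frame = Selection("A", atoms="backbone")
        measure = Selection("C")
        assert selection_rmsd(micro_groove, moved, frame, measure) == \
            pytest.approx(2.0, abs=1e-6)

    def test_atom_displacement_of_translated_residue(self, micro_groove):
        moved = micro_groove.copy()
        res = moved.chain("C").residues[5]
        for a in res.atoms:
            a.coord = a.coord + np.array([2.0, 0.0, 0.0])
        frame = Selection("A", atoms="backbone")
        d = atom_displacement(micro_groove, moved, frame, "C",
                              res.resseq, "CA")
        assert d == pytest.approx(2.0, abs=1e-6)

    def test_identical_structures_zero_displacement(self, micro_groove):
        d = atom_displacement(micro_groove, micro_groove,
                              Selection("A", atoms="backbone"), "C", 5, "CA")
        assert d == pytest.approx(0.0, abs=1e-9)


class TestSASA:
    def test_single_atom_closed_form(self):
        res = sasa_from_arrays(np.zeros((1, 3)), np.array([1.7]),
                               probe=1.4, n_points=960)
        assert res.total == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)

    def test_distant_atoms_are_independent(self):
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        res = sasa_from_arrays(coords, np.array([1.7, 1.52]))
        iso = (4 * np.pi * (1.7 + 1.4) ** 2
               + 4 * np.pi * (1.52 + 1.4) ** 2)
        assert res.total == pytest.approx(iso, rel=1e-6)

    def test_two_overlapping_spheres_match_cap_formula(self):
        r = 1.7 + 1.4
        d = 2.0
        coords = np.array([[0.0, 0, 0], [d, 0, 0]])
        numeric = sasa_from_arrays(coords, np.array([1.7, 1.7]),
                                   n_points=4000).total
        # analytic: each equal sphere loses a cap of height h = r - d/2
        cap = 2 * np.pi * r * (r - d / 2)
        analytic = 2 * (4 * np.pi * r ** 2 - cap)
        assert numeric == pytest.approx(analytic, rel=0.02)

    def test_convergence_with_point_count(self, micro_groove):
        pep = Selection("C")
        coarse = sasa(micro_groove, pep, n_points=480).total
        fine = sasa(micro_groove, pep, n_points=960).total
        assert abs(coarse - fine) / fine < 0.01

    def test_unknown_element_rejected(self):
        res = Residue(name="ALA", resseq=1)
        res.atoms = [Atom(name="XX", element="Zz", coord=np.zeros(3))]
        model = StructureModel([Chain("A", [res])])
        with pytest.raises(ValueError, match="radius"):
            sasa(model)


class TestBSA:
    def test_distant_parts_bury_nothing(self):
        def ball(chain_id, x):
            res = Residue(name="ALA", resseq=1)
            res.atoms = [Atom(name="CB", element="C",
                              coord=np.array([x, 0.0, 0.0]))]
            return Chain(chain_id, [res])

        model = StructureModel([ball("A", 0.0), ball("B", 50.0)])
        assert buried_surface_area(model, Selection("A"), Selection("B")) \
            == pytest.approx(0.0, abs=1e-9)

    def test_dimer_matches_two_sphere_oracle(self):
        def ball(chain_id, x):
            res = Residue(name="ALA", resseq=1)
            res.atoms = [Atom(name="CB", element="C",
                              coord=np.array([x, 0.0, 0.0]))]
            return Chain(chain_id, [res])

        d = 2.5
        model = StructureModel([ball("A", 0.0), ball("B", d)])
        bsa = buried_surface_area(model, Selection("A"), Selection("B"),
                                  n_points=4000)
        r = 1.7 + 1.4
        cap = 2 * np.pi * r * (r - d / 2)
        assert bsa == pytest.approx(2 * cap, rel=0.02)

    def test_symmetric_in_selections(self, micro_groove):
        a = buried_surface_area(micro_groove, Selection("A"), Selection("C"),
                                n_points=240)
        b = buried_surface_area(micro_groove, Selection("C"), Selection("A"),
                                n_points=240)
        assert a == pytest.approx(b, abs=1e-9)

    def test_interface_buries_area(self, micro_groove):
        assert buried_surface_area(micro_groove, Selection("A"),
                                   Selection("C"), n_points=240) > 100.0

    def test_overlapping_selections_rejected(self, micro_groove):
        with pytest.raises(ValueError):
            buried_surface_area(micro_groove, Selection("A"), Selection("A"))


class TestContacts:
    def two_residue_model(self, d, elements=("N", "O")):
        r1 = Residue(name="SER", resseq=1)
        r1.atoms = [Atom(name="N", element=elements[0], coord=np.zeros(3))]
        r2 = Residue(name="SER", resseq=1)
        r2.atoms = [Atom(name="O", element=elements[1],
                         coord=np.array([d, 0.0, 0.0]))]
        return StructureModel([Chain("A", [r1]), Chain("B", [r2])])

    def test_planted_polar_pair(self):
        model = self.two_residue_model(2.9)
        counts = contact_counts(contacts(model, Selection("A"),
                                         Selection("B")))
        assert counts == {"polar": 1, "hydrophobic": 0}

    def test_atoms_beyond_cutoffs_ignored(self):
        model = self.two_residue_model(6.0)
        assert contacts(model, Selection("A"), Selection("B")) == []

    def test_lowering_cutoffs_never_increases_counts(self, micro_groove):
        loose = contact_counts(contacts(micro_groove, Selection("A"),
                                        Selection("C"), 3.5, 4.5))
        tight = contact_counts(contacts(micro_groove, Selection("A"),
                                        Selection("C"), 3.0, 4.0))
        assert tight["polar"] <= loose["polar"]
        assert tight["hydrophobic"] <= loose["hydrophobic"]


class TestDihedrals:
    def build_peptide(self, phis, psis, seq=None):
        n = len(phis)
        seq = seq or "A" * n
        bb = build_backbone(n, phis, psis)
        chain = Chain("C")
        from neomhc.structure import ONE_TO_THREE
        for i, r in enumerate(bb):
            chain.residues.append(build_residue(r, ONE_TO_THREE[seq[i]],
                                                i + 1))
        return StructureModel([chain])

    def test_extended_strand_has_no_helix_span(self):
        model = self.build_peptide([-120.0] * 9, [120.0] * 9)
        records = phi_psi(model, "C")
        assert classify_310(records) == []
        assert records[0].phi is None and records[-1].psi is None

    def test_planted_310_span_recovered(self):
        phis = [-120.0] * 10
        psis = [120.0] * 10
        for i in (3, 4, 5, 6):  # residues 4..7
            phis[i], psis[i] = -60.0, -25.0
        model = self.build_peptide(phis, psis)
        spans = classify_310(phi_psi(model, "C"))
        assert spans == [(4, 7)]

    def test_run_shorter_than_minimum_not_reported(self):
        phis = [-120.0] * 8
        psis = [120.0] * 8
        for i in (3, 4):
            phis[i], psis[i] = -60.0, -25.0
        model = self.build_peptide(phis, psis)
        assert classify_310(phi_psi(model, "C")) == []

    def test_missing_backbone_marked_absent(self, micro_groove):
        broken = micro_groove.copy()
        res = broken.chain("C").residues[4]
        res.atoms = [a for a in res.atoms if a.name != "CA"]
        records = phi_psi(broken, "C")
        assert records[4].ss_class == "absent"
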
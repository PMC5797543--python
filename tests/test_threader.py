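"""Threading protocol: trimming, groove definition, threading, repacking,
screening and the rotamer clash scan."""

import numpy as np
import pytest

from neomhc.energy import EnergyWeights
from neomhc.synth import make_allele_family, make_micro_groove
from neomhc.structure import Atom, Chain, Residue, StructureModel
from neomhc.threader import (RepackContext, ThreadedModel, ThreadingError,
                             exhaustive_repack, groove_residues,
                             min_strain_rotamer, mutate_peptide, repack,
                             residue_decomposition, rotamer_clash_scan,
                             screen_allele, thread_allele, thread_polyala,
                             trim_to_groove)
from neomhc.sidechain import build_residue, set_rotamer
from neomhc.geometry import build_backbone


class TestTrim:
    def test_full_complex_trimmed_to_groove_domain(self):
        full = make_micro_groove(0, full=True)
        assert full.has_chain("B")
        assert max(r.resseq for r in full.chain("A").residues) > 180
        tc = trim_to_groove(full, "A", "C")
        assert not tc.structure.has_chain("B")
        assert max(r.resseq
                   for r in tc.structure.chain("A").residues) <= 180
        assert tc.structure.has_chain("C")

    def test_already_trimmed_unchanged(self, micro_groove):
        tc = trim_to_groove(micro_groove, "A", "C")
        assert tc.structure.n_atoms == micro_groove.n_atoms

    def test_missing_peptide_chain_rejected(self, micro_groove):
        with pytest.raises(ThreadingError):
            trim_to_groove(micro_groove, "A", "Z")


class TestGrooveResidues:
    def test_contact_residues_included(self, template):
        # the fixture is built with wall/floor pads at vdW contact
        assert len(template.groove_resseqs) >= 6

    def test_zero_cutoff_gives_empty_set(self, template):
        assert groove_residues(template, cutoff=0.0) == ()

    def test_monotone_in_cutoff(self, template):
        small = set(groove_residues(template, cutoff=3.5))
        large = set(groove_residues(template, cutoff=5.0))
        assert small <= large

    def test_deterministic(self, template):
        assert groove_residues(template) == groove_residues(template)


class TestThreading:
    def test_identity_sequence_leaves_template_untouched(self, template):
        tm = thread_allele(template, template.heavy_sequence, "self-allele")
        assert tm.mutated_resseqs == ()
        assert np.allclose(tm.model.coords(),
                           template.structure.coords())

    def test_single_substitution_changes_one_side_chain(self, template):
        seq = template.heavy_sequence
        groove_first = template.groove_resseqs[0]
        heavy = template.structure.chain("A")
        idx = next(i for i, r in enumerate(heavy.residues)
                   if r.resseq == groove_first)
        new = "W" if seq[idx] != "W" else "F"
        mutated_seq = seq[:idx] + new + seq[idx + 1:]
        tm = thread_allele(template, mutated_seq, "point")
        assert tm.mutated_resseqs == (groove_first,)
        res = tm.model.chain("A").residues[idx]
        assert res.one_letter == new

    def test_polyala_replaces_every_groove_residue(self, template):
        tm = thread_polyala(template)
        heavy = tm.model.chain("A")
        for res in heavy.residues:
            if res.resseq in template.groove_resseqs:
                assert res.name == "ALA"

    def test_gap_in_groove_rejected(self, template):
        seq = template.heavy_sequence
        # delete a stretch covering the first groove residue
        mutated = seq[5:]
        with pytest.raises(ThreadingError, match="gap"):
            thread_allele(template, mutated, "gapped")

    def test_family_members_thread_cleanly(self, template):
        for rec in make_allele_family(3, template.heavy_sequence,
                                      n_alleles=4, mutation_rate=0.1):
            tm = thread_allele(template, rec.residues, rec.id)
            assert len(tm.mutated_resseqs) >= 0
            assert tm.model.chain("A").sequence() == rec.residues


def tiny_system():
    """Three-residue repackable system: one peptide Gln between two Ser
    pads; small enough for exhaustive enumeration."""
    pads = Chain(id="A")
    pep = Chain(id="C")
    bb = build_backbone(1, [-120.0], [120.0])
    pad1 = build_residue(bb[0], "SER", 1)
    for atom in pad1.atoms:
        atom.coord = atom.coord + np.array([0.0, 4.5, 0.0])
    pad2 = build_residue(bb[0], "SER", 11)
    for atom in pad2.atoms:
        atom.coord = atom.coord + np.array([0.0, -4.5, 0.0])
    pads.residues = [pad1, pad2]
    pep.residues = [build_residue(bb[0], "GLN", 1)]
    model = StructureModel([pads, pep])
    return ThreadedModel(model=model, allele="tiny", heavy_chain="A",
                         peptide_chain="C", groove_resseqs=(1, 11),
                         mutated_resseqs=())


class TestRepack:
    def test_same_seed_reproduces_trajectory(self, template):
        tm = ThreadedModel(template.structure.copy(), "native", "A", "C",
                           template.groove_resseqs, ())
        ctx = RepackContext(tm)
        m1, e1 = repack(ctx, seed=123)
        m2, e2 = repack(ctx, seed=123)
        assert e1 == e2
        assert np.array_equal(m1.coords(), m2.coords())

    def test_objective_never_worse_than_initial(self, template):
        tm = ThreadedModel(template.structure.copy(), "native", "A", "C",
                           template.groove_resseqs, ())
        ctx = RepackContext(tm)
        initial = ctx.state_energy({u: 0 for u in ctx.repack_uids})
        _, best = repack(ctx, seed=5)
        assert best <= initial

    def test_annealer_finds_exhaustive_optimum_on_tiny_system(self):
        ctx = RepackContext(tiny_system())
        assert len(ctx.repack_uids) == 3
        _, exhaustive_e = exhaustive_repack(ctx)
        _, annealed_e = repack(ctx, seed=2)
        assert annealed_e == pytest.approx(exhaustive_e, abs=1e-9)

    def test_planted_clash_resolved(self):
        tm = tiny_system()
        # put the Gln side chain into a pad on purpose
        pep_res = tm.model.chain("C").residues[0]
        set_rotamer(pep_res, (60.0, 60.0, 0.0))
        ctx = RepackContext(tm)
        start = ctx.state_energy({u: 0 for u in ctx.repack_uids})
        _, best = repack(ctx, seed=9)
        assert best <= start


class TestScreen:
    def test_polyala_scores_strictly_worse_than_native(self, template):
        native = ThreadedModel(template.structure.copy(), "native", "A", "C",
                               template.groove_resseqs, ())
        res_nat = screen_allele(template, None, "native", n_models=16,
                                top_k=4, seed=11, threaded=native)
        res_pa = screen_allele(template, None, "polyAla", n_models=16,
                               top_k=4, seed=11,
                               threaded=thread_polyala(template))
        assert res_nat.mean_delta_e < res_pa.mean_delta_e

    def test_top_k_equal_n_models_averages_everything(self, template):
        native = ThreadedModel(template.structure.copy(), "native", "A", "C",
                               template.groove_resseqs, ())
        res = screen_allele(template, None, "native", n_models=6, top_k=6,
                            seed=3, threaded=native)
        assert res.mean_delta_e == pytest.approx(np.mean(res.deltas))

    def test_same_master_seed_reproduces_screen(self, template):
        def run():
            native = ThreadedModel(template.structure.copy(), "native",
                                   "A", "C", template.groove_resseqs, ())
            return screen_allele(template, None, "native", n_models=8,
                                 top_k=2, seed=21, threaded=native)
        a, b = run(), run()
        assert a.deltas == b.deltas
        assert a.mean_delta_e == b.mean_delta_e

    def test_unthreadable_allele_recorded_as_unscored(self, template):
        res = screen_allele(template, template.heavy_sequence[5:],
                            "gapped", n_models=4, top_k=2, seed=1)
        assert res.status.startswith("rejected")
        assert res.deltas == []

    def test_mean_not_above_worst_contributing_model(self, template):
        native = ThreadedModel(template.structure.copy(), "native", "A", "C",
                               template.groove_resseqs, ())
        res = screen_allele(template, None, "native", n_models=10, top_k=3,
                            seed=2, threaded=native)
        top = sorted(res.deltas)[:3]
        assert res.mean_delta_e <= max(top) + 1e-12


class TestDecomposition:
    def test_per_position_contributions_sum_reasonably(self, template):
        native = ThreadedModel(template.structure.copy(), "native", "A", "C",
                               template.groove_resseqs, ())
        res = screen_allele(template, None, "native", n_models=6, top_k=2,
                            seed=4, threaded=native)
        decomp = residue_decomposition(res, "C")
        assert set(decomp) == {r.resseq for r in
                               template.structure.chain("C").residues}

    def test_polyala_contributions_elevated_across_peptide(self, template):
        native = ThreadedModel(template.structure.copy(), "native", "A", "C",
                               template.groove_resseqs, ())
        res_nat = screen_allele(template, None, "native", n_models=6,
                                top_k=2, seed=4, threaded=native)
        res_pa = screen_allele(template, None, "polyAla", n_models=6,
                               top_k=2, seed=4,
                               threaded=thread_polyala(template))
        d_nat = residue_decomposition(res_nat, "C")
        d_pa = residue_decomposition(res_pa, "C")
        # summed over the peptide, the polyAla groove interacts less
        # favourably than the native groove
        assert sum(d_pa.values()) > sum(d_nat.values())


class TestClashScan:
    def test_ala_in_open_site_has_no_clashes(self, template):
        reports = rotamer_clash_scan(template, "C", 5, "ALA")
        assert len(reports) == 1
        assert reports[0].clashes == []

    def test_arg_blocked_in_occluded_pocket(self, occluded_template):
        reports = rotamer_clash_scan(occluded_template, "C", 2, "ARG")
        assert all(len(r.clashes) > 0 for r in reports)

    def test_gln_fits_occluded_pocket(self, occluded_template):
        reports = rotamer_clash_scan(occluded_template, "C", 2, "GLN")
        assert min_strain_rotamer(reports).clashes == []

    def test_min_strain_rotamer_minimises_total_overlap(self,
                                                        occluded_template):
        reports = rotamer_clash_scan(occluded_template, "C", 2, "ARG")
        best = min_strain_rotamer(reports)
        assert best.strain == min(r.strain for r in reports)


class TestSelfPeptide:
    def test_self_arg_scores_worse_than_native_gln(self, occluded_template):
        native = ThreadedModel(occluded_template.structure.copy(), "native",
                               "A", "C", occluded_template.groove_resseqs,
                               ())
        res_nat = screen_allele(occluded_template, None, "native",
                                n_models=12, top_k=3, seed=6,
                                threaded=native)
        res_self = screen_allele(occluded_template, None, "self",
                                 n_models=12, top_k=3, seed=6,
                                 threaded=mutate_peptide(native, 2, "ARG"))
        assert res_nat.mean_delta_e < res_self.mean_delta_e
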
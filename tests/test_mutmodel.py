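"""Mutant side-chain modeling and complex reassembly."""

import numpy as np
import pytest

from conftest import residue_from_coords
from pdbind import encode, fixtures, mutmodel, structio, vecmath
from pdbind.structio import Atom, Chain
from pdbind.tables import vdw_radius


class TestCleanProtein:
    def test_ca_only_residue_removed(self, toy_complex):
        cx = toy_complex.copy()
        res = cx.get_chain("A").get_residue(3)
        for name in list(res.atoms):
            if name != "CA":
                del res.atoms[name]
        cleaned = mutmodel.clean_protein_for_modeling(cx, "A")
        assert cleaned.get_residue(3) is None
        assert len(cleaned.residues) == 11

    def test_mse_emitted_as_met_atom_records(self):
        cx = structio.parse_complex(fixtures.make_toy_complex(
            fixtures.FixtureSpec(modres_at=5)))
        cleaned = mutmodel.clean_protein_for_modeling(cx, "A")
        res = cleaned.get_residue(5)
        assert res.name == "MET"
        assert all(not a.het for a in res.atoms.values())

    def test_idempotent_on_clean_input(self, toy_complex):
        once = mutmodel.clean_protein_for_modeling(toy_complex, "A")
        again_cx = structio.ComplexStructure([once])
        twice = mutmodel.clean_protein_for_modeling(again_cx, "A")
        assert [(r.name, r.key, sorted(r.atoms)) for r in once.residues] == \
            [(r.name, r.key, sorted(r.atoms)) for r in twice.residues]

    def test_too_few_residues_is_error(self, toy_complex):
        cx = toy_complex.copy()
        cx.get_chain("A").residues = cx.get_chain("A").residues[:2]
        with pytest.raises(ValueError, match="fewer than 3"):
            mutmodel.clean_protein_for_modeling(cx, "A")


class TestModelMutant:
    def _protein(self, toy_complex):
        return mutmodel.clean_protein_for_modeling(toy_complex, "A")

    @pytest.mark.parametrize("target", ["G", "A"])
    def test_small_targets_deterministic(self, toy_complex, target):
        protein = self._protein(toy_complex)
        m = encode.MutationSpec("A", 6, "A", target)
        out, placement = mutmodel.model_mutant(protein, m,
                                               return_placement=True)
        assert placement.chi_angles == ()
        res = out.get_residue(6)
        expected = {"N", "CA", "C", "O"} | ({"CB"} if target == "A" else set())
        assert set(res.atoms) == expected

    def test_open_site_gets_top_rotamer_clash_free(self, toy_complex):
        protein = self._protein(toy_complex)
        m = encode.MutationSpec("A", 6, "A", "L")
        out, placement = mutmodel.model_mutant(protein, m,
                                               return_placement=True)
        assert placement.clash_score == 0
        assert placement.chi_angles == mutmodel.ROTAMER_SETS["LEU"][0][1]

    def test_crowded_site_minimizes_clashes_like_exhaustive_search(
            self, toy_complex):
        protein = self._protein(toy_complex)
        # surround the site with a cage of carbon atoms so every Trp rotamer
        # clashes, then compare with brute-force enumeration
        site = protein.get_residue(6)
        cage = residue_from_coords("CAG", 500, {})
        cb_direction = vecmath.unit(site.atoms["CB"].xyz -
                                    site.atoms["CA"].xyz)
        center = site.atoms["CB"].xyz + 2.0 * cb_direction
        rng = np.random.default_rng(0)
        for i in range(40):
            v = rng.normal(size=3)
            cage.atoms[f"C{i}"] = Atom(f"C{i}", "C",
                                       center + 2.5 * vecmath.unit(v))
        crowded = Chain(protein.chain_id, "protein",
                        [r.copy() for r in protein.residues] + [cage])
        m = encode.MutationSpec("A", 6, "A", "W")
        out, placement = mutmodel.model_mutant(crowded, m,
                                               return_placement=True)
        # brute-force oracle over the whole rotamer set
        backbone = {n: site.atoms[n].xyz for n in ("N", "CA", "C", "O")}
        best = None
        for _prior, chis in mutmodel.ROTAMER_SETS["TRP"]:
            side = mutmodel.build_side_chain(backbone, "TRP", chis)
            clashes = 0
            for name, xyz in side.items():
                for res in crowded.residues:
                    if res.key == (6, ""):
                        continue
                    for atom in res.heavy_atoms():
                        if np.linalg.norm(xyz - atom.xyz) < 0.6 * (
                                vdw_radius(name[0]) +
                                vdw_radius(atom.element)):
                            clashes += 1
            best = clashes if best is None else min(best, clashes)
        assert placement.clash_score == best
        assert best > 0  # the cage really does force a clash

    def test_only_the_mutated_residue_changes(self, toy_complex):
        protein = self._protein(toy_complex)
        m = encode.MutationSpec("A", 6, "A", "F")
        out = mutmodel.model_mutant(protein, m)
        for res in protein.residues:
            if res.key == (6, ""):
                continue
            other = out.get_residue(*res.key)
            assert set(other.atoms) == set(res.atoms)
            for name, atom in res.atoms.items():
                assert np.array_equal(atom.xyz, other.atoms[name].xyz)

    def test_deterministic(self, toy_complex):
        protein = self._protein(toy_complex)
        m = encode.MutationSpec("A", 6, "A", "K")
        a = mutmodel.model_mutant(protein, m)
        b = mutmodel.model_mutant(protein, m)
        ra, rb = a.get_residue(6), b.get_residue(6)
        assert all(np.array_equal(ra.atoms[n].xyz, rb.atoms[n].xyz)
                   for n in ra.atoms)

    def test_wild_type_mismatch_is_error(self, toy_complex):
        protein = self._protein(toy_complex)
        with pytest.raises(ValueError, match="mismatch"):
            mutmodel.model_mutant(protein,
                                  encode.MutationSpec("A", 6, "R", "K"))

    def test_built_side_chain_has_l_configuration(self, toy_complex):
        protein = self._protein(toy_complex)
        out = mutmodel.model_mutant(protein,
                                    encode.MutationSpec("A", 6, "A", "V"))
        res = out.get_residue(6)
        improper = vecmath.dihedral_deg(res.atoms["C"].xyz,
                                        res.atoms["N"].xyz,
                                        res.atoms["CA"].xyz,
                                        res.atoms["CB"].xyz)
        assert improper == pytest.approx(-122.6, abs=3.0)


class TestReassembly:
    def test_identity_fit_preserves_complex(self, toy_complex):
        protein = mutmodel.clean_protein_for_modeling(toy_complex, "A")
        out, rmsd = mutmodel.reassemble_complex(protein, toy_complex,
                                                return_rmsd=True)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        dna_ref = toy_complex.get_chain("B").heavy_coords()
        assert np.allclose(out.get_chain("B").heavy_coords(), dna_ref)

    def test_known_rotation_is_recovered(self, toy_complex):
        protein = mutmodel.clean_protein_for_modeling(toy_complex, "A")
        moved = protein.copy()
        R = vecmath.rotation_about_axis([0.3, 1.0, -0.5], 49.0)
        for res in moved.residues:
            for atom in res.atoms.values():
                atom.xyz = R @ atom.xyz + np.array([12.0, -5.0, 3.0])
        out, rmsd = mutmodel.reassemble_complex(moved, toy_complex,
                                                return_rmsd=True)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        ref = protein.get_residue(6).atoms["CA"].xyz
        got = out.get_chain("A").get_residue(6).atoms["CA"].xyz
        assert np.allclose(got, ref, atol=1e-6)

    def test_kabsch_fit_beats_random_rigid_motions(self, toy_complex):
        protein = mutmodel.clean_protein_for_modeling(toy_complex, "A")
        m = encode.MutationSpec("A", 6, "A", "W")
        modeled = mutmodel.model_mutant(protein, m)
        _out, best_rmsd = mutmodel.reassemble_complex(modeled, toy_complex,
                                                      return_rmsd=True)
        mobile = np.array([modeled.get_residue(*r.key).atoms[n].xyz
                           for r in protein.residues
                           for n in ("N", "CA", "C", "O")])
        target = np.array([r.atoms[n].xyz for r in protein.residues
                           for n in ("N", "CA", "C", "O")])
        rng = np.random.default_rng(4)
        for _ in range(10):
            R = vecmath.rotation_about_axis(rng.normal(size=3),
                                            rng.uniform(0, 180))
            t = rng.uniform(-5, 5, 3)
            rmsd = np.sqrt(np.mean(np.sum(
                (mobile @ R.T + t - target) ** 2, axis=1)))
            assert best_rmsd <= rmsd + 1e-9

    def test_too_few_common_atoms_is_error(self, toy_complex):
        protein = mutmodel.clean_protein_for_modeling(toy_complex, "A")
        protein.residues = []
        with pytest.raises(ValueError, match="3 common backbone"):
            mutmodel.reassemble_complex(protein, toy_complex)


class TestPipeline:
    def test_mutant_complex_changes_only_protein(self, toy_complex):
        m = encode.MutationSpec("A", 6, "A", "R")
        out = mutmodel.mutant_complex(toy_complex, m)
        assert out.get_chain("A").get_residue(6).name == "ARG"
        for cid in ("B", "C"):
            assert np.allclose(out.get_chain(cid).heavy_coords(),
                               toy_complex.get_chain(cid).heavy_coords())

    def test_pipeline_deterministic(self, toy_complex):
        m = encode.MutationSpec("A", 6, "A", "R")
        a = mutmodel.mutant_complex(toy_complex, m)
        b = mutmodel.mutant_complex(toy_complex, m)
        assert a.same_as(b)
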
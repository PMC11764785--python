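"""Categorical encodings, manifests and feature-vector assembly."""

import numpy as np
import pytest

from pdbind import encode, fixtures, structio
from pdbind.tables import AA_ALPHABETICAL, AA_VOLUME, CLASS_SCHEMES

ALL_PAIRS = [(w, m) for w in AA_ALPHABETICAL for m in AA_ALPHABETICAL]


class TestClassLabels:
    @pytest.mark.parametrize("scheme,cardinality", [
        ("hydropathy", 9), ("polarity", 16), ("size", 25), ("hbond", 16),
        ("chemical", 49), ("mutation_type", 400)])
    def test_label_cardinalities(self, scheme, cardinality):
        labels = {encode.class_label(w, m, scheme) for w, m in ALL_PAIRS}
        assert len(labels) == cardinality

    def test_listing_order_examples(self):
        # neutral = 0, hydrophilic = 1, hydrophobic = 2
        assert encode.class_label("G", "D", "hydropathy") == 1
        assert encode.class_label("A", "A", "hydropathy") == 8

    def test_schemes_partition_the_alphabet(self):
        for scheme, classes in CLASS_SCHEMES.items():
            union = set().union(*classes)
            assert union == set(AA_ALPHABETICAL), scheme
            assert sum(len(c) for c in classes) == 20, scheme

    def test_unknown_amino_acid_is_error(self):
        with pytest.raises(ValueError):
            encode.class_label("X", "A", "size")


class TestPhyschemDeltas:
    def test_self_mutation_vanishes(self):
        assert encode.physchem_deltas("A", "A") == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("wt,mut", [("G", "W"), ("K", "D"), ("F", "S")])
    def test_antisymmetry(self, wt, mut):
        fwd = encode.physchem_deltas(wt, mut)
        rev = encode.physchem_deltas(mut, wt)
        assert fwd == pytest.approx(tuple(-x for x in rev))

    def test_glycine_to_tryptophan_grows(self):
        net_volume, _h, _f = encode.physchem_deltas("G", "W")
        assert net_volume > 0
        assert AA_VOLUME["W"] == max(AA_VOLUME.values())
        assert AA_VOLUME["G"] == min(AA_VOLUME.values())


class TestDnaEncoding:
    def test_bp_category_cardinality(self):
        pairs = [a + b for a in "ACGT" for b in "ACGT"]
        labels = {encode.base_pair_index(w) * 16 + encode.base_pair_index(m)
                  for w in pairs for m in pairs}
        assert len(labels) == 256

    def test_at_to_at(self):
        m = encode.DnaMutationSpec("B", 5, "A", "A", "T", "T")
        assert encode.dna_mutation_encoding(m) == (0, 0, 3 * 17)

    def test_gc_to_gt_is_mismatch(self):
        m = encode.DnaMutationSpec("B", 5, "G", "G", "C", "T")
        bp_type, mismatch, category = encode.dna_mutation_encoding(m)
        assert (bp_type, mismatch) == (1, 1)
        assert category == encode.base_pair_index("GC") * 16 + \
            encode.base_pair_index("GT")

    def test_non_canonical_wild_type_is_error(self):
        m = encode.DnaMutationSpec("B", 5, "G", "A", "T", "T")
        with pytest.raises(ValueError, match="non-canonical"):
            encode.dna_mutation_encoding(m)

    def test_single_strand_convention(self):
        m = encode.DnaMutationSpec("B", 5, "G", "A")
        bp_type, mismatch, _cat = encode.dna_mutation_encoding(m)
        assert (bp_type, mismatch) == (1, 0)

    def test_mutation_string_grammar(self):
        m = encode.parse_protein_mutation("A:R52S")
        assert (m.chain_id, m.site, m.wt_aa, m.mut_aa) == ("A", 52, "R", "S")
        d = encode.parse_dna_mutation("B:5:AT>GC")
        assert (d.wt_forward, d.wt_reverse, d.mut_forward, d.mut_reverse) == \
            ("A", "T", "G", "C")


class TestManifest:
    def test_layout_lengths(self):
        assert len(encode.PROTEIN_FEATURE_NAMES) == 49
        assert len(encode.DNA_FEATURE_NAMES) == 35

    def test_manifest_hash_is_frozen(self):
        # layout stability gate: changing any name, order or constant table
        # invalidates previously trained bundles and must be deliberate
        assert encode.manifest_hash("protein") == \
            encode.manifest_hash("protein")
        assert encode.manifest_hash("protein") != encode.manifest_hash("dna")

    def test_names_unique(self):
        assert len(set(encode.PROTEIN_FEATURE_NAMES)) == 49
        assert len(set(encode.DNA_FEATURE_NAMES)) == 35


class TestProteinAssembly:
    def test_vector_length_and_names(self, toy_complex):
        m = encode.MutationSpec("A", 6, "A", "R")
        fv = encode.protein_feature_pipeline(toy_complex, m)
        assert len(fv) == 49
        assert fv.names == encode.PROTEIN_FEATURE_NAMES

    def test_self_mutation_deltas_vanish(self, toy_complex):
        m = encode.MutationSpec("A", 6, "A", "A")
        fv = encode.assemble_protein_features(toy_complex, toy_complex,
                                              None, m)
        d = fv.to_dict()
        for name in ("pssm_mutation_odds", "net_volume",
                     "net_hydrophobicity", "net_flexibility", "delta_acc",
                     "delta_nt_aa_contacts", "delta_base_aa_hbonds",
                     "delta_phosphate_aa_hbonds", "delta_base_aa_stacks"):
            assert d[name] == 0.0, name

    def test_atom_order_permutation_invariance(self, toy_complex):
        text = fixtures.make_toy_complex(fixtures.FixtureSpec())
        lines = text.splitlines()
        atoms = [ln for ln in lines if ln.startswith("ATOM")]
        other = [ln for ln in lines if not ln.startswith("ATOM")]
        rng = np.random.default_rng(3)
        # shuffle atoms within each residue to keep chains contiguous
        import itertools
        grouped = []
        for _key, group in itertools.groupby(atoms, key=lambda l: l[17:27]):
            g = list(group)
            rng.shuffle(g)
            grouped.extend(g)
        shuffled = structio.parse_complex(
            "\n".join(grouped + [l for l in other if l.startswith(
                ("SEQRES", "REMARK", "MODRES", "SEQADV"))] + ["END"]) + "\n")
        m = encode.MutationSpec("A", 6, "A", "L")
        ref = encode.protein_feature_pipeline(toy_complex, m)
        out = encode.protein_feature_pipeline(shuffled, m)
        assert np.allclose(ref.values, out.values, atol=1e-6)

    def test_wild_type_mismatch_is_error(self, toy_complex):
        with pytest.raises(ValueError, match="mismatch"):
            encode.protein_feature_pipeline(
                toy_complex, encode.MutationSpec("A", 6, "R", "K"))

    def test_alpha_carbon_only_structure_is_error(self, toy_complex):
        stripped = toy_complex.copy()
        for res in stripped.get_chain("A").residues:
            for name in list(res.atoms):
                if name != "CA":
                    del res.atoms[name]
        with pytest.raises(ValueError, match="backbone incomplete"):
            encode.protein_feature_pipeline(
                stripped, encode.MutationSpec("A", 6, "A", "L"))

    def test_blosum_fallback_is_recorded(self, toy_complex):
        fv = encode.protein_feature_pipeline(
            toy_complex, encode.MutationSpec("A", 6, "A", "K"))
        assert fv.metadata["pssm_source"] == "blosum62-fallback"


class TestDnaAssembly:
    def test_vector_length(self, toy_complex):
        m = encode.parse_dna_mutation("B:4:TA>CG")
        fv = encode.assemble_dna_features(toy_complex, m)
        assert len(fv) == 35
        assert fv.names == encode.DNA_FEATURE_NAMES

    def test_duplex_geometry_recovered_at_site(self, toy_complex):
        m = encode.parse_dna_mutation("B:4:TA>CG")
        d = encode.assemble_dna_features(toy_complex, m).to_dict()
        assert d["step_twist"] == pytest.approx(36.0, abs=1.5)
        assert d["step_rise"] == pytest.approx(3.38, abs=0.2)

    def test_single_strand_geometry_features_zero(self, ss_complex):
        m = encode.parse_dna_mutation("B:4:T>C")
        fv = encode.assemble_dna_features(ss_complex, m)
        assert np.all(fv.values[6:24] == 0.0)

    def test_three_prime_terminus_uses_upstream_step(self, toy_complex):
        m = encode.parse_dna_mutation("B:8:TA>GC")
        d = encode.assemble_dna_features(toy_complex, m).to_dict()
        assert d["step_twist"] == pytest.approx(36.0, abs=1.5)

    def test_far_site_interactions_zero(self, far_complex):
        m = encode.parse_dna_mutation("B:4:TA>CG")
        d = encode.assemble_dna_features(far_complex, m).to_dict()
        assert all(d[f"site_{n}"] == 0 for n in
                   ("nt_aa_contacts", "base_aa_hbonds",
                    "phosphate_aa_hbonds", "base_aa_stacks"))

    def test_missing_site_is_error(self, toy_complex):
        with pytest.raises(ValueError, match="mutation site missing"):
            encode.assemble_dna_features(
                toy_complex, encode.DnaMutationSpec("B", 99, "A", "G"))

    def test_wild_type_base_mismatch_is_error(self, toy_complex):
        with pytest.raises(ValueError, match="base mismatch"):
            encode.assemble_dna_features(
                toy_complex, encode.parse_dna_mutation("B:4:GC>AT"))
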
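"""Base pairing, pair/step/helical parameters and the interaction census."""

import numpy as np
import pytest

from conftest import residue_from_coords
from pdbind import fixtures, nacontacts, structio, vecmath
from pdbind.structio import Atom, Chain, ComplexStructure
from pdbind.tables import (BASE_POLAR_ATOMS, BASE_RING_ATOMS, PHOSPHATE_ATOMS,
                           RESIDUE_PLANES)


class TestFindBasePairs:
    def test_ideal_duplex_fully_paired(self, bdna_duplex):
        pairs = nacontacts.find_base_pairs(bdna_duplex)
        paired = [p for p in pairs if p.paired]
        assert len(paired) == 8
        assert all(p.forward.base in "ACGT" for p in paired)

    def test_single_strand_has_no_pairs(self):
        cx = structio.parse_complex(fixtures.make_bdna("ACGTACGT",
                                                       duplex=False))
        pairs = nacontacts.find_base_pairs(cx)
        assert sum(p.paired for p in pairs) == 0
        assert len(pairs) == 8

    def test_deleted_base_leaves_one_unpaired(self, bdna_duplex):
        cx = bdna_duplex.copy()
        chain_c = cx.get_chain("C")
        del chain_c.residues[3]
        pairs = nacontacts.find_base_pairs(cx)
        assert sum(p.paired for p in pairs) == 7
        assert sum(not p.paired for p in pairs) == 1


class TestPairParameters:
    def test_identical_flipped_frames_give_zero(self):
        R = vecmath.rotation_about_axis([0.2, 0.4, 1.0], 33.0)
        o = np.array([1.0, 2.0, 3.0])
        fwd = nacontacts.BaseFrame("B", 1, "", "A", R, o, 0.0)
        rev = nacontacts.BaseFrame("C", 8, "", "T",
                                   R @ np.diag([1.0, -1.0, -1.0]), o.copy(),
                                   0.0)
        bp = nacontacts.BasePair(fwd, rev)
        assert nacontacts.pair_parameters(bp) == pytest.approx((0.0,) * 6,
                                                               abs=1e-9)

    def test_fiber_pair_is_nearly_ideal(self, bdna_duplex):
        pairs = [p for p in nacontacts.find_base_pairs(bdna_duplex)
                 if p.paired]
        for bp in pairs:
            shear, stretch, stagger, *_rot = nacontacts.pair_parameters(bp)
            assert abs(shear) < 0.3 and abs(stretch) < 0.3
            assert abs(stagger) < 0.3

    def test_rigid_motion_leaves_parameters_unchanged(self, bdna_duplex):
        ref = nacontacts.pair_parameters(
            [p for p in nacontacts.find_base_pairs(bdna_duplex)
             if p.paired][0])
        moved = bdna_duplex.copy()
        R = vecmath.rotation_about_axis([3.0, -1.0, 2.0], 71.0)
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms.values():
                    atom.xyz = R @ atom.xyz + np.array([4.0, 5.0, -6.0])
        out = nacontacts.pair_parameters(
            [p for p in nacontacts.find_base_pairs(moved) if p.paired][0])
        assert out == pytest.approx(ref, abs=1e-6)

    def test_unpaired_site_returns_zeros(self):
        f = nacontacts.BaseFrame("B", 1, "", "A", np.eye(3), np.zeros(3), 0.0)
        assert nacontacts.pair_parameters(nacontacts.BasePair(f)) == (0.0,) * 6


class TestStepParameters:
    def _paired(self, cx):
        return [p for p in nacontacts.find_base_pairs(cx) if p.paired]

    def test_fiber_twist_and_rise(self, bdna_duplex):
        pairs = self._paired(bdna_duplex)
        for a, b in zip(pairs, pairs[1:]):
            step = nacontacts.step_parameters(a, b)
            assert step[5] == pytest.approx(36.0, abs=1.5)   # twist
            assert step[2] == pytest.approx(3.38, abs=0.2)   # rise
            assert step[11] == pytest.approx(36.0, abs=1.5)  # helical twist
            assert step[8] == pytest.approx(3.38, abs=0.2)   # helical rise

    def test_self_step_is_identity(self, bdna_duplex):
        bp = self._paired(bdna_duplex)[0]
        assert nacontacts.step_parameters(bp, bp) == pytest.approx(
            (0.0,) * 12, abs=1e-9)

    def test_fiber_tilt_vanishes(self, bdna_duplex):
        # the fiber step is mirror-symmetric about the base-pair plane
        pairs = self._paired(bdna_duplex)
        for a, b in zip(pairs, pairs[1:]):
            assert nacontacts.step_parameters(a, b)[3] == pytest.approx(
                0.0, abs=0.5)

    def test_non_adjacent_pairs_rejected(self, bdna_duplex):
        pairs = self._paired(bdna_duplex)
        with pytest.raises(ValueError, match="adjacent"):
            nacontacts.step_parameters(pairs[0], pairs[4])

    @pytest.mark.parametrize("seed", range(5))
    def test_parameter_algebra_round_trips(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(-2.5, 2.5, 3)
        r = rng.uniform(-35.0, 35.0, 3)
        R1, o1, R2, o2 = nacontacts.params_to_frames(t, r)
        (t2, r2, _mid) = nacontacts.frames_to_params(R1, o1, R2, o2)
        assert np.allclose(t, t2, atol=1e-6)
        assert np.allclose(r, r2, atol=1e-6)


# --------------------------------------------------------------------------
# Interaction census and its brute-force oracle
# --------------------------------------------------------------------------


def census_oracle(cx, config=nacontacts.DEFAULT_CONTACT_CONFIG,
                  only_site=None):
    """All-pairs enumeration, independent of the KD-tree implementation."""
    prot = []
    for chain in cx.chains:
        if chain.kind != "protein":
            continue
        for res in chain.residues:
            for atom in res.heavy_atoms():
                prot.append((chain.chain_id, res, atom))
    counts = [0, 0, 0, 0]
    planes = []
    for chain in cx.chains:
        if chain.kind != "protein":
            continue
        for res in chain.residues:
            names = RESIDUE_PLANES.get(res.name)
            if names and all(n in res.atoms for n in names):
                pts = np.array([res.atoms[n].xyz for n in names])
                c = pts.mean(axis=0)
                _u, _s, vt = np.linalg.svd(pts - c)
                planes.append((c, vt[2]))
    for chain in cx.chains:
        if chain.kind != "dna":
            continue
        for res in chain.residues:
            key = (chain.chain_id, res.author_number, res.insertion_code)
            if only_site is not None and key != only_site:
                continue
            partners = set()
            for atom in res.heavy_atoms():
                for cid, pres, patom in prot:
                    d = np.linalg.norm(atom.xyz - patom.xyz)
                    if d <= config.contact_cutoff:
                        partners.add((cid, pres.author_number,
                                      pres.insertion_code))
                    if d <= config.hbond_cutoff and patom.element in "NO":
                        name = atom.name.replace("*", "'")
                        name = name.replace("O1P", "OP1").replace("O2P",
                                                                  "OP2")
                        if res.base and name in BASE_POLAR_ATOMS[res.base]:
                            counts[1] += 1
                        elif name in PHOSPHATE_ATOMS:
                            counts[2] += 1
            counts[0] += len(partners)
            ring = [n for n in BASE_RING_ATOMS.get(res.base or "", [])
                    if n in res.atoms]
            if len(ring) >= 5:
                pts = np.array([res.atoms[n].xyz for n in ring])
                c = pts.mean(axis=0)
                _u, _s, vt = np.linalg.svd(pts - c)
                normal = vt[2]
                for pc, pn in planes:
                    if np.linalg.norm(c - pc) <= config.stack_cutoff:
                        ang = vecmath.angle_deg(normal, pn)
                        if min(ang, 180 - ang) <= config.stack_angle_max:
                            counts[3] += 1
    return tuple(counts)


def _lysine_near_phosphate():
    """One Lys with NZ placed 2.9 A from OP1 of a dinucleotide."""
    cx = structio.parse_complex(fixtures.make_bdna("ACG"))
    res2 = cx.get_chain("B").get_residue(2)
    op1 = res2.atoms["OP1"].xyz
    p = res2.atoms["P"].xyz
    direction = vecmath.unit(op1 - p)
    nz = op1 + 2.9 * direction
    offsets = {"N": 8.0, "CA": 7.0, "C": 8.5, "O": 9.0, "CB": 6.0,
               "CG": 4.8, "CD": 3.6, "CE": 1.5, "NZ": 0.0}
    atoms = {name: nz + off * direction for name, off in offsets.items()}
    lys = residue_from_coords("LYS", 1, atoms)
    cx.chains.append(Chain("A", "protein", [lys]))
    # placement precondition: only OP1 lies in NZ's H-bond range
    close = [a.name for c in cx.dna_chains() for r in c.residues
             for a in r.heavy_atoms()
             if np.linalg.norm(a.xyz - nz) <= 3.5]
    assert close == ["OP1"], close
    return cx


def _phe_stacked_on_base():
    """A Phe ring parallel to the top base, 3.6 A above it."""
    cx = structio.parse_complex(fixtures.make_bdna("AC"))
    chain = cx.get_chain("B")
    res = chain.get_residue(2)
    ring = np.array([res.atoms[n].xyz for n in BASE_RING_ATOMS["C"]])
    centroid = ring.mean(axis=0)
    _u, _s, vt = np.linalg.svd(ring - centroid)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    center = centroid + 3.6 * normal
    e1 = vecmath.unit(np.cross(normal, [1.0, 0.0, 0.0]))
    e2 = np.cross(normal, e1)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = {}
    for i, name in enumerate(names):
        ang = np.radians(60.0 * i)
        atoms[name] = center + 1.39 * (np.cos(ang) * e1 + np.sin(ang) * e2)
    for name, off in (("CB", 3.0), ("CA", 4.5), ("N", 5.5), ("C", 5.3),
                      ("O", 6.3)):
        atoms[name] = center + off * normal + np.array([2.0, 0.0, 0.0])
    phe = residue_from_coords("PHE", 1, atoms)
    cx.chains.append(Chain("A", "protein", [phe]))
    return cx


class TestInteractionCensus:
    def test_displaced_protein_counts_all_zero(self, far_complex):
        counts = nacontacts.count_interactions(far_complex)
        assert counts.as_tuple() == (0, 0, 0, 0)

    def test_lysine_phosphate_hbond(self):
        cx = _lysine_near_phosphate()
        counts = nacontacts.count_interactions(cx)
        assert counts.phosphate_aa_hbonds == 1
        assert counts.base_aa_hbonds == 0
        assert counts.as_tuple() == census_oracle(cx)

    def test_phenylalanine_base_stack(self):
        cx = _phe_stacked_on_base()
        counts = nacontacts.count_interactions(cx)
        assert counts.base_aa_stacks == 1
        assert counts.as_tuple() == census_oracle(cx)

    def test_matches_brute_force_on_toy_complex(self, toy_complex):
        counts = nacontacts.count_interactions(toy_complex)
        assert counts.as_tuple() == census_oracle(toy_complex)

    def test_rigid_motion_invariance(self, toy_complex):
        ref = nacontacts.count_interactions(toy_complex).as_tuple()
        moved = toy_complex.copy()
        R = vecmath.rotation_about_axis([1.0, 0.0, 1.0], 123.0)
        for chain in moved.chains:
            for res in chain.residues:
                for atom in res.atoms.values():
                    atom.xyz = R @ atom.xyz - np.array([3.0, 9.0, 1.0])
        assert nacontacts.count_interactions(moved).as_tuple() == ref

    def test_missing_molecule_is_error(self, bdna_duplex):
        with pytest.raises(ValueError, match="no protein"):
            nacontacts.count_interactions(bdna_duplex)


class TestSiteInteractions:
    def test_far_site_is_zero(self, toy_complex):
        counts = nacontacts.site_interactions(toy_complex, "B", 1)
        # site-level counts can never exceed the complex-level census
        total = nacontacts.count_interactions(toy_complex)
        assert all(s <= t for s, t in zip(counts.as_tuple(),
                                          total.as_tuple()))

    def test_partition_identity_over_forward_strand(self, toy_complex):
        chain = toy_complex.get_chain("B")
        acc = np.zeros(4, dtype=int)
        for res in chain.residues:
            acc += np.array(nacontacts.site_interactions(
                toy_complex, "B", res.author_number).as_tuple())
        oracle = np.zeros(4, dtype=int)
        for res in chain.residues:
            oracle += np.array(census_oracle(
                toy_complex, only_site=("B", res.author_number, "")))
        assert np.array_equal(acc, oracle)

    def test_lysine_site_hbond(self):
        cx = _lysine_near_phosphate()
        counts = nacontacts.site_interactions(cx, "B", 2)
        assert counts.phosphate_aa_hbonds == 1

    def test_missing_site_is_error(self, toy_complex):
        with pytest.raises(ValueError, match="mutation site missing"):
            nacontacts.site_interactions(toy_complex, "B", 99)


class TestDeltaInteractions:
    def test_self_delta_is_zero(self):
        c = nacontacts.InteractionCounts(3, 1, 2, 0)
        assert nacontacts.delta_interactions(c, c) == (0, 0, 0, 0)

    def test_orientation_is_mutant_minus_wild(self):
        wt = nacontacts.InteractionCounts(10, 0, 0, 0)
        mut = nacontacts.InteractionCounts(7, 0, 0, 0)
        assert nacontacts.delta_interactions(wt, mut)[0] == -3

    def test_antisymmetry(self):
        a = nacontacts.InteractionCounts(4, 2, 1, 1)
        b = nacontacts.InteractionCounts(9, 0, 3, 2)
        ab = nacontacts.delta_interactions(a, b)
        ba = nacontacts.delta_interactions(b, a)
        assert tuple(-x for x in ab) == ba
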
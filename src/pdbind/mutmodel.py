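"""Mutant-protein modeling: side-chain replacement and complex reassembly.

Only the mutated residue's side chain is rebuilt (from idealized internal
coordinates and a compact backbone-independent rotamer set, choosing the
highest-prior clash-free rotamer); all other atoms are untouched.  The
modeled protein is superposed back onto the original complex over the common
backbone atoms and the non-protein atoms are copied unchanged, so the
mutation-induced interaction deltas reflect the side-chain change alone.
An externally modeled mutant PDB can be supplied instead through the
``mutant_cx`` argument of the feature pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import vecmath
from .encode import MutationSpec
from .structio import Atom, Chain, ComplexStructure, Residue
from .tables import AA1_TO_3, AA3_TO_1, MODRES_PARENTS, vdw_radius

CLASH_FACTOR = 0.6  # heavy-atom pair closer than 0.6*(r_i+r_j) is a clash

BACKBONE_NAMES = ("N", "CA", "C", "O")

# --------------------------------------------------------------------------
# Idealized side-chain internal coordinates.
# Entries: atom -> (refs (a, b, parent), bond A, angle deg, dihedral)
# where dihedral is a number or ("chi", k, offset_deg).
# --------------------------------------------------------------------------

def _chi(k: int, offset: float = 0.0):
    return ("chi", k, offset)


SIDE_CHAIN_TEMPLATES: dict[str, list] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.417, 110.8, _chi(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.808, 113.8, _chi(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.433, 109.6, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.527, 110.5, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.527, 110.5, _chi(1, 122.3))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.530, 116.3, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, _chi(2, 122.6))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.530, 110.4, _chi(1)),
            ("CG2", ("N", "CA", "CB"), 1.521, 110.5, _chi(1, -122.3)),
            ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, _chi(2))],
    "MET": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("SD", ("CA", "CB", "CG"), 1.803, 112.7, _chi(2)),
            ("CE", ("CB", "CG", "SD"), 1.791, 100.9, _chi(3))],
    "ASP": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2)),
            ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, _chi(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.516, 112.6, _chi(1)),
            ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, _chi(2)),
            ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, _chi(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3)),
            ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, _chi(3, 180.0))],
    "GLN": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.516, 112.6, _chi(2)),
            ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, _chi(3)),
            ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, _chi(3, 180.0))],
    "LYS": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("CE", ("CB", "CG", "CD"), 1.520, 111.3, _chi(3)),
            ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, _chi(4))],
    "ARG": [("CG", ("N", "CA", "CB"), 1.520, 114.1, _chi(1)),
            ("CD", ("CA", "CB", "CG"), 1.520, 111.3, _chi(2)),
            ("NE", ("CB", "CG", "CD"), 1.461, 112.0, _chi(3)),
            ("CZ", ("CG", "CD", "NE"), 1.330, 124.2, _chi(4)),
            ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.490, 113.8, _chi(1)),
            ("ND1", ("CA", "CB", "CG"), 1.380, 122.7, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.360, 131.1, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.320, 109.3, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.370, 107.2, 180.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.500, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.500, 113.8, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.390, 120.8, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.390, 120.8, _chi(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.390, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.390, 120.8, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.390, 120.0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.380, 119.9, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.500, 113.6, _chi(1)),
            ("CD1", ("CA", "CB", "CG"), 1.370, 126.9, _chi(2)),
            ("CD2", ("CA", "CB", "CG"), 1.430, 126.7, _chi(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.380, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.410, 107.2, 180.0),
            ("CE3", ("CD1", "CG", "CD2"), 1.400, 133.9, 180.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.400, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.400, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.400, 117.5, 0.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.492, 104.5, -26.0),
            ("CD", ("CA", "CB", "CG"), 1.503, 106.1, 32.0)],
}

#: Compact backbone-independent rotamer set: (prior, chi angles in deg),
#: listed by decreasing prior probability.
ROTAMER_SETS: dict[str, list[tuple[float, tuple[float, ...]]]] = {
    "SER": [(0.48, (62.0,)), (0.29, (-65.0,)), (0.23, (180.0,))],
    "CYS": [(0.50, (-65.0,)), (0.30, (180.0,)), (0.20, (62.0,))],
    "THR": [(0.49, (62.0,)), (0.43, (-60.0,)), (0.08, (180.0,))],
    "VAL": [(0.73, (175.0,)), (0.20, (-60.0,)), (0.07, (64.0,))],
    "LEU": [(0.59, (-65.0, 175.0)), (0.29, (180.0, 65.0)),
            (0.07, (-85.0, 65.0)), (0.05, (62.0, 80.0))],
    "ILE": [(0.60, (-65.0, 170.0)), (0.15, (-57.0, -60.0)),
            (0.13, (62.0, 170.0)), (0.12, (180.0, 165.0))],
    "MET": [(0.35, (-65.0, 175.0, 175.0)), (0.25, (-65.0, -65.0, -70.0)),
            (0.20, (180.0, 175.0, 75.0)), (0.20, (62.0, 180.0, 75.0))],
    "ASP": [(0.51, (-70.0, -15.0)), (0.30, (-177.0, 0.0)),
            (0.19, (62.0, -10.0))],
    "ASN": [(0.45, (-65.0, -20.0)), (0.30, (-177.0, 30.0)),
            (0.25, (62.0, -20.0))],
    "GLU": [(0.40, (-67.0, 180.0, -10.0)), (0.30, (-177.0, 175.0, 0.0)),
            (0.30, (-65.0, -65.0, -40.0))],
    "GLN": [(0.40, (-67.0, 180.0, -25.0)), (0.35, (-177.0, 175.0, 0.0)),
            (0.25, (-65.0, -65.0, -40.0))],
    "LYS": [(0.35, (-67.0, 180.0, 180.0, 180.0)),
            (0.25, (180.0, 180.0, 180.0, 180.0)),
            (0.25, (-67.0, -68.0, 180.0, 180.0)),
            (0.15, (62.0, 180.0, 180.0, 180.0))],
    "ARG": [(0.30, (-67.0, 180.0, 180.0, 180.0)),
            (0.25, (-67.0, -68.0, 180.0, 180.0)),
            (0.25, (180.0, 180.0, 180.0, 180.0)),
            (0.20, (62.0, 180.0, 180.0, 85.0))],
    "HIS": [(0.45, (-65.0, -70.0)), (0.30, (180.0, 60.0)),
            (0.25, (62.0, -85.0))],
    "PHE": [(0.48, (-65.0, 90.0)), (0.33, (180.0, 80.0)),
            (0.19, (62.0, 90.0))],
    "TYR": [(0.48, (-65.0, 90.0)), (0.33, (180.0, 80.0)),
            (0.19, (62.0, 90.0))],
    "TRP": [(0.40, (-65.0, 95.0)), (0.30, (180.0, -105.0)),
            (0.18, (180.0, 90.0)), (0.12, (62.0, -90.0))],
    "PRO": [(1.00, ())],
    "ALA": [(1.00, ())],
    "GLY": [(1.00, ())],
}

CB_PARAMS = (1.530, 110.5, -122.6)  # bond, angle N-CA-CB, improper C-N-CA-CB


@dataclass
class RotamerPlacement:
    residue_key: tuple[str, int, str]
    aa: str
    chi_angles: tuple[float, ...]
    clash_score: int
    prior: float


# --------------------------------------------------------------------------
# Protein cleaning
# --------------------------------------------------------------------------


def clean_protein_for_modeling(cx: ComplexStructure,
                               chain_id: str | None = None) -> Chain:
    """Standard-residue, complete-backbone protein chain ready for modeling.

    Residues with incomplete N/CA/C/O backbones are purged; modified residues
    are renamed to their standard parents (MSE selenium becomes the Met SD
    sulfur) and flagged as ATOM records.
    """
    chains = cx.protein_chains()
    if chain_id is not None:
        chains = [c for c in chains if c.chain_id == chain_id]
    if not chains:
        raise ValueError("no protein chain to clean")
    src = chains[0]
    out = Chain(src.chain_id, "protein")
    for res in src.residues:
        name = res.name
        if name not in AA3_TO_1:
            entry = cx.modres.get((src.chain_id, res.author_number,
                                   res.insertion_code))
            if entry and entry[0] == name:
                name = entry[1]
            elif name in MODRES_PARENTS:
                name = MODRES_PARENTS[name]
            else:
                continue  # not an amino acid
        if not res.has_backbone(BACKBONE_NAMES):
            continue
        new = Residue(name, res.author_number, res.insertion_code)
        for atom in res.atoms.values():
            a = atom.copy()
            a.het = False
            if res.name == "MSE" and a.name == "SE":
                a.name, a.element = "SD", "S"
            new.atoms[a.name] = a
        out.residues.append(new)
    if len(out.residues) < 3:
        raise ValueError("fewer than 3 residues survive backbone cleaning")
    return out


# --------------------------------------------------------------------------
# Side-chain construction
# --------------------------------------------------------------------------


def build_side_chain(backbone: dict[str, np.ndarray], aa3: str,
                     chi_angles: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Heavy side-chain atoms (CB onward) from idealized internal coords."""
    coords = dict(backbone)
    if aa3 == "GLY":
        return {}
    bond, angle, improper = CB_PARAMS
    coords["CB"] = vecmath.place_atom(coords["C"], coords["N"], coords["CA"],
                                      bond, angle, improper)
    built = {"CB": coords["CB"]}
    for name, refs, bond, angle, dihedral in SIDE_CHAIN_TEMPLATES[aa3]:
        if isinstance(dihedral, tuple):
            _tag, k, offset = dihedral
            if k > len(chi_angles):
                raise ValueError(f"{aa3} needs chi{k}, rotamer supplies "
                                 f"{len(chi_angles)} angles")
            value = chi_angles[k - 1] + offset
        else:
            value = dihedral
        a, b, c = (coords[r] for r in refs)
        coords[name] = vecmath.place_atom(a, b, c, bond, angle, value)
        built[name] = coords[name]
    return built


def _clash_count(new_atoms: dict[str, np.ndarray], protein: Chain,
                 skip_key: tuple[int, str]) -> int:
    others = []
    for res in protein.residues:
        if (res.author_number, res.insertion_code) == skip_key:
            continue
        for atom in res.heavy_atoms():
            others.append((atom.element, atom.xyz))
    clashes = 0
    for name, xyz in new_atoms.items():
        r_new = vdw_radius(name[0])
        for element, other in others:
            if np.linalg.norm(xyz - other) < CLASH_FACTOR * (
                    r_new + vdw_radius(element)):
                clashes += 1
    return clashes


def model_mutant(protein: Chain, m: MutationSpec,
                 return_placement: bool = False):
    """Replace one side chain; all other residues stay bit-identical.

    The rotamer with the highest prior among clash-free placements wins; if
    every rotamer clashes, the minimal-clash one is used.  Mutations to Gly
    or Ala have no chi degrees of freedom and are deterministic by
    construction.
    """
    res = protein.get_residue(m.site, m.insertion_code)
    if res is None:
        raise ValueError(f"mutation site {m.site}{m.insertion_code} not in "
                         f"chain {protein.chain_id}")
    if AA3_TO_1.get(res.name) != m.wt_aa:
        raise ValueError(
            f"wild-type residue mismatch: structure has {res.name}, "
            f"mutation names {m.wt_aa}")
    if not res.has_backbone(BACKBONE_NAMES):
        raise ValueError("mutation site lacks a complete backbone")

    out = protein.copy()
    new_res = out.get_residue(m.site, m.insertion_code)
    backbone = {n: new_res.atoms[n].xyz for n in BACKBONE_NAMES}
    new_res.name = AA1_TO_3[m.mut_aa]
    for name in list(new_res.atoms):
        if name not in BACKBONE_NAMES:
            del new_res.atoms[name]

    aa3 = new_res.name
    best = None
    skip = (m.site, m.insertion_code)
    for prior, chis in ROTAMER_SETS[aa3]:
        side = build_side_chain(backbone, aa3, chis)
        clashes = _clash_count(side, protein, skip)
        cand = (clashes, -prior, chis, side, prior)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if clashes == 0:
            break  # rotamers are prior-sorted; first clash-free wins
    _clashes, _negp, chis, side, prior = best
    for name, xyz in side.items():
        new_res.atoms[name] = Atom(name, "S" if name.startswith("S") else
                                   name[0], xyz)
    placement = RotamerPlacement((protein.chain_id, m.site, m.insertion_code),
                                 m.mut_aa, tuple(chis), _clashes, prior)
    if return_placement:
        return out, placement
    return out


# --------------------------------------------------------------------------
# Reassembly
# --------------------------------------------------------------------------


def reassemble_complex(modeled: Chain, original: ComplexStructure,
                       return_rmsd: bool = False):
    """Superpose the modeled protein onto the original complex (Kabsch fit
    over common backbone atoms) and copy all non-protein atoms unchanged."""
    target_chain = original.get_chain(modeled.chain_id)
    if target_chain is None:
        raise ValueError(f"original complex lacks chain {modeled.chain_id!r}")
    mobile, target = [], []
    for res in modeled.residues:
        orig = target_chain.get_residue(res.author_number, res.insertion_code)
        if orig is None:
            continue
        for name in BACKBONE_NAMES:
            if name in res.atoms and name in orig.atoms:
                mobile.append(res.atoms[name].xyz)
                target.append(orig.atoms[name].xyz)
    if len(mobile) < 3:
        raise ValueError("fewer than 3 common backbone atoms for superposition")
    R, t, rmsd = vecmath.kabsch(np.array(mobile), np.array(target))

    placed = modeled.copy()
    for res in placed.residues:
        for atom in res.atoms.values():
            atom.xyz = atom.xyz @ R.T + t
    out = original.copy()
    out.chains = [placed if c.chain_id == modeled.chain_id
                  and c.kind == "protein" else c
                  for c in out.chains]
    if return_rmsd:
        return out, rmsd
    return out


def mutant_complex(cx: ComplexStructure, m: MutationSpec) -> ComplexStructure:
    """Full mutant-modeling stage: clean, mutate, reassemble."""
    protein = clean_protein_for_modeling(cx, m.chain_id)
    modeled = model_mutant(protein, m)
    return reassemble_complex(modeled, cx)
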
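"""Per-residue structural descriptors of the protein in its complex.

Solvent accessibility (Shrake-Rupley, computed in the complex so DNA atoms
occlude), Kabsch-Sander secondary structure in seven classes, backbone phi/psi
torsions, and the six secondary-structure composition ratios used as features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from . import vecmath
from .structio import ComplexStructure
from .tables import sasa_radius

logger = logging.getLogger(__name__)

TORSION_SENTINEL = 360.0  # encodes "undefined" phi/psi outside [-180, 180]
HBOND_ENERGY_CUTOFF = -0.5    # kcal/mol, Kabsch-Sander threshold
HBOND_Q1Q2F = 0.084 * 332.0   # kcal/mol*A, electrostatic H-bond model
BEND_KAPPA = 70.0             # deg, bend (S) threshold
PEPTIDE_BOND_MAX = 2.5        # A, C(i)-N(i+1) continuity check

ResKey = tuple[str, int, str]  # (chain_id, author_number, insertion_code)


# --------------------------------------------------------------------------
# Solvent accessibility
# --------------------------------------------------------------------------


def solvent_accessibility(cx: ComplexStructure,
                          point_number: int = 1000) -> dict[ResKey, float]:
    """Absolute per-residue SASA (A^2) of protein residues in the complex.

    Shrake-Rupley with a 1.4 A probe and DSSP-compatible heavy-atom radii;
    every heavy atom of the complex (DNA included) occludes.
    """
    records = []  # (key or None, radius, xyz)
    for chain in cx.chains:
        for res in chain.residues:
            key = (chain.chain_id, res.author_number, res.insertion_code)
            heavy = res.heavy_atoms()
            if chain.kind == "protein" and not heavy:
                logger.warning("residue %s has no heavy atoms; excluded", key)
                continue
            for atom in heavy:
                records.append((key if chain.kind == "protein" else None,
                                sasa_radius(atom.element, atom.name),
                                atom.xyz, atom.element))
    if not records:
        raise ValueError("no heavy atoms in structure")

    n = len(records)
    array = struc.AtomArray(n)
    array.coord = np.array([r[2] for r in records], dtype=np.float32)
    array.element = np.array([r[3] for r in records], dtype="U2")
    array.atom_name = np.array(["X"] * n, dtype="U4")
    array.res_name = np.array(["UNK"] * n, dtype="U3")
    array.res_id = np.arange(n)
    array.chain_id = np.array(["A"] * n, dtype="U1")
    radii = np.array([r[1] for r in records])
    per_atom = struc.sasa(array, probe_radius=1.4, point_number=point_number,
                          vdw_radii=radii, ignore_ions=False)

    out: dict[ResKey, float] = {}
    for (key, _r, _xyz, _e), area in zip(records, per_atom):
        if key is None or not np.isfinite(area):
            continue
        out[key] = out.get(key, 0.0) + float(area)
    return out


# --------------------------------------------------------------------------
# Kabsch-Sander secondary structure
# --------------------------------------------------------------------------


@dataclass
class _BBRes:
    key: ResKey
    chain_index: int
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray | None
    h: np.ndarray | None = None
    is_pro: bool = False


def _rebuild_o(prev_res, ca, c, n_next):
    # carbonyl O lies in the CA-C-N(next) plane, anti to N(next)
    return vecmath.place_atom(n_next, ca, c, 1.231, 120.8, 180.0)


def _collect_backbone(cx: ComplexStructure) -> list[list[_BBRes]]:
    chains = []
    for ci, chain in enumerate(cx.protein_chains()):
        items: list[_BBRes] = []
        for res in chain.residues:
            if not res.has_backbone(("N", "CA", "C")):
                items.append(None)  # keeps neighbour indexing honest
                continue
            items.append(_BBRes(
                key=(chain.chain_id, res.author_number, res.insertion_code),
                chain_index=ci,
                n=res.atoms["N"].xyz, ca=res.atoms["CA"].xyz,
                c=res.atoms["C"].xyz,
                o=res.atoms["O"].xyz if "O" in res.atoms else None,
                is_pro=res.name == "PRO"))
        # rebuild missing carbonyl O where the next residue provides N
        for i, it in enumerate(items):
            if it is None or it.o is not None:
                continue
            nxt = items[i + 1] if i + 1 < len(items) else None
            if nxt is not None and _bonded(it, nxt):
                it.o = _rebuild_o(it, it.ca, it.c, nxt.n)
        chains.append([it for it in items if it is not None and it.o is not None])
    return chains


def _bonded(a: _BBRes, b: _BBRes) -> bool:
    return float(np.linalg.norm(b.n - a.c)) <= PEPTIDE_BOND_MAX


def _place_amide_h(chains: list[list[_BBRes]]) -> None:
    for items in chains:
        for i, it in enumerate(items):
            if i == 0 or it.is_pro:
                continue
            prev = items[i - 1]
            if not _bonded(prev, it):
                continue
            direction = prev.c - prev.o
            it.h = it.n + direction / np.linalg.norm(direction)


def _hbond_energy(donor: _BBRes, acceptor: _BBRes) -> float:
    """Kabsch-Sander electrostatic N-H...O=C energy in kcal/mol."""
    if donor.h is None:
        return 0.0
    r_on = np.linalg.norm(acceptor.o - donor.n)
    r_ch = np.linalg.norm(acceptor.c - donor.h)
    r_oh = np.linalg.norm(acceptor.o - donor.h)
    r_cn = np.linalg.norm(acceptor.c - donor.n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return HBOND_Q1Q2F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def assign_secondary_structure(cx: ComplexStructure) -> dict[ResKey, str]:
    """Seven-class Kabsch-Sander assignment: H, G, I, E, B, T, S or C (coil).

    Precedence H > E > B > G > I > T > S; residues lacking N/CA/C backbone
    atoms are reported as coil.
    """
    chains = _collect_backbone(cx)
    _place_amide_h(chains)
    flat: list[_BBRes] = [it for items in chains for it in items]
    index = {id(it): k for k, it in enumerate(flat)}
    pos_in_chain: dict[int, tuple[int, int]] = {}
    for ci, items in enumerate(chains):
        for pi, it in enumerate(items):
            pos_in_chain[id(it)] = (ci, pi)

    nres = len(flat)
    hbond = np.zeros((nres, nres), dtype=bool)  # donor row -> acceptor col
    ca = np.array([it.ca for it in flat]) if flat else np.zeros((0, 3))
    for i, donor in enumerate(flat):
        for j, acceptor in enumerate(flat):
            ci, pi = pos_in_chain[id(donor)]
            cj, pj = pos_in_chain[id(acceptor)]
            if ci == cj and abs(pi - pj) <= 1:
                continue
            if np.linalg.norm(ca[i] - ca[j]) > 9.0:
                continue
            if _hbond_energy(donor, acceptor) < HBOND_ENERGY_CUTOFF:
                hbond[i, j] = True

    def bond(donor_it, acceptor_it) -> bool:
        return hbond[index[id(donor_it)], index[id(acceptor_it)]]

    classes: dict[ResKey, set[str]] = {it.key: set() for it in flat}

    # n-turns and helices per chain
    for items in chains:
        m = len(items)
        for n_turn, code in ((3, "G"), (4, "H"), (5, "I")):
            turn = [False] * m
            for i in range(m - n_turn):
                if bond(items[i + n_turn], items[i]):
                    turn[i] = True
                    for k in range(i + 1, i + n_turn):
                        classes[items[k].key].add("T")
            for i in range(1, m - n_turn):
                if turn[i - 1] and turn[i]:
                    for k in range(i, i + n_turn):
                        classes[items[k].key].add(code)

    # bridges and ladders (global over chains)
    bridges: list[tuple[int, int, str]] = []
    for i in range(nres):
        for j in range(nres):
            if abs(i - j) < 3 and _same_chain(flat, pos_in_chain, i, j):
                continue
            if j <= i:
                continue
            par = ((_b(hbond, flat, pos_in_chain, i, -1, j)
                    and _b(hbond, flat, pos_in_chain, j, 0, i, +1))
                   or (_b(hbond, flat, pos_in_chain, j, -1, i)
                       and _b(hbond, flat, pos_in_chain, i, 0, j, +1)))
            anti = ((hbond[i, j] and hbond[j, i])
                    or (_b2(hbond, flat, pos_in_chain, i, -1, j, +1)
                        and _b2(hbond, flat, pos_in_chain, j, -1, i, +1)))
            if par:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))
    in_ladder: set[int] = set()
    bridge_res: set[int] = set()
    bset = set((i, j, t) for i, j, t in bridges)
    for i, j, t in bridges:
        bridge_res.update((i, j))
        neighbours = [(i + 1, j + 1, "P"), (i - 1, j - 1, "P")] if t == "P" \
            else [(i + 1, j - 1, "A"), (i - 1, j + 1, "A")]
        for x, y, tt in neighbours:
            if (x, y, tt) in bset or (y, x, tt) in bset:
                in_ladder.update((i, j))
    for r in bridge_res:
        classes[flat[r].key].add("E" if r in in_ladder else "B")

    # bends
    for items in chains:
        for i in range(2, len(items) - 2):
            if not (_bonded(items[i - 2], items[i - 1])
                    and _bonded(items[i - 1], items[i])
                    and _bonded(items[i], items[i + 1])
                    and _bonded(items[i + 1], items[i + 2])):
                continue
            kappa = vecmath.angle_deg(items[i].ca - items[i - 2].ca,
                                      items[i + 2].ca - items[i].ca)
            if kappa > BEND_KAPPA:
                classes[items[i].key].add("S")

    out: dict[ResKey, str] = {}
    for chain in cx.protein_chains():
        for res in chain.residues:
            key = (chain.chain_id, res.author_number, res.insertion_code)
            got = classes.get(key, set())
            for cls in ("H", "E", "B", "G", "I", "T", "S"):
                if cls in got:
                    out[key] = cls
                    break
            else:
                out[key] = "C"
    return out


def _same_chain(flat, pos, i, j) -> bool:
    return pos[id(flat[i])][0] == pos[id(flat[j])][0]


def _shifted(flat, pos, i, delta):
    cache = getattr(_shifted, "_cache", None)
    if cache is None or cache[0] is not flat:
        table = {pos[id(it)]: k for k, it in enumerate(flat)}
        _shifted._cache = cache = (flat, table)
    ci, pi = pos[id(flat[i])]
    return cache[1].get((ci, pi + delta))


def _b(hbond, flat, pos, i, di, j, dj=0):
    ii = _shifted(flat, pos, i, di) if di else i
    jj = _shifted(flat, pos, j, dj) if dj else j
    if ii is None or jj is None:
        return False
    return hbond[ii, jj]


def _b2(hbond, flat, pos, i, di, j, dj):
    return _b(hbond, flat, pos, i, di, j, dj)


# --------------------------------------------------------------------------
# Backbone torsions
# --------------------------------------------------------------------------


def backbone_torsions(cx: ComplexStructure, chain_id: str, number: int,
                      icode: str = "") -> tuple[float, float]:
    """(phi, psi) of a residue in degrees; 360.0 encodes undefined."""
    chain = cx.get_chain(chain_id)
    if chain is None or chain.kind != "protein":
        raise ValueError(f"no protein chain {chain_id!r}")
    idx = next((i for i, r in enumerate(chain.residues)
                if r.key == (number, icode)), None)
    if idx is None:
        raise ValueError(f"residue {number}{icode} not found in chain {chain_id}")
    res = chain.residues[idx]
    if not res.has_backbone(("N", "CA", "C")):
        return (TORSION_SENTINEL, TORSION_SENTINEL)
    phi = psi = TORSION_SENTINEL
    if idx > 0:
        prev = chain.residues[idx - 1]
        if prev.has_backbone(("C",)) and \
                np.linalg.norm(res.atoms["N"].xyz - prev.atoms["C"].xyz) \
                <= PEPTIDE_BOND_MAX:
            phi = vecmath.dihedral_deg(prev.atoms["C"].xyz, res.atoms["N"].xyz,
                                       res.atoms["CA"].xyz, res.atoms["C"].xyz)
    if idx + 1 < len(chain.residues):
        nxt = chain.residues[idx + 1]
        if nxt.has_backbone(("N",)) and \
                np.linalg.norm(nxt.atoms["N"].xyz - res.atoms["C"].xyz) \
                <= PEPTIDE_BOND_MAX:
            psi = vecmath.dihedral_deg(res.atoms["N"].xyz, res.atoms["CA"].xyz,
                                       res.atoms["C"].xyz, nxt.atoms["N"].xyz)
    return (phi, psi)


# --------------------------------------------------------------------------
# Secondary-structure composition
# --------------------------------------------------------------------------

SS_COMPOSITION_ORDER = ("H", "B", "E", "G", "T", "S")


@dataclass
class SSComposition:
    """Fractions of residues in the six reported secondary-structure classes
    (alpha-helix, isolated beta-bridge, extended strand, 3-10 helix,
    hydrogen-bonded turn, bend); pi-helix and coil are assigned internally
    but not reported."""
    ratios: dict[str, float]

    def as_vector(self) -> np.ndarray:
        return np.array([self.ratios[c] for c in SS_COMPOSITION_ORDER])


def ss_composition(cx: ComplexStructure,
                   assignment: dict[ResKey, str] | None = None) -> SSComposition:
    if assignment is None:
        assignment = assign_secondary_structure(cx)
    total = len(assignment)
    if total == 0:
        raise ValueError("no protein residues to classify")
    ratios = {c: sum(1 for v in assignment.values() if v == c) / total
              for c in SS_COMPOSITION_ORDER}
    return SSComposition(ratios)
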
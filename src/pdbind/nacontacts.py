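"""DNA base-pair geometry and the protein-DNA interaction census.

Base pairs are detected by fitting each base to its standard reference frame
(consensus base geometry) and testing the relative frame geometry; base-pair,
step and helical parameters follow the mid-frame (CEHS/3DNA) convention.  The
interaction census counts nucleotide-residue contacts, base and phosphate
hydrogen bonds and base-residue stacks with configurable geometric cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import vecmath
from .structio import Chain, ComplexStructure, Residue
from .tables import (BASE_ATOMS, BASE_POLAR_ATOMS, BASE_RING_ATOMS,
                     PHOSPHATE_ATOMS, RESIDUE_PLANES,
                     standard_base_frame_coords)

_FLIP = np.diag([1.0, -1.0, -1.0])

# pairing acceptance thresholds (frame geometry)
PAIR_ORIGIN_CUTOFF = 2.5     # A between base-frame origins
PAIR_VERTICAL_CUTOFF = 1.5   # A separation along the mean normal
PAIR_NORMAL_ANGLE = 65.0     # deg between (flipped) base normals


@dataclass
class ContactConfig:
    """Geometric cutoffs of the interaction census (standard structural-
    biology defaults; retrainable installations may override them)."""
    contact_cutoff: float = 4.5      # A, any heavy-atom pair
    hbond_cutoff: float = 3.5        # A, donor/acceptor N/O distance
    hbond_angle_min: float = 120.0   # deg, D-H...A when an H is present
    stack_cutoff: float = 4.5        # A, planar-group centroid distance
    stack_angle_max: float = 30.0    # deg, inter-normal angle


DEFAULT_CONTACT_CONFIG = ContactConfig()


# --------------------------------------------------------------------------
# Base frames and pairing
# --------------------------------------------------------------------------


@dataclass
class BaseFrame:
    chain_id: str
    number: int
    icode: str
    base: str
    rotation: np.ndarray  # 3x3, columns = base x, y, z in global coords
    origin: np.ndarray
    rmsd: float

    @property
    def key(self):
        return (self.chain_id, self.number, self.icode)


@dataclass
class BasePair:
    forward: BaseFrame
    reverse: BaseFrame | None = None
    pair_rotation: np.ndarray | None = None  # mid (base-pair) frame
    pair_origin: np.ndarray | None = None

    @property
    def paired(self) -> bool:
        return self.reverse is not None


def fit_base_frame(chain: Chain, res: Residue) -> BaseFrame | None:
    """Least-squares fit of the standard base frame to an observed base."""
    base = res.base
    if base is None:
        return None
    names = [n for n in BASE_RING_ATOMS[base] if n in res.atoms]
    if len(names) < 6:
        return None
    obs = np.array([res.atoms[n].xyz for n in names])
    ideal = standard_base_frame_coords(base, names)
    R, t, rmsd = vecmath.kabsch(ideal, obs)
    # frame origin = image of the standard-frame origin
    return BaseFrame(chain.chain_id, res.author_number, res.insertion_code,
                     base, R, t, rmsd)


def _pair_score(f1: BaseFrame, f2: BaseFrame) -> float | None:
    z1 = f1.rotation[:, 2]
    z2f = -f2.rotation[:, 2]            # normal after strand-II flip
    if vecmath.angle_deg(z1, z2f) > PAIR_NORMAL_ANGLE:
        return None
    d = f1.origin - f2.origin
    if np.linalg.norm(d) > PAIR_ORIGIN_CUTOFF:
        return None
    zm = z1 + z2f
    zm /= np.linalg.norm(zm)
    if abs(float(np.dot(d, zm))) > PAIR_VERTICAL_CUTOFF:
        return None
    return float(np.linalg.norm(d))


def find_base_pairs(cx: ComplexStructure) -> list[BasePair]:
    """Detect base pairs across DNA strands; unpaired bases are returned with
    ``reverse = None``.  Each base joins at most one pair (best score wins)."""
    frames: list[BaseFrame] = []
    for chain in cx.dna_chains():
        for res in chain.residues:
            f = fit_base_frame(chain, res)
            if f is not None:
                frames.append(f)
    candidates = []
    for i in range(len(frames)):
        for j in range(i + 1, len(frames)):
            if frames[i].chain_id == frames[j].chain_id:
                continue
            score = _pair_score(frames[i], frames[j])
            if score is not None:
                candidates.append((score, i, j))
    candidates.sort(key=lambda t: t[0])
    used: set[int] = set()
    pairs: list[BasePair] = []
    for score, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        bp = BasePair(frames[i], frames[j])
        _compute_pair_frame(bp)
        pairs.append(bp)
    for k, f in enumerate(frames):
        if k not in used:
            pairs.append(BasePair(f, None, f.rotation.copy(),
                                  f.origin.copy()))
    order = {f.key: n for n, f in enumerate(frames)}
    pairs.sort(key=lambda p: order[p.forward.key])
    return pairs


def pair_for_site(pairs: list[BasePair], chain_id: str, number: int,
                  icode: str = "") -> BasePair | None:
    """The pair containing the named nucleotide, oriented so it is forward."""
    key = (chain_id, number, icode)
    for bp in pairs:
        if bp.forward.key == key:
            return bp
        if bp.reverse is not None and bp.reverse.key == key:
            flipped = BasePair(bp.reverse, bp.forward)
            _compute_pair_frame(flipped)
            return flipped
    return None


# --------------------------------------------------------------------------
# Mid-frame parameter algebra
# --------------------------------------------------------------------------


def _rot(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    return vecmath.rotation_about_axis(axis, angle_deg_)


def _signed_angle(a, b, about) -> float:
    return float(np.degrees(np.arctan2(np.dot(np.cross(a, b), about),
                                       np.dot(a, b))))


def frames_to_params(R1, o1, R2, o2):
    """Mid-frame decomposition of the rigid relation between two frames.

    Returns ((tx, ty, tz), (rot_x, rot_y, rot_z), (Rm, om)): translations of
    frame-2 origin from frame-1 origin in the mid frame, and the rotation
    decomposed into components about the mid-frame axes (the tilt/roll/twist
    pattern for steps; buckle/propeller/opening for pairs).
    """
    z1, z2 = R1[:, 2], R2[:, 2]
    gamma = vecmath.angle_deg(z1, z2)
    if gamma > 1e-9 and np.linalg.norm(np.cross(z1, z2)) > 1e-12:
        hinge = vecmath.unit(np.cross(z1, z2))
        R1p = _rot(hinge, gamma / 2) @ R1
        R2p = _rot(hinge, -gamma / 2) @ R2
    else:
        hinge = None
        R1p, R2p = R1, R2
    zm = vecmath.unit(R1p[:, 2] + R2p[:, 2])
    twist = _signed_angle(R1p[:, 0], R2p[:, 0], zm)
    Rm = _rot(zm, twist / 2) @ R1p
    t = Rm.T @ (np.asarray(o2) - np.asarray(o1))
    if hinge is None:
        rot_x = rot_y = 0.0
    else:
        phase = _signed_angle(hinge, Rm[:, 1], zm)
        rot_y = gamma * np.cos(np.radians(phase))
        rot_x = gamma * np.sin(np.radians(phase))
    om = 0.5 * (np.asarray(o1) + np.asarray(o2))
    return (tuple(float(x) for x in t), (float(rot_x), float(rot_y),
                                         float(twist)), (Rm, om))


def params_to_frames(translations, rotations):
    """Inverse of :func:`frames_to_params` with the mid frame at identity.

    Used for algebraic self-consistency checks: the two frames implied by a
    parameter set must decompose back to the same parameters.
    """
    tx, ty, tz = translations
    rot_x, rot_y, twist = rotations
    Rm = np.eye(3)
    om = np.zeros(3)
    gamma = float(np.hypot(rot_x, rot_y))
    if gamma > 1e-12:
        phase = np.degrees(np.arctan2(rot_x, rot_y))
        hinge = _rot(Rm[:, 2], -phase) @ Rm[:, 1]
    else:
        hinge = Rm[:, 1]
    R1 = _rot(hinge, -gamma / 2) @ _rot(Rm[:, 2], -twist / 2) @ Rm
    R2 = _rot(hinge, gamma / 2) @ _rot(Rm[:, 2], twist / 2) @ Rm
    t_global = Rm @ np.asarray(translations, float)
    o1 = om - t_global / 2
    o2 = om + t_global / 2
    return R1, o1, R2, o2


def _compute_pair_frame(bp: BasePair) -> None:
    Rr = bp.reverse.rotation @ _FLIP
    _t, _r, (Rm, om) = frames_to_params(Rr, bp.reverse.origin,
                                        bp.forward.rotation,
                                        bp.forward.origin)
    bp.pair_rotation, bp.pair_origin = Rm, om


def pair_parameters(bp: BasePair):
    """(shear, stretch, stagger, buckle, propeller, opening); A / deg.

    Unpaired (single-stranded) sites return all zeros by convention.
    """
    if not bp.paired:
        return (0.0,) * 6
    Rr = bp.reverse.rotation @ _FLIP
    (tx, ty, tz), (rx, ry, rz), _ = frames_to_params(
        Rr, bp.reverse.origin, bp.forward.rotation, bp.forward.origin)
    return (tx, ty, tz, rx, ry, rz)


def step_parameters(bp1: BasePair, bp2: BasePair):
    """Step + helical parameters between two successive base pairs.

    Returns (shift, slide, rise, tilt, roll, twist, x_displacement,
    y_displacement, helical_rise, inclination, tip, helical_twist).
    """
    for bp in (bp1, bp2):
        if bp.pair_rotation is None:
            raise ValueError("base pair lacks a reference frame")
    if not _adjacent(bp1, bp2):
        raise ValueError("step parameters require adjacent base pairs")
    R1, o1 = bp1.pair_rotation, bp1.pair_origin
    R2, o2 = bp2.pair_rotation, bp2.pair_origin
    (tx, ty, tz), (rx, ry, rz), (Rm, om) = frames_to_params(R1, o1, R2, o2)
    helical = _helical_parameters(R1, o1, R2, o2, Rm)
    return (tx, ty, tz, rx, ry, rz) + helical


def _adjacent(bp1: BasePair, bp2: BasePair) -> bool:
    f1, f2 = bp1.forward, bp2.forward
    if f1.chain_id != f2.chain_id:
        return False
    return abs(f1.number - f2.number) <= 1 and f1.icode == f2.icode


def _helical_parameters(R1, o1, R2, o2, Rm):
    Rrel = R2 @ R1.T
    rotvec = Rotation.from_matrix(Rrel).as_rotvec()
    ang = float(np.linalg.norm(rotvec))
    zm = Rm[:, 2]
    d = np.asarray(o2) - np.asarray(o1)
    if ang < 1e-9:
        return (0.0, 0.0, float(np.dot(d, zm)), 0.0, 0.0, 0.0)
    u = rotvec / ang
    h_twist = np.degrees(ang)
    if np.dot(u, zm) < 0:
        u, h_twist = -u, -h_twist
    h_rise = float(np.dot(d, u))
    # bp displacement from the helical axis
    d_perp = d - h_rise * u
    A = np.eye(3) - Rrel
    p_rel = np.linalg.pinv(A, rcond=1e-8) @ d_perp
    axis_point = np.asarray(o1) + p_rel
    # helical frame: mid frame rotated so z coincides with the axis
    lam = vecmath.angle_deg(zm, u)
    if lam > 1e-9 and np.linalg.norm(np.cross(zm, u)) > 1e-12:
        hinge = vecmath.unit(np.cross(zm, u))
        Rh = _rot(hinge, lam) @ Rm
        phase = _signed_angle(hinge, Rm[:, 1], zm)
        inclination = lam * np.cos(np.radians(phase))
        tip = lam * np.sin(np.radians(phase))
    else:
        Rh = Rm
        inclination = tip = 0.0
    rel = np.asarray(o1) - axis_point
    x_disp = float(np.dot(rel, Rh[:, 0]))
    y_disp = float(np.dot(rel, Rh[:, 1]))
    return (x_disp, y_disp, h_rise, float(inclination), float(tip),
            float(h_twist))


# --------------------------------------------------------------------------
# Interaction census
# --------------------------------------------------------------------------


@dataclass
class InteractionCounts:
    nt_aa_contacts: int = 0
    base_aa_hbonds: int = 0
    phosphate_aa_hbonds: int = 0
    base_aa_stacks: int = 0

    def as_tuple(self):
        return (self.nt_aa_contacts, self.base_aa_hbonds,
                self.phosphate_aa_hbonds, self.base_aa_stacks)


def delta_interactions(wt: InteractionCounts,
                       mut: InteractionCounts) -> tuple[int, int, int, int]:
    """Mutation-induced interaction changes, oriented mutant - wild-type."""
    return tuple(m - w for w, m in zip(wt.as_tuple(), mut.as_tuple()))


def _protein_atoms(cx: ComplexStructure):
    atoms = []  # (residue index, residue, atom)
    for chain in cx.protein_chains():
        for res in chain.residues:
            key = (chain.chain_id, res.author_number, res.insertion_code)
            for atom in res.heavy_atoms():
                atoms.append((key, res, atom))
    return atoms


def _normalize_atom_name(name: str) -> str:
    return name.replace("*", "'").replace("O1P", "OP1").replace("O2P", "OP2")


def _plane_normal(coords: np.ndarray):
    centroid = coords.mean(axis=0)
    _u, _s, vt = np.linalg.svd(coords - centroid)
    return centroid, vt[2]


def _attached_hydrogens(res: Residue, donor_name: str) -> list[np.ndarray]:
    donor = res.atoms[donor_name].xyz
    out = []
    for atom in res.atoms.values():
        if atom.element in ("H", "D") and np.linalg.norm(atom.xyz - donor) < 1.25:
            out.append(atom.xyz)
    return out


def _hbond_geometry_ok(res_a: Residue, name_a: str, res_b: Residue,
                       name_b: str, config: ContactConfig) -> bool:
    """Angle screen applied only when explicit hydrogens are present."""
    any_h = False
    for donor_res, donor_name, acc_res, acc_name in (
            (res_a, name_a, res_b, name_b), (res_b, name_b, res_a, name_a)):
        hs = _attached_hydrogens(donor_res, donor_name)
        if not hs:
            continue
        any_h = True
        a = acc_res.atoms[acc_name].xyz
        if any(vecmath.angle_deg(donor_res.atoms[donor_name].xyz - h,
                                 a - h) >= config.hbond_angle_min
               for h in hs):
            return True
    # crystal structures rarely carry hydrogens: fall back to distance only
    return not any_h


def _census(cx: ComplexStructure, dna_filter,
            config: ContactConfig) -> InteractionCounts:
    prot = _protein_atoms(cx)
    if not prot:
        raise ValueError("no protein chain in complex")
    dna_residues = []
    for chain in cx.dna_chains():
        for res in chain.residues:
            key = (chain.chain_id, res.author_number, res.insertion_code)
            if dna_filter(key):
                dna_residues.append((key, res))
    if not cx.dna_chains():
        raise ValueError("no DNA chain in complex")

    prot_coords = np.array([a.xyz for _k, _r, a in prot])
    tree = cKDTree(prot_coords)
    counts = InteractionCounts()

    # residue-plane cache for stacking
    planes = []
    for chain in cx.protein_chains():
        for res in chain.residues:
            names = RESIDUE_PLANES.get(res.name)
            if not names or any(n not in res.atoms for n in names):
                continue
            centroid, normal = _plane_normal(
                np.array([res.atoms[n].xyz for n in names]))
            planes.append((centroid, normal))

    for key, res in dna_residues:
        base = res.base
        heavy = res.heavy_atoms()
        if not heavy:
            continue
        coords = np.array([a.xyz for a in heavy])
        # contacts: any heavy-atom pair within cutoff -> one (nt, aa) count
        near = tree.query_ball_point(coords, config.contact_cutoff)
        partner_res = {prot[idx][0] for lst in near for idx in lst}
        counts.nt_aa_contacts += len(partner_res)

        # hydrogen bonds
        for atom in heavy:
            name = _normalize_atom_name(atom.name)
            in_base = base is not None and name in BASE_POLAR_ATOMS[base]
            in_phosphate = name in PHOSPHATE_ATOMS
            if not (in_base or in_phosphate):
                continue
            for idx in tree.query_ball_point(atom.xyz, config.hbond_cutoff):
                _pkey, pres, patom = prot[idx]
                if patom.element not in ("N", "O"):
                    continue
                if not _hbond_geometry_ok(res, atom.name, pres, patom.name,
                                          config):
                    continue
                if in_base:
                    counts.base_aa_hbonds += 1
                else:
                    counts.phosphate_aa_hbonds += 1

        # stacking
        if base is not None:
            ring = [n for n in BASE_RING_ATOMS[base] if n in res.atoms]
            if len(ring) >= 5:
                bc, bn = _plane_normal(
                    np.array([res.atoms[n].xyz for n in ring]))
                for pc, pn in planes:
                    if np.linalg.norm(bc - pc) > config.stack_cutoff:
                        continue
                    ang = vecmath.angle_deg(bn, pn)
                    ang = min(ang, 180.0 - ang)
                    if ang <= config.stack_angle_max:
                        counts.base_aa_stacks += 1
    return counts


def count_interactions(cx: ComplexStructure,
                       config: ContactConfig = DEFAULT_CONTACT_CONFIG
                       ) -> InteractionCounts:
    """Complex-level protein-DNA interaction census."""
    return _census(cx, lambda key: True, config)


def site_interactions(cx: ComplexStructure, chain_id: str, number: int,
                      icode: str = "",
                      config: ContactConfig = DEFAULT_CONTACT_CONFIG
                      ) -> InteractionCounts:
    """Census restricted to one forward-strand nucleotide."""
    target = (chain_id, number, icode)
    chain = cx.get_chain(chain_id)
    if chain is None or chain.get_residue(number, icode) is None:
        raise ValueError(f"mutation site missing: nucleotide {target}")
    return _census(cx, lambda key: key == target, config)
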
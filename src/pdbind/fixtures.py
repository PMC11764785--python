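"""Synthetic protein-DNA complexes and training tables.

The generators make the whole pipeline testable without downloads: a
fiber-model B-DNA builder (twist 36.0 deg, rise 3.38 A, standard-frame base
geometry), an ideal poly-Ala alpha-helix placed at a controlled distance from
the duplex, optional header-record perturbations (REMARK 465 gaps, MODRES
selenomethionine, SEQADV expression tags, duplicated assemblies), and a
planted-signal feature-table generator for the regression harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import vecmath
from .tables import (FIXTURE_BACKBONE_COORDS, STANDARD_BASE_COORDS,
                     WC_COMPLEMENT)

FIBER_TWIST = 36.0   # deg per base-pair step
FIBER_RISE = 3.38    # A per base-pair step

_FLIP = np.diag([1.0, -1.0, -1.0])  # strand-II frame flip (y, z reversed)

# ideal backbone internal coordinates (A / deg)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
      "CA-CB": 1.530}
_A = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
      "N-CA-CB": 110.5}
CB_IMPROPER = -122.6  # dihedral(C, N, CA, CB) for an L-amino acid


@dataclass
class FixtureSpec:
    dna_sequence: str = "ACGTACGT"
    duplex: bool = True
    helix_length: int = 12
    offset: float = 3.5          # min heavy-atom distance helix <-> DNA, A
    copies: int = 1              # duplicated crystallographic assemblies
    n_missing: int = 0           # leading residues present only in REMARK 465
    modres_at: int | None = None  # author position emitted as MSE + MODRES
    tag_positions: tuple[int, ...] = ()  # SEQADV expression-tag positions
    include_headers: bool = True
    protein_chain: str = "A"
    dna_chains: tuple[str, str] = ("B", "C")


# --------------------------------------------------------------------------
# PDB text assembly
# --------------------------------------------------------------------------


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element,
                   het=False, icode=""):
    rec = "HETATM" if het else "ATOM  "
    if len(name) < 4 and len(element) == 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    x, y, z = xyz
    return (f"{rec}{serial:5d} {name_f} {resname:>3s} {chain:1s}{resnum:4d}"
            f"{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


# --------------------------------------------------------------------------
# B-DNA fiber model
# --------------------------------------------------------------------------


def base_pair_frames(n: int, twist: float = FIBER_TWIST,
                     rise: float = FIBER_RISE):
    """Rotation/origin of each base-pair reference frame along the fiber."""
    frames = []
    for i in range(n):
        R = vecmath.rotation_about_axis([0.0, 0.0, 1.0], i * twist)
        o = np.array([0.0, 0.0, i * rise])
        frames.append((R, o))
    return frames


def _nucleotide_atoms(base: str, R: np.ndarray, o: np.ndarray,
                      with_phosphate: bool) -> list[tuple[str, np.ndarray, str]]:
    out = []
    for name, local in STANDARD_BASE_COORDS[base].items():
        out.append((name, R @ np.asarray(local) + o,
                    name[0] if name[0] in "CNOP" else "C"))
    if with_phosphate:
        for name, local in FIXTURE_BACKBONE_COORDS.items():
            out.append((name, R @ np.asarray(local) + o, name[0]))
    return out


def make_bdna(sequence: str, duplex: bool = True,
              chain_forward: str = "B", chain_reverse: str = "C",
              twist: float = FIBER_TWIST, rise: float = FIBER_RISE,
              origin=(0.0, 0.0, 0.0), as_lines: bool = False):
    """Fiber-model B-DNA duplex (or single strand) as PDB text.

    The forward strand runs 5'->3' with author numbers 1..n; the reverse
    strand is the reverse complement, numbered 1..n in its own 5'->3' order.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid bases: {sorted(bad)}")
    origin = np.asarray(origin, float)
    frames = base_pair_frames(len(sequence), twist, rise)
    lines: list[str] = []
    serial = 1
    for i, base in enumerate(sequence):
        R, o = frames[i]
        for name, xyz, element in _nucleotide_atoms(base, R, o + origin, i > 0):
            lines.append(_pdb_atom_line(serial, name, "D" + base,
                                        chain_forward, i + 1, xyz, element))
            serial += 1
    lines.append(f"TER   {serial:5d}      {'D' + sequence[-1]:>3s} "
                 f"{chain_forward:1s}{len(sequence):4d}")
    serial += 1
    if duplex:
        n = len(sequence)
        for j in range(n):
            i = n - 1 - j           # paired forward position
            base = WC_COMPLEMENT[sequence[i]]
            R, o = frames[i]
            Rr = R @ _FLIP
            for name, xyz, element in _nucleotide_atoms(
                    base, Rr, o + origin, j > 0):
                lines.append(_pdb_atom_line(serial, name, "D" + base,
                                            chain_reverse, j + 1, xyz,
                                            element))
                serial += 1
        lines.append(f"TER   {serial:5d}      "
                     f"{'D' + WC_COMPLEMENT[sequence[0]]:>3s} "
                     f"{chain_reverse:1s}{n:4d}")
    if as_lines:
        return lines
    return "\n".join(lines) + "\nEND\n"


# --------------------------------------------------------------------------
# Ideal alpha-helix
# --------------------------------------------------------------------------


def helix_backbone(n_res: int, phi: float = -57.0, psi: float = -47.0,
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone + CB coordinates of an ideal poly-Ala helix (per residue)."""
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    nv = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B["N-CA"], 0.0, 0.0])
    # orient the first C via place_atom from a dummy pre-N reference point
    c = vecmath.place_atom(np.array([-1.0, 1.0, 0.0]), nv, ca,
                           _B["CA-C"], _A["N-CA-C"], phi)
    residues.append({"N": nv, "CA": ca, "C": c})
    for i in range(1, n_res):
        prev = residues[-1]
        n_next = vecmath.place_atom(prev["N"], prev["CA"], prev["C"],
                                    _B["C-N"], _A["CA-C-N"], psi)
        ca_next = vecmath.place_atom(prev["CA"], prev["C"], n_next,
                                     _B["N-CA"], _A["C-N-CA"], omega)
        c_next = vecmath.place_atom(prev["C"], n_next, ca_next,
                                    _B["CA-C"], _A["N-CA-C"], phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, res in enumerate(residues):
        if i + 1 < n_res:
            nxt = residues[i + 1]["N"]
            res["O"] = vecmath.place_atom(nxt, res["CA"], res["C"],
                                          _B["C-O"], _A["CA-C-O"], 180.0)
        else:
            res["O"] = vecmath.place_atom(res["N"], res["CA"], res["C"],
                                          _B["C-O"], _A["CA-C-O"], psi + 180.0)
        res["CB"] = vecmath.place_atom(res["C"], res["N"], res["CA"],
                                       _B["CA-CB"], _A["N-CA-CB"], CB_IMPROPER)
    return residues


# --------------------------------------------------------------------------
# Toy complexes
# --------------------------------------------------------------------------


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    d, _ = cKDTree(b).query(a, k=1)
    return float(np.min(d))


def make_toy_complex(spec: FixtureSpec) -> str:
    """Poly-Ala helix + DNA duplex assembly as PDB text, per the spec."""
    dna_lines_parts = []
    dna_coords = []
    seq = spec.dna_sequence
    frames = base_pair_frames(len(seq))
    for i, base in enumerate(seq):
        R, o = frames[i]
        dna_coords.extend(x for _, x, _ in _nucleotide_atoms(base, R, o, i > 0))
        if spec.duplex:
            Rr = R @ _FLIP
            dna_coords.extend(
                x for _, x, _ in _nucleotide_atoms(WC_COMPLEMENT[base], Rr, o,
                                                   True))
    dna_coords = np.array(dna_coords)

    helix = helix_backbone(spec.helix_length)
    helix_coords = np.vstack([np.vstack(list(r.values())) for r in helix])
    # start well outside the duplex, then slide along +x to the target offset
    shift0 = np.array([30.0, 0.0, dna_coords[:, 2].mean()
                       - helix_coords[:, 2].mean()])
    lo, hi = -40.0, 200.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        d = _min_distance(helix_coords + shift0 + np.array([mid, 0, 0]),
                          dna_coords)
        if d < spec.offset:
            lo = mid
        else:
            hi = mid
    shift = shift0 + np.array([0.5 * (lo + hi), 0.0, 0.0])

    n_prot = spec.helix_length + spec.n_missing
    lines: list[str] = []
    if spec.include_headers:
        if spec.n_missing:
            lines.append("REMARK 465 MISSING RESIDUES")
            lines.append("REMARK 465   M RES C SSSEQI")
            for k in range(1, spec.n_missing + 1):
                lines.append(f"REMARK 465     ALA {spec.protein_chain:1s} "
                             f"{k:5d} ")
        if spec.modres_at is not None:
            lines.append(f"MODRES FIXT MSE {spec.protein_chain:1s} "
                         f"{spec.modres_at:4d}  MET  SELENOMETHIONINE")
        for pos in spec.tag_positions:
            lines.append(f"SEQADV FIXT ALA {spec.protein_chain:1s} {pos:4d}"
                         f"{'':1s} {'':>4s} {'':>9s} {'':>3s} {'':5s} "
                         "EXPRESSION TAG")
        names = []
        for k in range(1, n_prot + 1):
            if spec.modres_at == k:
                names.append("MSE")
            else:
                names.append("ALA")
        for start in range(0, n_prot, 13):
            block = names[start:start + 13]
            ser = start // 13 + 1
            lines.append(f"SEQRES {ser:3d} {spec.protein_chain:1s} "
                         f"{n_prot:4d}  " + " ".join(f"{x:>3s}" for x in block))

    def emit_copy(copy_index: int, prot_chain: str, dna_f: str, dna_r: str,
                  serial_start: int) -> int:
        serial = serial_start
        displace = np.array([0.0, 80.0 * copy_index, 0.0])
        for k, res in enumerate(helix):
            author = spec.n_missing + k + 1
            resname = "MSE" if spec.modres_at == author else "ALA"
            het = resname == "MSE"
            for name in ("N", "CA", "C", "O", "CB"):
                element = name[0]
                lines.append(_pdb_atom_line(
                    serial, name, resname, prot_chain, author,
                    res[name] + shift + displace, element, het=het))
                serial += 1
        lines.append(f"TER   {serial:5d}      ALA {prot_chain:1s}"
                     f"{spec.n_missing + spec.helix_length:4d}")
        serial += 1
        for line in make_bdna(seq, duplex=spec.duplex, chain_forward=dna_f,
                              chain_reverse=dna_r, origin=displace,
                              as_lines=True):
            # re-serial the embedded DNA lines
            if line.startswith(("ATOM", "HETATM")):
                lines.append(line[:6] + f"{serial:5d}" + line[11:])
            else:
                lines.append(line[:6] + f"{serial:5d}" + line[11:])
            serial += 1
        return serial

    serial = 1
    chain_sets = [(spec.protein_chain, *spec.dna_chains)]
    if spec.copies > 1:
        extra = "DEFGHIJ"
        for ci in range(1, spec.copies):
            base_idx = 3 * (ci - 1)
            chain_sets.append((extra[base_idx], extra[base_idx + 1],
                               extra[base_idx + 2]))
    for ci, (pc, fc, rc) in enumerate(chain_sets):
        serial = emit_copy(ci, pc, fc, rc, serial)
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Synthetic training tables
# --------------------------------------------------------------------------

#: feature name -> (low, high) sampling range used for synthetic tables
def _feature_ranges(names: list[str]) -> list[tuple[float, float]]:
    ranges = []
    for name in names:
        if name.startswith("pssm_mean_"):
            ranges.append((0.2, 0.8))
        elif name == "pssm_mutation_odds":
            ranges.append((-1.0, 1.0))
        elif name == "net_volume":
            ranges.append((-170.0, 170.0))
        elif name == "net_hydrophobicity":
            ranges.append((-6.0, 6.0))
        elif name == "net_flexibility":
            ranges.append((-3.6, 3.6))
        elif name.startswith("class_"):
            ranges.append((0, 399 if "mutation_type" in name else 48))
        elif name.startswith("acc"):
            ranges.append((0.0, 250.0))
        elif name == "delta_acc":
            ranges.append((-100.0, 100.0))
        elif name in ("phi", "psi"):
            ranges.append((-180.0, 180.0))
        elif name.startswith("ss_ratio"):
            ranges.append((0.0, 0.8))
        elif "hbond" in name or "stack" in name:
            ranges.append((0.0, 15.0))
        elif name.startswith("delta_"):
            ranges.append((-8.0, 8.0))
        elif "contact" in name:
            ranges.append((0.0, 80.0))
        elif name in ("bp_type", "mismatch"):
            ranges.append((0, 1))
        elif name == "bp_category":
            ranges.append((0, 255))
        elif name.startswith(("pair_", "step_", "helical_")):
            ranges.append((-3.0, 40.0))
        else:
            ranges.append((0.0, 1.0))
    return ranges


def synth_training_table(n: int, task: str = "protein",
                         snr: float = np.inf, seed: int = 0):
    """Planted-signal feature table on the real feature manifest.

    The response is a sparse linear + one-interaction function of named
    features plus Gaussian noise scaled so var(signal)/var(noise) = snr;
    snr = inf plants a noiseless signal, snr = 0 a pure-noise response.
    The planted coefficients are stored in ``table.meta``.
    """
    from .encode import DNA_FEATURE_NAMES, PROTEIN_FEATURE_NAMES, manifest_hash
    from .mlcore import TrainingTable
    import pandas as pd

    if n < 20:
        raise ValueError("n must be >= 20")
    names = (PROTEIN_FEATURE_NAMES if task == "protein"
             else DNA_FEATURE_NAMES)
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in zip(names, _feature_ranges(list(names))):
        cols[name] = rng.uniform(lo, hi, size=n)
    X = pd.DataFrame(cols)

    if task == "protein":
        terms = {"net_hydrophobicity": 0.35, "delta_acc": 0.02,
                 "pssm_mutation_odds": 1.5}
        inter = ("net_volume", "ss_ratio_alpha_helix", 0.01)
    else:
        terms = {"step_twist": 0.05, "bp_type": 0.8,
                 "site_nt_aa_contacts": 0.12}
        inter = ("pair_propeller", "mismatch", 0.08)
    signal = np.zeros(n)
    for name, coef in terms.items():
        signal += coef * X[name].to_numpy()
    signal += inter[2] * X[inter[0]].to_numpy() * X[inter[1]].to_numpy()
    signal -= signal.mean()

    if snr == 0:
        y = rng.normal(0.0, 1.0, size=n)
    elif np.isinf(snr):
        y = signal.copy()
    else:
        noise_sd = signal.std(ddof=0) / np.sqrt(snr)
        y = signal + rng.normal(0.0, noise_sd, size=n)

    ids = [f"SYN{i:04d}" for i in range(n)]
    muts = [f"A:A{i + 1}G" for i in range(n)]
    return TrainingTable(
        complex_ids=ids, mutations=muts, X=X, y=y,
        manifest_hash=manifest_hash(task),
        meta={"task": task, "snr": snr, "seed": seed,
              "planted_linear": terms, "planted_interaction": inter},
    )
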
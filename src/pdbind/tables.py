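"""Constant tables shared across the feature pipeline.

Everything a feature value can depend on numerically is collected here so the
feature manifest can reference one authoritative copy: amino-acid alphabets
and class schemes, physicochemical scales, atomic radii, and the standard
reference-frame coordinates used to fit base frames.
"""

from __future__ import annotations

import numpy as np

# --------------------------------------------------------------------------
# Amino-acid alphabets
# --------------------------------------------------------------------------

#: PSI-BLAST ASCII PSSM column order; the canonical order for PSSM features.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Alphabetical one-letter order; used for the 400-label mutation-type scheme.
AA_ALPHABETICAL = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Common chemically modified residues and their standard parents, used as a
#: fallback when a file carries the modification but no MODRES header.
MODRES_PARENTS = {
    "MSE": "MET", "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "HYP": "PRO", "MLY": "LYS", "M3L": "LYS", "CME": "CYS", "KCX": "LYS",
    "PCA": "GLU", "LLP": "LYS",
}

# --------------------------------------------------------------------------
# Mutation class schemes.  Each scheme lists its classes in a fixed order;
# the class index of an amino acid is its class's position in that list.
# --------------------------------------------------------------------------

CLASS_SCHEMES: dict[str, list[set[str]]] = {
    # neutral, hydrophilic, hydrophobic
    "hydropathy": [
        set("GHPSTY"),
        set("DEKNQR"),
        set("ACFILMVW"),
    ],
    # nonpolar, polar-acidic, polar-basic, polar-neutral
    "polarity": [
        set("ACFILMVWGP"),
        set("DE"),
        set("KRH"),
        set("NQSTY"),
    ],
    # very small, small, medium, large, very large
    "size": [
        set("AGS"),
        set("CPDNT"),
        set("VEHQ"),
        set("ILMKR"),
        set("FWY"),
    ],
    # non-H-bonding, donor, donor-acceptor, acceptor
    "hbond": [
        set("ILMVCPFAG"),
        set("KRW"),
        set("HQNTYS"),
        set("ED"),
    ],
    # basic, amide, acidic, sulfur, hydroxyl, aromatic, aliphatic
    "chemical": [
        set("KRH"),
        set("QN"),
        set("DE"),
        set("MC"),
        set("ST"),
        set("WYF"),
        set("ILVPAG"),
    ],
}

#: mutation_type is the identity scheme over the 20 amino acids.
CLASS_SCHEMES["mutation_type"] = [set(a) for a in AA_ALPHABETICAL]


def _check_partitions() -> None:
    for name, classes in CLASS_SCHEMES.items():
        seen: set[str] = set()
        for cls in classes:
            if cls & seen:
                raise AssertionError(f"scheme {name}: overlapping classes")
            seen |= cls
        if seen != set(AA_ALPHABETICAL):
            raise AssertionError(f"scheme {name}: not a partition of the 20 AAs")


_check_partitions()

# --------------------------------------------------------------------------
# Physicochemical scales
# --------------------------------------------------------------------------

#: Residue volumes, A^3 (Zamyatnin).
AA_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

#: Side-chain hydrophobicity index (Moon-Fleming water-to-bilayer scale,
#: kcal/mol; more negative = more hydrophobic, Ala = 0 reference).
AA_HYDROPHOBICITY = {
    "A": 0.00, "R": 2.57, "N": 1.27, "D": 3.64, "C": -0.49,
    "Q": 1.55, "E": 2.67, "G": 1.15, "H": 2.33, "I": -1.81,
    "L": -1.61, "K": 2.39, "M": -1.40, "F": -2.20, "P": 1.44,
    "S": 0.57, "T": 0.34, "W": -2.09, "Y": -0.70, "V": -1.20,
}

#: Compact backbone-independent rotamer counts (Dunbrack-style library);
#: Gly and Ala have a single (side-chain-free) state.
AA_ROTAMER_COUNT = {
    "A": 1, "G": 1, "P": 2, "S": 3, "C": 3, "T": 3, "V": 3,
    "I": 7, "L": 5, "D": 5, "N": 7, "H": 8, "F": 4, "Y": 4,
    "W": 7, "M": 13, "E": 8, "Q": 9, "K": 27, "R": 34,
}

# --------------------------------------------------------------------------
# Atomic radii
# --------------------------------------------------------------------------


def sasa_radius(element: str, atom_name: str) -> float:
    """DSSP-compatible radius (A) for solvent-accessibility calculations."""
    element = element.upper()
    if element == "C":
        # carbonyl carbon is slightly smaller than tetrahedral/aromatic C
        return 1.76 if atom_name in ("C",) else 1.87
    return {"N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90}.get(element, 1.80)


#: van der Waals radii (A) for clash detection in side-chain placement.
VDW_RADIUS = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}


def vdw_radius(element: str) -> float:
    return VDW_RADIUS.get(element.upper(), 1.70)


# --------------------------------------------------------------------------
# DNA vocabulary
# --------------------------------------------------------------------------

DNA_RESNAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
                "A": "A", "C": "C", "G": "G", "T": "T"}
WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Base ring + exocyclic heavy atoms (the "base" moiety).
BASE_ATOMS = {
    "A": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"},
    "G": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "T": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C5M", "C6"},
}

#: Ring atoms used for base-frame fitting and stacking planes.
BASE_RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

#: Base N/O atoms that can donate/accept hydrogen bonds.
BASE_POLAR_ATOMS = {
    "A": {"N1", "N3", "N6", "N7"},
    "G": {"N1", "N2", "N3", "N7", "O6"},
    "C": {"N3", "N4", "O2"},
    "T": {"N3", "O2", "O4"},
}

#: Phosphate-group atoms for phosphate hydrogen bonds.
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O1P", "O2P", "O5'", "O3'", "O5*", "O3*"}

#: Planar side-chain groups eligible for base stacking.
RESIDUE_PLANES = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "ARG": ["NE", "CZ", "NH1", "NH2"],
}

# --------------------------------------------------------------------------
# Standard reference frame base coordinates (Olson consensus geometry).
# Each base lies in its standard frame: origin at the pair center, z normal
# to the base plane, C1' at (-2.477, 5.399, 0).  Coordinates in Angstrom.
# --------------------------------------------------------------------------

STANDARD_BASE_COORDS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.399, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.477, 5.399, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}

#: Approximate sugar-phosphate positions in the standard base frame, used by
#: the fiber-model fixture generator (plausible B-DNA backbone placement).
FIXTURE_BACKBONE_COORDS: dict[str, tuple[float, float, float]] = {
    "P": (-4.30, 7.65, 0.85),
    "OP1": (-5.50, 8.35, 0.45),
    "OP2": (-4.15, 7.65, 2.30),
    "O5'": (-3.05, 8.35, 0.25),
    "O3'": (-3.65, 6.25, -1.35),
}


def standard_base_frame_coords(base: str, atom_names) -> np.ndarray:
    """Standard-frame coordinates for the named atoms of ``base`` (n x 3)."""
    table = STANDARD_BASE_COORDS[base]
    return np.array([table[n] for n in atom_names], dtype=float)
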
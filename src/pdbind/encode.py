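"""Mutation encodings and assembly of the frozen feature vectors.

The protein-mutation vector has 49 entries, the DNA-mutation vector 35; the
layouts are frozen by a versioned manifest so trained models and feature
tables remain interchangeable.  Conventions recorded in the manifest:
interaction deltas are oriented mutant - wild-type (matching the ddG sign
convention ddG = dG(mutant) - dG(wild-type)), accessibility change is
acc_wt - acc_mut, and undefined torsions carry the 360.0 sentinel.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np

from . import geometry, nacontacts, pssm as pssm_mod
from .structio import ComplexStructure, extract_protein_sequence
from .tables import (AA3_TO_1, AA_ALPHABETICAL, AA_HYDROPHOBICITY,
                     AA_ROTAMER_COUNT, AA_VOLUME, CLASS_SCHEMES, PSSM_ALPHABET,
                     WC_COMPLEMENT)

MANIFEST_VERSION = "1.0"

CANONICAL_PAIRS = {"AT", "TA", "GC", "CG"}

_PROT_MUT_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]):)?"
                          r"(?P<wt>[A-Z])(?P<pos>\d+)(?P<icode>[A-Za-z]?)"
                          r"(?P<mut>[A-Z])$")
_DNA_MUT_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]):(?P<pos>\d+):"
                         r"(?P<wt>[ACGT]{1,2})>(?P<mut>[ACGT]{1,2})$")


# --------------------------------------------------------------------------
# Mutation specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationSpec:
    """One amino-acid point mutation in author numbering."""
    chain_id: str
    site: int
    wt_aa: str
    mut_aa: str
    insertion_code: str = ""

    def __post_init__(self):
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AA_ALPHABETICAL:
                raise ValueError(f"unknown amino acid {aa!r}")

    def __str__(self):
        return (f"{self.chain_id}:{self.wt_aa}{self.site}"
                f"{self.insertion_code}{self.mut_aa}")


@dataclass(frozen=True)
class DnaMutationSpec:
    """One base or base-pair mutation; reverse = None for single strands."""
    chain_id: str
    site: int
    wt_forward: str
    mut_forward: str
    wt_reverse: str | None = None
    mut_reverse: str | None = None
    insertion_code: str = ""

    def __post_init__(self):
        for b in (self.wt_forward, self.mut_forward):
            if b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")
        for b in (self.wt_reverse, self.mut_reverse):
            if b is not None and b not in "ACGT":
                raise ValueError(f"invalid base {b!r}")

    def __str__(self):
        wt = self.wt_forward + (self.wt_reverse or "")
        mut = self.mut_forward + (self.mut_reverse or "")
        return f"{self.chain_id}:{self.site}:{wt}>{mut}"


def parse_protein_mutation(text: str, default_chain: str = "A") -> MutationSpec:
    m = _PROT_MUT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse protein mutation {text!r} "
                         "(expected e.g. A:R52S)")
    return MutationSpec(m.group("chain") or default_chain,
                        int(m.group("pos")), m.group("wt"), m.group("mut"),
                        m.group("icode") or "")


def parse_dna_mutation(text: str) -> DnaMutationSpec:
    m = _DNA_MUT_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse DNA mutation {text!r} "
                         "(expected e.g. B:5:AT>GC or B:5:A>G)")
    wt, mut = m.group("wt"), m.group("mut")
    if len(wt) != len(mut):
        raise ValueError(f"wild-type and mutant of {text!r} differ in arity")
    return DnaMutationSpec(m.group("chain"), int(m.group("pos")),
                           wt[0], mut[0],
                           wt[1] if len(wt) == 2 else None,
                           mut[1] if len(mut) == 2 else None)


# --------------------------------------------------------------------------
# Categorical and physicochemical encodings
# --------------------------------------------------------------------------


def class_index(aa: str, scheme: str) -> int:
    for idx, members in enumerate(CLASS_SCHEMES[scheme]):
        if aa in members:
            return idx
    raise ValueError(f"unknown amino acid {aa!r}")


def class_label(wt: str, mut: str, scheme: str) -> int:
    """Combined wild-type/mutant class label: idx(wt) * K + idx(mut)."""
    classes = CLASS_SCHEMES[scheme]
    return class_index(wt, scheme) * len(classes) + class_index(mut, scheme)


def physchem_deltas(wt: str, mut: str) -> tuple[float, float, float]:
    """(net volume, net hydrophobicity, net flexibility), mutant - wild-type.

    Net flexibility is the log-ratio of rotamer counts, ln n(mut) - ln n(wt).
    """
    for aa in (wt, mut):
        if aa not in AA_VOLUME:
            raise ValueError(f"unknown amino acid {aa!r}")
    return (AA_VOLUME[mut] - AA_VOLUME[wt],
            AA_HYDROPHOBICITY[mut] - AA_HYDROPHOBICITY[wt],
            float(np.log(AA_ROTAMER_COUNT[mut]) - np.log(AA_ROTAMER_COUNT[wt])))


def base_pair_index(pair: str) -> int:
    """Lexicographic index of an ordered two-base pair: AA=0 ... TT=15."""
    if len(pair) != 2 or any(b not in "ACGT" for b in pair):
        raise ValueError(f"invalid base pair {pair!r}")
    return "ACGT".index(pair[0]) * 4 + "ACGT".index(pair[1])


def dna_mutation_encoding(m: DnaMutationSpec) -> tuple[int, int, int]:
    """(bp_type, mismatch, bp_category) for a DNA mutation.

    bp_type encodes the wild-type pair's hydrogen bonding (0 = A:T, 1 = G:C);
    mismatch flags a non-canonical mutant pair; bp_category combines the 16
    ordered wild and mutant pairs as BPI(wt) * 16 + BPI(mut).  Single-stranded
    sites derive the nominal pair from the Watson-Crick complement.
    """
    if m.wt_reverse is None:
        bp_type = 0 if m.wt_forward in "AT" else 1
        mismatch = 0
        wt_pair = m.wt_forward + WC_COMPLEMENT[m.wt_forward]
        mut_pair = m.mut_forward + (m.mut_reverse
                                    or WC_COMPLEMENT[m.mut_forward])
    else:
        wt_pair = m.wt_forward + m.wt_reverse
        if wt_pair not in CANONICAL_PAIRS:
            raise ValueError(f"non-canonical wild-type base pair {wt_pair!r}")
        bp_type = 0 if set(wt_pair) == {"A", "T"} else 1
        mut_pair = m.mut_forward + (m.mut_reverse
                                    or WC_COMPLEMENT[m.mut_forward])
        mismatch = 0 if mut_pair in CANONICAL_PAIRS else 1
    return (bp_type, mismatch,
            base_pair_index(wt_pair) * 16 + base_pair_index(mut_pair))


# --------------------------------------------------------------------------
# Feature manifests
# --------------------------------------------------------------------------

SS_RATIO_NAMES = ("ss_ratio_alpha_helix", "ss_ratio_beta_bridge",
                  "ss_ratio_strand", "ss_ratio_three_ten_helix",
                  "ss_ratio_turn", "ss_ratio_bend")

_COUNT_NAMES = ("nt_aa_contacts", "base_aa_hbonds", "phosphate_aa_hbonds",
                "base_aa_stacks")

PROTEIN_FEATURE_NAMES: tuple[str, ...] = (
    tuple(f"pssm_mean_{a}" for a in PSSM_ALPHABET)
    + ("pssm_mutation_odds", "net_volume", "net_hydrophobicity",
       "net_flexibility",
       "class_hydropathy", "class_polarity", "class_size", "class_hbond",
       "class_chemical", "class_mutation_type",
       "acc_wt", "acc_mut", "delta_acc", "phi", "psi")
    + SS_RATIO_NAMES
    + _COUNT_NAMES
    + tuple(f"delta_{n}" for n in _COUNT_NAMES)
)

DNA_FEATURE_NAMES: tuple[str, ...] = (
    SS_RATIO_NAMES
    + ("pair_shear", "pair_stretch", "pair_stagger", "pair_buckle",
       "pair_propeller", "pair_opening",
       "step_shift", "step_slide", "step_rise", "step_tilt", "step_roll",
       "step_twist",
       "helical_x_displacement", "helical_y_displacement", "helical_rise",
       "helical_inclination", "helical_tip", "helical_twist",
       "bp_type", "mismatch", "bp_category")
    + _COUNT_NAMES
    + tuple(f"site_{n}" for n in _COUNT_NAMES)
)

assert len(PROTEIN_FEATURE_NAMES) == 49
assert len(DNA_FEATURE_NAMES) == 35


def feature_manifest(task: str) -> dict:
    """Frozen description of a feature layout and its conventions."""
    names = {"protein": PROTEIN_FEATURE_NAMES,
             "dna": DNA_FEATURE_NAMES}[task]
    return {
        "version": MANIFEST_VERSION,
        "task": task,
        "features": list(names),
        "conventions": {
            "ddg": "dG(mutant) - dG(wild-type), kcal/mol",
            "interaction_deltas": "mutant - wild-type",
            "delta_acc": "acc_wt - acc_mut",
            "torsion_sentinel": geometry.TORSION_SENTINEL,
            "ss_ratio_order": list(geometry.SS_COMPOSITION_ORDER),
            "single_strand_geometry": "all 18 pair/step/helical features 0.0",
            "bp_index": "lexicographic over (forward, reverse), A<C<G<T",
            "pssm_alphabet": PSSM_ALPHABET,
            "class_index_order": {k: [sorted(c) for c in v]
                                  for k, v in CLASS_SCHEMES.items()},
        },
        "tables": {
            "volume": AA_VOLUME,
            "hydrophobicity": AA_HYDROPHOBICITY,
            "rotamer_counts": AA_ROTAMER_COUNT,
        },
    }


def manifest_hash(task: str) -> str:
    payload = json.dumps(feature_manifest(task), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray
    manifest_version: str = MANIFEST_VERSION
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names/values length mismatch")

    def __len__(self):
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


# --------------------------------------------------------------------------
# Assembly
# --------------------------------------------------------------------------


def _locate_protein_site(cx: ComplexStructure, m: MutationSpec):
    chain = cx.get_chain(m.chain_id)
    if chain is None or chain.kind != "protein":
        raise ValueError(f"no protein chain {m.chain_id!r}")
    res = chain.get_residue(m.site, m.insertion_code)
    if res is None:
        raise ValueError(f"mutation site missing: residue {m.site}"
                         f"{m.insertion_code} not in chain {m.chain_id}")
    one = AA3_TO_1.get(res.name)
    if one is None:
        from .tables import MODRES_PARENTS
        one = AA3_TO_1.get(MODRES_PARENTS.get(res.name, ""), None)
    if one != m.wt_aa:
        raise ValueError(
            f"wild-type residue mismatch at {m.chain_id}:{m.site}: structure "
            f"has {res.name} ({one}), mutation names {m.wt_aa}")
    if not res.has_backbone(("N", "CA", "C")):
        raise ValueError(
            "backbone incomplete at the mutation site (alpha-carbon-only "
            "structure?): secondary structure cannot be determined")
    return chain, res


def assemble_protein_features(cx_wt: ComplexStructure,
                              cx_mut: ComplexStructure,
                              profile: pssm_mod.PSSMMatrix | None,
                              m: MutationSpec,
                              config: nacontacts.ContactConfig =
                              nacontacts.DEFAULT_CONTACT_CONFIG
                              ) -> FeatureVector:
    """The 49-entry protein-mutation feature vector.

    ``cx_mut`` is the modeled mutant complex (see :mod:`pdbind.mutmodel`);
    passing the wild-type complex again evaluates a self-mutation, for which
    every delta feature vanishes.
    """
    _chain, _res = _locate_protein_site(cx_wt, m)
    record = extract_protein_sequence(cx_wt, m.chain_id)
    try:
        site_index = record.author_numbers.index(m.site) + 1
    except ValueError:
        raise ValueError(f"mutation site {m.site} not in extracted sequence")

    if profile is None:
        profile = pssm_mod.pssm_from_blosum62(record.one_letter_sequence)
    if len(profile.sequence) != len(record.one_letter_sequence):
        raise ValueError(
            f"PSSM length {len(profile.sequence)} does not match protein "
            f"sequence length {len(record.one_letter_sequence)}")

    comp = pssm_mod.composition_features(profile)
    odds = pssm_mod.mutation_odds(profile, site_index, m.wt_aa, m.mut_aa)
    net_vol, net_hyd, net_flex = physchem_deltas(m.wt_aa, m.mut_aa)
    labels = [class_label(m.wt_aa, m.mut_aa, s)
              for s in ("hydropathy", "polarity", "size", "hbond",
                        "chemical", "mutation_type")]

    key = (m.chain_id, m.site, m.insertion_code)
    acc_wt_map = geometry.solvent_accessibility(cx_wt)
    acc_mut_map = geometry.solvent_accessibility(cx_mut)
    if key not in acc_wt_map or key not in acc_mut_map:
        raise ValueError(f"no accessibility for mutation site {key}")
    acc_wt, acc_mut = acc_wt_map[key], acc_mut_map[key]
    phi, psi = geometry.backbone_torsions(cx_wt, m.chain_id, m.site,
                                          m.insertion_code)
    ratios = geometry.ss_composition(cx_wt).as_vector()

    counts_wt = nacontacts.count_interactions(cx_wt, config)
    counts_mut = nacontacts.count_interactions(cx_mut, config)
    deltas = nacontacts.delta_interactions(counts_wt, counts_mut)

    values = np.concatenate([
        comp, [odds, net_vol, net_hyd, net_flex], labels,
        [acc_wt, acc_mut, acc_wt - acc_mut, phi, psi], ratios,
        counts_wt.as_tuple(), deltas])
    return FeatureVector(PROTEIN_FEATURE_NAMES, values,
                         metadata={"pssm_source": profile.source,
                                   "mutation": str(m)})


def assemble_dna_features(cx_wt: ComplexStructure, m: DnaMutationSpec,
                          config: nacontacts.ContactConfig =
                          nacontacts.DEFAULT_CONTACT_CONFIG) -> FeatureVector:
    """The 35-entry DNA-mutation feature vector.

    Single-stranded (unpaired) sites carry zeros for the 18 pair/step/helical
    geometry features; the step at the mutation site runs to the 3' neighbour
    pair, falling back to the 5' step at the 3' terminus.
    """
    chain = cx_wt.get_chain(m.chain_id)
    if chain is None or chain.kind != "dna":
        raise ValueError(f"no DNA chain {m.chain_id!r}")
    res = chain.get_residue(m.site, m.insertion_code)
    if res is None:
        raise ValueError(f"mutation site missing: nucleotide {m.site} not in "
                         f"chain {m.chain_id}")
    if res.base != m.wt_forward:
        raise ValueError(
            f"wild-type base mismatch at {m.chain_id}:{m.site}: structure "
            f"has {res.base}, mutation names {m.wt_forward}")

    pairs = nacontacts.find_base_pairs(cx_wt)
    bp = nacontacts.pair_for_site(pairs, m.chain_id, m.site, m.insertion_code)
    geometry18 = np.zeros(18)
    if bp is not None and bp.paired:
        geometry18[:6] = nacontacts.pair_parameters(bp)
        neighbour = nacontacts.pair_for_site(pairs, m.chain_id, m.site + 1,
                                             m.insertion_code)
        step_from, step_to = bp, neighbour
        if neighbour is None or not neighbour.paired:
            prev = nacontacts.pair_for_site(pairs, m.chain_id, m.site - 1,
                                            m.insertion_code)
            if prev is not None and prev.paired:
                step_from, step_to = prev, bp
            else:
                step_to = None
        if step_to is not None:
            geometry18[6:] = nacontacts.step_parameters(step_from, step_to)

    bp_type, mismatch, bp_category = dna_mutation_encoding(m)
    counts = nacontacts.count_interactions(cx_wt, config)
    site_counts = nacontacts.site_interactions(cx_wt, m.chain_id, m.site,
                                               m.insertion_code, config)
    ratios = geometry.ss_composition(cx_wt).as_vector()

    values = np.concatenate([
        ratios, geometry18, [bp_type, mismatch, bp_category],
        counts.as_tuple(), site_counts.as_tuple()])
    return FeatureVector(DNA_FEATURE_NAMES, values,
                         metadata={"mutation": str(m),
                                   "paired": bool(bp is not None and bp.paired)})


# --------------------------------------------------------------------------
# End-to-end feature pipelines
# --------------------------------------------------------------------------


def protein_feature_pipeline(cx: ComplexStructure, m: MutationSpec,
                             profile: pssm_mod.PSSMMatrix | None = None,
                             mutant_cx: ComplexStructure | None = None,
                             config: nacontacts.ContactConfig =
                             nacontacts.DEFAULT_CONTACT_CONFIG
                             ) -> FeatureVector:
    """Model the mutant complex (unless supplied externally) and assemble the
    protein feature vector."""
    from . import mutmodel

    _locate_protein_site(cx, m)  # fail fast on bad sites / Calpha-only input
    if mutant_cx is None:
        mutant_cx = mutmodel.mutant_complex(cx, m)
    return assemble_protein_features(cx, mutant_cx, profile, m, config)
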
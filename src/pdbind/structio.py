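"""Reading, cleaning and writing protein-DNA complex structures.

The in-memory container is a light chain/residue/atom hierarchy tailored to
the feature pipeline: author numbering (with insertion codes) is preserved as
the coordinate system for mutation sites, altlocs are resolved at parse time,
and the PDB header records needed to reconstruct the full protein sequence
(SEQRES, REMARK 465, MODRES, SEQADV) are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .tables import AA3_TO_1, DNA_RESNAMES, MODRES_PARENTS

logger = logging.getLogger(__name__)

INTERFACE_CUTOFF = 5.0  # A; two chains interact if any heavy-atom pair is closer


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


# --------------------------------------------------------------------------
# Container types
# --------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    het: bool = False
    occupancy: float = 1.0

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.xyz.copy(), self.het,
                    self.occupancy)


@dataclass
class Residue:
    name: str
    author_number: int
    insertion_code: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.author_number, self.insertion_code)

    @property
    def is_standard_aa(self) -> bool:
        return self.name in AA3_TO_1

    @property
    def is_dna(self) -> bool:
        return self.name in DNA_RESNAMES

    @property
    def base(self) -> str | None:
        """One-letter base code for nucleotides, else None."""
        return DNA_RESNAMES.get(self.name)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms.values() if a.element not in ("H", "D")]

    def heavy_coords(self) -> np.ndarray:
        atoms = self.heavy_atoms()
        if not atoms:
            return np.zeros((0, 3))
        return np.array([a.xyz for a in atoms])

    def has_backbone(self, names=("N", "CA", "C")) -> bool:
        return all(n in self.atoms for n in names)

    def copy(self) -> "Residue":
        return Residue(self.name, self.author_number, self.insertion_code,
                       {n: a.copy() for n, a in self.atoms.items()})


@dataclass
class Chain:
    chain_id: str
    kind: str  # protein | dna | other
    residues: list[Residue] = field(default_factory=list)

    def get_residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.author_number == number and r.insertion_code == icode:
                return r
        return None

    def heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues]
        parts = [p for p in parts if len(p)]
        if not parts:
            return np.zeros((0, 3))
        return np.vstack(parts)

    def residue_names(self) -> list[str]:
        return [r.name for r in self.residues]

    def copy(self) -> "Chain":
        return Chain(self.chain_id, self.kind, [r.copy() for r in self.residues])


@dataclass
class ComplexStructure:
    chains: list[Chain] = field(default_factory=list)
    # header records, kept verbatim enough to round-trip
    seqres: dict[str, list[str]] = field(default_factory=dict)
    remark465: list[tuple[str, str, int, str]] = field(default_factory=list)
    modres: dict[tuple[str, int, str], tuple[str, str]] = field(default_factory=dict)
    seqadv_tags: set[tuple[str, int, str]] = field(default_factory=set)

    def get_chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.kind == "protein"]

    def dna_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.kind == "dna"]

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            [c.copy() for c in self.chains], dict(self.seqres),
            list(self.remark465), dict(self.modres), set(self.seqadv_tags))

    def same_as(self, other: "ComplexStructure", tol: float = 0.0) -> bool:
        """Structural equality: chains, residues, atom names and coordinates."""
        if [c.chain_id for c in self.chains] != [c.chain_id for c in other.chains]:
            return False
        for ca, cb in zip(self.chains, other.chains):
            if ca.kind != cb.kind or len(ca.residues) != len(cb.residues):
                return False
            for ra, rb in zip(ca.residues, cb.residues):
                if (ra.name, ra.key) != (rb.name, rb.key):
                    return False
                if set(ra.atoms) != set(rb.atoms):
                    return False
                for n, a in ra.atoms.items():
                    if not np.allclose(a.xyz, rb.atoms[n].xyz, atol=max(tol, 1e-9)):
                        return False
        return True


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------


def _validate_coordinate_lines(text: str) -> int:
    n_coord = 0
    for i, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_coord += 1
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fragment = line[lo:hi].strip()
                try:
                    float(fragment)
                except ValueError:
                    raise PDBParseError(
                        f"line {i}: non-numeric {what} coordinate "
                        f"{fragment!r}: {line.rstrip()}") from None
    return n_coord


def _parse_headers(text: str):
    seqres: dict[str, list[str]] = {}
    remark465: list[tuple[str, str, int, str]] = []
    modres: dict[tuple[str, int, str], tuple[str, str]] = {}
    seqadv_tags: set[tuple[str, int, str]] = set()
    in_465 = False
    for line in text.splitlines():
        rec = line[:6]
        if rec == "SEQRES":
            chain = line[11].strip()
            seqres.setdefault(chain, []).extend(line[19:].split())
        elif rec == "REMARK" and line[7:10] == "465":
            body = line[10:]
            fields = body.split()
            # data rows look like "  MET A   1"; header rows are prose
            if len(fields) >= 3 and fields[-1].lstrip("-").rstrip(
                    "ABCDEFGHIJKLMNOPQRSTUVWXYZ").isdigit() and len(fields[0]) <= 3:
                resname, chain = fields[0], fields[1]
                numtext = fields[2]
                icode = ""
                if numtext and numtext[-1].isalpha():
                    numtext, icode = numtext[:-1], numtext[-1]
                try:
                    number = int(numtext)
                except ValueError:
                    in_465 = True
                    continue
                if resname.upper() == "RES":  # column header row
                    continue
                remark465.append((chain, resname, number, icode))
            in_465 = True
        elif rec == "MODRES":
            resname = line[12:15].strip()
            chain = line[16].strip()
            number = int(line[18:22])
            icode = line[22].strip()
            parent = line[24:27].strip()
            modres[(chain, number, icode)] = (resname, parent)
        elif rec == "SEQADV":
            comment = line[49:].strip().upper()
            if "EXPRESSION TAG" in comment or "CLONING ARTIFACT" in comment:
                chain = line[16].strip()
                numtext = line[18:22].strip()
                icode = line[22].strip()
                if numtext:
                    seqadv_tags.add((chain, int(numtext), icode))
    return seqres, remark465, modres, seqadv_tags


def _classify(residues: list[Residue], modres_names: set[str]) -> str:
    protein = sum(r.is_standard_aa or r.name in MODRES_PARENTS
                  or r.name in modres_names for r in residues)
    dna = sum(r.is_dna for r in residues)
    if protein and protein >= dna:
        return "protein"
    if dna:
        return "dna"
    return "other"


def parse_complex(pdb_text: str) -> ComplexStructure:
    """Parse PDB text into a :class:`ComplexStructure`.

    Chains are classified protein/dna/other by residue vocabulary; altlocs
    are resolved to the highest-occupancy (then lexicographically first)
    conformer.
    """
    if not pdb_text.strip():
        raise PDBParseError("empty input")
    n_coord = _validate_coordinate_lines(pdb_text)
    if n_coord == 0:
        raise PDBParseError("no ATOM/HETATM records found")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"unreadable PDB text: {exc}") from exc
    seqres, remark465, modres, seqadv_tags = _parse_headers(pdb_text)
    modres_names = {v[0] for v in modres.values()}

    cx = ComplexStructure(seqres=seqres, remark465=remark465, modres=modres,
                          seqadv_tags=seqadv_tags)
    if len(st) == 0:
        raise PDBParseError("no models in PDB text")
    model = st[0]
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            res = Residue(gres.name.strip(),
                          gres.seqid.num,
                          (gres.seqid.icode or "").strip())
            chosen: dict[str, gemmi.Atom] = {}
            for atom in gres:
                prev = chosen.get(atom.name)
                if prev is None:
                    chosen[atom.name] = atom
                else:
                    better = (atom.occ > prev.occ
                              or (atom.occ == prev.occ
                                  and (atom.altloc or "") < (prev.altloc or "")))
                    if better:
                        chosen[atom.name] = atom
            for name, atom in chosen.items():
                res.atoms[name] = Atom(
                    name=name,
                    element=atom.element.name.upper(),
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    het=gres.het_flag == "H",
                    occupancy=atom.occ,
                )
            residues.append(res)
        kind = _classify(residues, modres_names)
        cx.chains.append(Chain(gchain.name, kind, residues))
    return cx


# --------------------------------------------------------------------------
# Sequence reconstruction
# --------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    chain_id: str
    one_letter_sequence: str
    provenance: list[str]            # per kept position: coordinates|REMARK465|SEQRES
    author_numbers: list[int | None]  # per kept position
    excluded_tag_positions: list[int] = field(default_factory=list)

    def to_fasta(self, name: str | None = None) -> str:
        header = name or f"chain_{self.chain_id}"
        return f">{header}\n{self.one_letter_sequence}\n"


def _to_one_letter(resname: str, cx: ComplexStructure, chain_id: str,
                   number: int, icode: str) -> str | None:
    if resname in AA3_TO_1:
        return AA3_TO_1[resname]
    entry = cx.modres.get((chain_id, number, icode))
    if entry and entry[0] == resname and entry[1] in AA3_TO_1:
        return AA3_TO_1[entry[1]]
    if resname in MODRES_PARENTS:
        return AA3_TO_1[MODRES_PARENTS[resname]]
    return None


def extract_protein_sequence(source, chain_id: str) -> SequenceRecord:
    """Reconstruct the full protein sequence of one chain.

    Coordinate residues are merged with REMARK 465 missing residues and
    reconciled against SEQRES; MODRES entries are reverted to their standard
    parents and SEQADV expression-tag residues are excluded.
    """
    cx = parse_complex(source) if isinstance(source, str) else source
    chain = cx.get_chain(chain_id)
    if chain is None:
        raise ValueError(f"chain {chain_id!r} not found")
    if chain.kind != "protein":
        raise ValueError(f"chain {chain_id!r} is not a protein chain")

    merged: list[tuple[int, str, str, str]] = []  # (number, icode, resname, prov)
    for res in chain.residues:
        one = _to_one_letter(res.name, cx, chain_id, res.author_number,
                             res.insertion_code)
        if one is None:
            continue  # waters/ligands sharing the chain id
        merged.append((res.author_number, res.insertion_code, res.name,
                       "coordinates"))
    for rchain, resname, number, icode in cx.remark465:
        if rchain == chain_id:
            merged.append((number, icode, resname, "REMARK465"))
    merged.sort(key=lambda t: (t[0], t[1]))

    seqres = cx.seqres.get(chain_id)
    letters: list[str] = []
    provenance: list[str] = []
    numbers: list[int | None] = []
    conflicts: list[str] = []
    for number, icode, resname, prov in merged:
        one = _to_one_letter(resname, cx, chain_id, number, icode)
        if one is None:
            conflicts.append(f"{resname}{number}{icode}")
            continue
        letters.append(one)
        provenance.append(prov)
        numbers.append(number)
    if conflicts:
        raise ValueError("unmappable residues: " + ", ".join(conflicts))

    if seqres is not None:
        seqres_letters = []
        for i, name in enumerate(seqres):
            one = AA3_TO_1.get(name)
            if one is None:
                one = AA3_TO_1.get(MODRES_PARENTS.get(name, ""), None)
            if one is None:
                # fall back to any MODRES header entry naming this residue
                for (mc, _n, _i), (mname, parent) in cx.modres.items():
                    if mc == chain_id and mname == name:
                        one = AA3_TO_1.get(parent)
                        break
            seqres_letters.append(one or "X")
        if len(seqres_letters) != len(letters):
            raise ValueError(
                f"SEQRES length {len(seqres_letters)} does not match merged "
                f"coordinate+REMARK465 sequence length {len(letters)} "
                f"for chain {chain_id}")
        bad = [i + 1 for i, (a, b) in enumerate(zip(letters, seqres_letters))
               if b != "X" and a != b]
        if bad:
            raise ValueError(
                f"SEQRES/coordinate conflict for chain {chain_id} at merged "
                f"positions {bad}")
    else:
        logger.warning("chain %s: no SEQRES record; sequence taken from "
                       "coordinates and REMARK 465 only", chain_id)

    tags = {(n, i) for (c, n, i) in cx.seqadv_tags if c == chain_id}
    keep_letters, keep_prov, keep_numbers, excluded = [], [], [], []
    for letter, prov, number in zip(letters, provenance, numbers):
        icode = ""
        if (number, icode) in tags:
            excluded.append(number)
            continue
        keep_letters.append(letter)
        keep_prov.append(prov)
        keep_numbers.append(number)
    return SequenceRecord(chain_id, "".join(keep_letters), keep_prov,
                          keep_numbers, excluded)


# --------------------------------------------------------------------------
# Interfaces and cleaning
# --------------------------------------------------------------------------


def chains_interact(a: Chain, b: Chain, threshold: float = INTERFACE_CUTOFF) -> bool:
    """True iff any heavy-atom pair across the two chains is within threshold."""
    ca, cb = a.heavy_coords(), b.heavy_coords()
    if not len(ca) or not len(cb):
        raise ValueError("cannot test interaction of an empty chain")
    if a is b:
        return True
    tree = cKDTree(cb)
    dists, _ = tree.query(ca, k=1, distance_upper_bound=threshold + 1e-9)
    return bool(np.any(np.isfinite(dists) & (dists <= threshold)))


def _chains_are_copies(a: Chain, b: Chain, min_identity: float = 0.95) -> bool:
    if a.kind != b.kind or len(a.residues) != len(b.residues) or not a.residues:
        return False
    same = sum(x == y for x, y in zip(a.residue_names(), b.residue_names()))
    return same / len(a.residues) >= min_identity


def clean_complex(cx: ComplexStructure, protein_chain: str) -> ComplexStructure:
    """Reduce to a single copy of the interacting protein-DNA assembly.

    Keeps the named protein chain, every DNA chain interacting with it
    (transitively closed over DNA-DNA partners, so both strands of a duplex
    survive), and any non-polymer chain touching the kept protein.  Duplicate
    crystallographic copies among the kept DNA are pruned.
    """
    prot = cx.get_chain(protein_chain)
    if prot is None:
        raise ValueError(f"protein chain {protein_chain!r} not found")
    if prot.kind != "protein":
        raise ValueError(f"chain {protein_chain!r} is not a protein chain")

    dna = cx.dna_chains()
    kept_dna = [c for c in dna if chains_interact(prot, c)]
    changed = True
    while changed:
        changed = False
        for c in dna:
            if c in kept_dna:
                continue
            if any(chains_interact(c, k) for k in kept_dna):
                kept_dna.append(c)
                changed = True
    if not kept_dna:
        raise ValueError("no protein-DNA interface: the selected protein "
                         f"chain {protein_chain!r} contacts no DNA within "
                         f"{INTERFACE_CUTOFF} A")

    # prune duplicate crystallographic DNA copies: copies that do not touch
    # each other (true duplex partners do) collapse to the first by chain id
    kept_dna.sort(key=lambda c: c.chain_id)
    pruned: list[Chain] = []
    for c in kept_dna:
        dup = any(_chains_are_copies(c, k) and not chains_interact(c, k)
                  for k in pruned)
        if not dup:
            pruned.append(c)

    others = [c for c in cx.chains
              if c.kind == "other" and len(c.heavy_coords())
              and chains_interact(prot, c)]

    keep_ids = [prot.chain_id] + [c.chain_id for c in pruned] + \
        [c.chain_id for c in others]
    out = ComplexStructure(seqres={k: v for k, v in cx.seqres.items()
                                   if k in keep_ids},
                           remark465=[r for r in cx.remark465
                                      if r[0] in keep_ids],
                           modres={k: v for k, v in cx.modres.items()
                                   if k[0] in keep_ids},
                           seqadv_tags={t for t in cx.seqadv_tags
                                        if t[0] in keep_ids})
    for c in cx.chains:
        if c.chain_id in keep_ids and (c.kind != "dna" or c in pruned
                                       or c is prot):
            if c.kind == "dna" and c not in pruned:
                continue
            out.chains.append(c.copy())
    return out


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(cx: ComplexStructure) -> str:
    """Serialize a complex as PDB text (header records + coordinates)."""
    lines: list[str] = []
    if cx.remark465:
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465   M RES C SSSEQI")
        for chain, resname, number, icode in cx.remark465:
            lines.append(f"REMARK 465     {resname:>3s} {chain:1s} "
                         f"{number:5d}{icode:1s}")
    for (chain, number, icode), (resname, parent) in sorted(cx.modres.items()):
        lines.append(f"MODRES XXXX {resname:>3s} {chain:1s} {number:4d}"
                     f"{icode:1s} {parent:>3s}")
    for chain_id, names in cx.seqres.items():
        for start in range(0, len(names), 13):
            block = names[start:start + 13]
            ser = start // 13 + 1
            lines.append(f"SEQRES {ser:3d} {chain_id:1s} {len(names):4d}  "
                         + " ".join(f"{n:>3s}" for n in block))
    serial = 1
    for chain in cx.chains:
        last = None
        for res in chain.residues:
            for atom in res.atoms.values():
                rec = "HETATM" if atom.het else "ATOM  "
                name = _format_atom_name(atom.name, atom.element)
                x, y, z = atom.xyz
                lines.append(
                    f"{rec}{serial:5d} {name}{'':1s}{res.name:>3s} "
                    f"{chain.chain_id:1s}{res.author_number:4d}"
                    f"{res.insertion_code:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}")
                serial = min(serial + 1, 99999)
                last = res
        if last is not None and chain.kind in ("protein", "dna"):
            lines.append(f"TER   {serial:5d}      {last.name:>3s} "
                         f"{chain.chain_id:1s}{last.author_number:4d}"
                         f"{last.insertion_code:1s}")
            serial = min(serial + 1, 99999)
    lines.append("END")
    return "\n".join(lines) + "\n"
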
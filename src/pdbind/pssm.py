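"""Evolutionary-profile features from PSI-BLAST position-specific scoring
matrices.

PSSMs are consumed as ASCII files (the ``-out_ascii_pssm`` dialect).  When no
profile is available, a substitution-matrix fallback builds pseudo-scores
from BLOSUM62 rows so the feature layout is preserved; the provenance is
flagged in the matrix metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .tables import PSSM_ALPHABET


class PSSMParseError(ValueError):
    """Raised for malformed PSSM text."""


@dataclass
class PSSMMatrix:
    sequence: str
    scores: np.ndarray               # n x 20 int log-odds, PSSM_ALPHABET order
    source: str = "psiblast"         # psiblast | blosum62-fallback
    aa_column_order: str = PSSM_ALPHABET

    def __post_init__(self):
        self.scores = np.asarray(self.scores)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match sequence "
                f"length {len(self.sequence)}")


def parse_pssm(text: str) -> PSSMMatrix:
    """Parse a PSI-BLAST ASCII PSSM into canonical column order.

    Only the 20 log-odds columns are used; trailing weighted-frequency
    columns are ignored.  Header column order is honoured and remapped to
    :data:`~pdbind.tables.PSSM_ALPHABET`.
    """
    lines = text.splitlines()
    header_cols: list[str] | None = None
    rows: list[tuple[int, str, list[int]]] = []
    for line in lines:
        fields = line.split()
        if header_cols is None:
            if len(fields) >= 20 and all(len(f) == 1 and f.isalpha()
                                         for f in fields[:20]):
                header_cols = fields[:20]
            continue
        if not fields:
            continue
        if not fields[0].lstrip("-").isdigit():
            continue  # footer (statistics lines)
        if len(fields) < 22:
            raise PSSMParseError(
                f"row {fields[0]}: expected 20 integer scores, got "
                f"{max(0, len(fields) - 2)}")
        idx, aa = int(fields[0]), fields[1]
        try:
            scores = [int(x) for x in fields[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"row {idx}: non-integer score") from exc
        rows.append((idx, aa, scores))
    if header_cols is None:
        raise PSSMParseError("no 20-column amino-acid header line found")
    if not rows:
        raise PSSMParseError("no score rows found")
    if sorted(set(header_cols)) != sorted(set(PSSM_ALPHABET)):
        raise PSSMParseError(f"unexpected header alphabet: {header_cols}")
    perm = [header_cols.index(a) for a in PSSM_ALPHABET]
    sequence = "".join(aa for _i, aa, _s in rows)
    scores = np.array([[s[p] for p in perm] for _i, _aa, s in rows],
                      dtype=int)
    return PSSMMatrix(sequence, scores, source="psiblast")


def pssm_from_blosum62(sequence: str) -> PSSMMatrix:
    """Substitution-matrix pseudo-profile: row i = BLOSUM62 row of residue i.

    A stand-in when no PSI-BLAST profile is supplied; flagged via ``source``.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    scores = np.zeros((len(sequence), 20), dtype=int)
    for i, aa in enumerate(sequence):
        if aa not in PSSM_ALPHABET:
            raise ValueError(f"non-standard residue {aa!r} at position {i + 1}")
        for j, other in enumerate(PSSM_ALPHABET):
            scores[i, j] = int(blosum[aa][other])
    return PSSMMatrix(sequence, scores, source="blosum62-fallback")


def logistic(x) -> float | np.ndarray:
    """Numerically stable logistic 1/(1+exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def composition_features(pssm: PSSMMatrix) -> np.ndarray:
    """Mean normalized odds ratio per amino acid: (1/n) sum_i f(S[i, a])."""
    if len(pssm.sequence) == 0:
        raise ValueError("empty PSSM")
    return logistic(pssm.scores.astype(float)).mean(axis=0)


def mutation_odds(pssm: PSSMMatrix, site: int, wt: str, mut: str) -> float:
    """f(S[site, mut]) - f(S[site, wt]) at a 1-based sequence position."""
    if not 1 <= site <= len(pssm.sequence):
        raise ValueError(f"site {site} outside sequence of length "
                         f"{len(pssm.sequence)}")
    if pssm.sequence[site - 1] != wt:
        raise ValueError(
            f"wild-type residue mismatch at site {site}: profile has "
            f"{pssm.sequence[site - 1]!r}, mutation names {wt!r}")
    col_wt = PSSM_ALPHABET.index(wt)
    col_mut = PSSM_ALPHABET.index(mut)
    return float(logistic(float(pssm.scores[site - 1, col_mut]))
                 - logistic(float(pssm.scores[site - 1, col_wt])))
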
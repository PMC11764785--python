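"""Staged curation of tabular mutation/ddG records.

Reusable filters mirroring a binding-database cleaning workflow: drop records
without ddG, RNA entries, simultaneous protein+DNA mutations, multi-mutation
entries and records without a wild-type structure; gate on DNA sequence
identity between the record and the structure; aggregate duplicated
measurements; and report the mutation spectrum with its Shannon entropy.
Structure-dependent exclusions (alpha-carbon-only models, residue/base
mismatches at the site) are enforced downstream by the structure and
encoding modules, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .tables import AA_ALPHABETICAL

#: expected columns of a record table
RECORD_COLUMNS = ("pdb_id", "molecule", "mutation", "n_mutations", "ddg",
                  "dna_sequence")

_MUT_WT_RE = re.compile(r"^(?:[A-Za-z0-9]+:)?([A-Z])\d+[A-Za-z]?[A-Z]$")


# --------------------------------------------------------------------------
# Stage filters
# --------------------------------------------------------------------------


def apply_stage_filters(records: pd.DataFrame
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Ordered tabular cleaning stages; returns surviving records and the
    record count after each stage."""
    df = records.copy()
    counts: dict[str, int] = {"input": len(df)}

    df = df[df["ddg"].notna() & np.isfinite(df["ddg"].astype(float))]
    counts["has_ddg"] = len(df)

    is_rna = df["molecule"].str.lower().eq("rna")
    if "mutation" in df:
        # a U base in a nucleic-acid mutation string marks RNA
        u_base = df["molecule"].str.lower().ne("protein") & \
            df["mutation"].fillna("").str.contains("U")
        is_rna |= u_base
    df = df[~is_rna]
    counts["dna_only"] = len(df)

    simultaneous = df["molecule"].str.lower().isin(
        ("protein+dna", "dna+protein", "both"))
    df = df[~simultaneous]
    counts["single_molecule"] = len(df)

    multi = df["n_mutations"].fillna(1).astype(int) > 1
    df = df[~multi]
    counts["single_mutation"] = len(df)

    df = df[df["pdb_id"].notna() & df["pdb_id"].astype(str).str.len().gt(0)]
    counts["has_structure"] = len(df)
    return df.reset_index(drop=True), counts


# --------------------------------------------------------------------------
# Sequence-identity gate
# --------------------------------------------------------------------------


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def dna_identity(a: str, b: str) -> float:
    """Needleman-Wunsch identity: matches / alignment length."""
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _global_aligner().align(a.upper(), b.upper())[0]
    s1, s2 = str(alignment[0]), str(alignment[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def sequence_identity_gate(records: pd.DataFrame, pdb_seqs: dict[str, str],
                           threshold: float = 0.80
                           ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Keep records whose DNA sequence matches the structure's at >= threshold
    identity (inclusive).  Records lacking a sequence on either side are
    dropped with a reason."""
    keep = []
    dropped: list[tuple[str, str]] = []
    for idx, row in records.iterrows():
        seq_rec = row.get("dna_sequence")
        seq_pdb = pdb_seqs.get(str(row["pdb_id"]))
        if not isinstance(seq_rec, str) or not seq_rec:
            dropped.append((str(row["pdb_id"]), "missing record sequence"))
            continue
        if not seq_pdb:
            dropped.append((str(row["pdb_id"]), "missing structure sequence"))
            continue
        if dna_identity(seq_rec, seq_pdb) >= threshold:
            keep.append(idx)
        else:
            dropped.append((str(row["pdb_id"]),
                            f"identity below {threshold:.0%}"))
    return records.loc[keep].reset_index(drop=True), dropped


# --------------------------------------------------------------------------
# Duplicate aggregation
# --------------------------------------------------------------------------


def aggregate_duplicates(records: pd.DataFrame,
                         sd_max: float = 1.0) -> pd.DataFrame:
    """Collapse repeated (pdb_id, mutation) measurements.

    Groups whose sample SD exceeds ``sd_max`` kcal/mol are dropped entirely
    (irreconcilable measurements); the rest collapse to their mean ddG.
    """
    out_rows = []
    for _key, group in records.groupby(["pdb_id", "mutation"], sort=False):
        if len(group) == 1:
            out_rows.append(group.iloc[0])
            continue
        sd = float(group["ddg"].std(ddof=1))
        if sd > sd_max:
            continue
        row = group.iloc[0].copy()
        row["ddg"] = float(group["ddg"].mean())
        out_rows.append(row)
    return pd.DataFrame(out_rows).reset_index(drop=True)


# --------------------------------------------------------------------------
# Mutation spectrum
# --------------------------------------------------------------------------


@dataclass
class SpectrumReport:
    counts: dict[str, int]
    rejected: int
    total: int
    percentages: dict[str, float] = field(init=False)
    shannon_entropy: float = field(init=False)

    def __post_init__(self):
        self.percentages = {aa: 100.0 * c / self.total if self.total else 0.0
                            for aa, c in self.counts.items()}
        self.shannon_entropy = shannon_entropy(
            np.array(list(self.counts.values())))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mutated_residue": list(self.counts),
                             "count": list(self.counts.values()),
                             "percent": [round(self.percentages[a], 2)
                                         for a in self.counts]})


def mutation_spectrum(mutations) -> SpectrumReport:
    """Counts and percentages of the mutated (wild-type) residue identity."""
    counts = {aa: 0 for aa in AA_ALPHABETICAL}
    rejected = 0
    for text in mutations:
        m = _MUT_WT_RE.match(str(text).strip())
        if m and m.group(1) in counts:
            counts[m.group(1)] += 1
        else:
            rejected += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no parseable mutation strings")
    return SpectrumReport(counts, rejected, total)


def shannon_entropy(counts) -> float:
    """H = -sum p ln p in nats; zero-count categories contribute nothing."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())
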
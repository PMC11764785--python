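# Methods

`pdbind` predicts the change in protein–DNA binding free energy,
ΔΔG = ΔG(mutant) − ΔG(wild-type) in kcal/mol, caused by a single amino-acid
mutation in the protein or a single base/base-pair mutation in the DNA of a
protein–DNA complex. Positive ΔΔG means weakened binding. The method is a
feature-engineering pipeline over the wild-type (and modeled mutant)
structure feeding a gradient-boosted tree regressor; this note records the
model, its assumptions, the numerical choices, and what the synthetic test
data do and do not establish.

## Feature model

Two frozen layouts are used, recorded in a versioned JSON manifest whose
hash is stored with every trained model so that feature tables and bundles
remain interchangeable.

**Protein mutations — 49 features.**

1. *Evolutionary profile (21).* A position-specific scoring matrix (PSSM)
   over the chain's reconstructed sequence supplies n×20 integer log-odds
   S. Each score is squashed with the logistic f(x) = 1/(1+e^(−x)); the 20
   per-amino-acid column means are composition features, and
   f(S[site, mut]) − f(S[site, wt]) is the mutation-odds feature. PSSMs are
   consumed as PSI-BLAST ASCII files (the recommended recipe is three
   iterations against a large clustered database such as UniRef50). When no
   profile is supplied, BLOSUM62 rows stand in as pseudo-scores and the
   provenance is flagged in the output — a deliberately crude fallback that
   preserves the layout, not the information content.
2. *Physicochemical deltas (3).* Mutant-minus-wild-type differences of
   residue volume (Zamyatnin, Å³), a side-chain hydrophobicity index
   (Moon–Fleming water-to-bilayer scale, kcal/mol) and log rotamer count
   (compact backbone-independent counts; Gly and Ala have one state). The
   cited scales print no values in most summaries; the exact tables shipped
   are embedded in the manifest so retraining is reproducible.
3. *Category labels (6).* Five class partitions of the 20 amino acids
   (hydropathy 3, polarity 4, size 5, hydrogen-bonding 4, chemical type 7)
   plus the 400-label identity scheme. A mutation maps to
   idx(wt)·K + idx(mut); class indices follow the order the classes are
   listed in (e.g. hydropathy: neutral 0, hydrophilic 1, hydrophobic 2).
   Any consistent index order is model-equivalent for tree learners; the
   chosen order is fixed in the manifest. The partitions are asserted at
   import time (union = 20, pairwise disjoint).
4. *Structure at the site (5).* Absolute solvent accessibility of the site
   in the wild-type complex and in the modeled mutant complex (Å²; DNA
   atoms occlude), their difference acc_wt − acc_mut, and the backbone
   φ/ψ torsions. Undefined torsions (chain termini, missing neighbours)
   are encoded as 360.0 — a sentinel outside the legal [−180, 180] range —
   rather than 0.0, which is a legal angle.
5. *Secondary-structure composition (6).* Fractions of residues in
   α-helix (H), isolated β-bridge (B), extended strand (E), 3₁₀-helix (G),
   hydrogen-bonded turn (T) and bend (S). π-helix is assigned internally
   but not reported (it is empty in practice for these complexes), and
   coil is the complement.
6. *Interface census (4 + 4).* Complex-level counts of
   nucleotide–residue contacts, base–residue hydrogen bonds,
   phosphate–residue hydrogen bonds and base–residue stacks, plus their
   mutant − wild-type deltas computed on the modeled mutant complex.

The point-by-point enumeration above yields 48 distinct quantities; the
49-entry layout keeps acc_mut as its own feature beside the delta, which
is the reading that reaches the stated feature count while isolating the
choice behind the manifest.

**DNA mutations — 35 features.** The six secondary-structure ratios of the
protein; the 18 base-pair geometry parameters at the mutation site (six
pair parameters: shear, stretch, stagger, buckle, propeller, opening; six
step parameters: shift, slide, rise, tilt, roll, twist; six helical
parameters: x/y-displacement, helical rise, inclination, tip, helical
twist); three categorical encodings (wild-type pair A:T/G:C type, mutant
mismatch flag, and the 256-label pair-of-pairs category BPI(wt)·16 +
BPI(mut) with BPI the lexicographic index over ordered two-base pairs,
A < C < G < T); the four complex-level census counts; and the same four
counts restricted to the forward-strand nucleotide at the site. For
single-stranded (unpaired) sites all 18 geometry features are exactly 0.0
by convention.

## Structure processing

**Parsing and cleaning.** PDB coordinates are read with gemmi; altlocs
resolve to the highest-occupancy (then lexicographically first) conformer;
chains are classified protein/DNA/other by residue vocabulary. The full
protein sequence is reconstructed by merging coordinate residues with
REMARK 465 missing residues, reconciling against SEQRES, reverting MODRES
entries to their standard parents, and excluding SEQADV expression-tag
residues. `clean_complex` reduces crystallographic assemblies to one copy
of the biological unit: the named protein chain, every DNA chain within
5.0 Å of it (closed transitively over DNA–DNA partners so both duplex
strands survive), with duplicate copies pruned. Copy detection — same
kind, same length, ≥95 % identical residue names — deliberately exempts
chains that touch each other, so the two strands of a palindromic duplex
are never collapsed.

**Solvent accessibility.** Shrake–Rupley (biotite) with a 1.4 Å probe,
1000 mesh points per atom, and DSSP-compatible heavy-atom radii (N 1.65,
carbonyl C 1.76, other C 1.87, O 1.40, S 1.85, P 1.90 Å). Computed in the
complex, so DNA burial registers.

**Secondary structure.** A Kabsch–Sander implementation: amide hydrogens
are rebuilt anti-parallel to the preceding carbonyl, the electrostatic
H-bond energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol
defines a bond at E < −0.5, and n-turns, bridges/ladders, hydrogen-bonded
turns and bends (κ > 70°) are assigned with precedence
H > E > B > G > I > T > S. Chains of fewer than three residues and
residues with incomplete backbones are coil. Missing carbonyl oxygens are
rebuilt geometrically when the next residue provides its N. The
implementation is cross-checked against an independent DSSP implementation
(mdtraj) on the helix fixture in the test suite.

**Base pairs and geometry.** Each base is least-squares fitted to the
standard reference frame (consensus base geometry, C1′ at
(−2.477, 5.399, 0)); two bases on different strands pair when, after the
strand-II y/z flip, frame origins are within 2.5 Å, vertical separation is
under 1.5 Å and normals agree within 65° (greedy best-score matching, one
pair per base). Pair, step and helical parameters follow the mid-frame
(CEHS/3DNA) convention; helical parameters come from the screw
decomposition of the step transform. The algebra is self-inverse: frames
rebuilt from parameters decompose back to the same parameters within
1e-6. The step at a DNA mutation site runs from the site pair to its 3′
neighbour, falling back to the 5′ step at the 3′ terminus.

**Interaction census.** Cutoffs are not part of the published record, so
standard structural-biology defaults are fixed and exposed in a config:
contacts at ≤4.5 Å any heavy-atom pair (counted per nucleotide–residue
pair), hydrogen bonds at ≤3.5 Å between N/O partners (with a D–H···A
≥120° screen only when explicit hydrogens exist — crystal structures
rarely carry them), stacks at ≤4.5 Å centroid distance and ≤30°
inter-normal angle between base rings and the planar groups of
Phe/Tyr/Trp/His and the Arg guanidinium. Base hydrogen bonds require the
DNA atom in the base's polar N/O set; phosphate bonds the
{P, OP1, OP2, O5′, O3′} set; sugar oxygens count toward contacts but to
neither hydrogen-bond class. All detectors are validated against a
brute-force all-pairs enumeration on small fixtures.

**Mutant modeling.** Only the mutated residue's side chain is rebuilt:
the protein is cleaned (standard residues, complete N/CA/C/O backbones,
MODRES reverted, HETATM→ATOM), the side chain is regrown from idealized
internal coordinates, and the rotamer with the highest prior probability
among clash-free placements wins (clash: heavy-atom pair closer than
0.6·(r_i + r_j) van der Waals; if all clash, the minimal-clash rotamer).
Neighbouring side chains are held fixed — a single-site perturbation is
what the delta features consume — and full combinatorial repacking is out
of scope; an externally modeled mutant PDB can be supplied instead. The
modeled protein is superposed back over the common backbone atoms (Kabsch)
and all non-protein atoms are copied untransformed, so the pipeline is
fully deterministic.

## Regression harness

The regressor is gradient-boosted decision trees (XGBoost), behind a
registry that also exposes random forest, extra trees and sklearn gradient
boosting for comparison runs. Training uses k-fold cross-validation
(k = 5): metrics — Pearson correlation, RMSE, and the slope/intercept of
the predicted-versus-true ordinary-least-squares line — are computed on
the pooled out-of-fold predictions, in which each row appears exactly
once (per-fold correlations are logged as well). Hyperparameters come
from random search (default 1000 iterations) over a documented dictionary:
tree count 100–2000, depth 2–10, learning rate 0.005–0.3 log-uniform,
subsample/colsample 0.5–1.0, L1/L2 0–10, min child weight 1–10. The final
model is the fold ensemble of the best iteration: the mean of its k fold
models. A repeat-CV routine reports mean ± SD of the pooled correlation
over independent splits. One master seed fans out to all split, search and
regressor seeds and is recorded in the serialized bundle, so identical
inputs and seed reproduce identical bundles bit-for-bit.

## Curation rules

The tabular filters operate on user-supplied record tables (live database
access is out of scope): drop records without ΔΔG, RNA records (including
any nucleic-acid mutation naming a U base), simultaneous protein+DNA
mutations, multi-mutation entries, and records without a wild-type
structure id — each stage logged with its surviving count. The DNA
sequence-identity gate aligns record and structure sequences globally
(match 1, mismatch −1, gap −2; matches/alignment-length) and keeps
records at ≥80 % — the threshold is inclusive, since "below 80 %" is what
is discarded. Duplicated (structure, mutation) measurements collapse to
their mean when the sample standard deviation (n−1 denominator; the
convention is not dictated by the record format and is documented here) is
≤1 kcal/mol and are dropped entirely otherwise. The mutation-spectrum
report counts wild-type residue identities and summarizes diversity as
Shannon entropy H = −Σ p·ln p in nats (maximum ln 20 ≈ 2.996 for a
uniform spectrum).

## Synthetic data: what it shows and what it does not

The fixture generators make the entire pipeline testable without
downloads. `make_bdna` builds fiber-model B-DNA (twist 36.0°, rise
3.38 Å, standard-frame bases, plausible rigid phosphate placement);
`make_toy_complex` adds an ideal poly-alanine α-helix (φ = −57°,
ψ = −47°) at a controlled minimum distance from the duplex, with optional
REMARK 465 gaps, MSE+MODRES substitutions, SEQADV tags and duplicated
assemblies. `synth_training_table` draws features with realistic ranges
directly from the real manifest and plants a sparse linear + interaction
signal with Gaussian noise scaled to a chosen signal-to-noise variance
ratio; the planted coefficients are stored for recovery tests.

These fixtures establish *mechanical* correctness: geometric detectors
against brute-force oracles, parameter algebra round-trips, construction
parameters recovered, leak-free cross-validation, planted-signal recovery
(noiseless n = 200 reaches pooled PCC > 0.95; pure noise stays below
|PCC| < 0.25). They do not establish predictive accuracy on real
complexes: the fixtures have no sequence-specific readout, no realistic
interface chemistry, and no experimental noise structure. Reproducing the
published cross-validated accuracies requires the curated experimental
tables, the corresponding PDB structures and real PSSMs, which are inputs
a user supplies, not artifacts of this package.

## Numerical choices and degenerate inputs

- Undefined torsions → 360.0 sentinel; single-stranded sites → 18 zeros;
  unpaired duplex sites are treated by the same zero convention.
- Interaction deltas are oriented mutant − wild-type, matching the ΔΔG
  sign convention; accessibility change is acc_wt − acc_mut. Both are
  recorded in the manifest (any consistent orientation retrains to an
  equivalent model).
- Base-frame fits fall back to "no frame" below six matched ring atoms;
  frameless bases cannot pair and contribute zeros.
- Pairing degeneracies (two candidate partners) resolve by smallest
  origin distance, one pair per base.
- Waters and ligands are retained through cleaning but never counted as
  protein or DNA.
- Empty chains, chains of fewer than three residues, Cα-only structures
  and wild-type mismatches at the mutation site raise explicit errors
  rather than producing silent zeros.

## Known limitations

- Backbone relaxation and energy minimization are out of scope; a large
  buried mutation can clash in reality where the minimal-clash rotamer
  here merely scores it.
- The BLOSUM62 PSSM fallback carries no position-specific information;
  predictions made with it are flagged and should be treated as degraded.
- The interaction-census cutoffs are sensible defaults, not a published
  standard; models trained under one config are only comparable to
  predictions made under the same config (the config travels with the
  bundle's manifest).
- mmCIF input, BIOMT-generated assemblies, RNA and multi-site mutations
  are unsupported by design.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run on desk-scale synthetic
inputs chosen to exercise every code path quickly: 8-bp duplexes,
12-residue helices, 200-row planted-signal tables, and 10-iteration
hyperparameter searches (the production default remains 1000).
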
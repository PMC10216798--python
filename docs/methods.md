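# Methods

## Alignment handling and numbering

Alignments are read as aligned FASTA over a closed 24-symbol alphabet (20
amino acids, gap `-`, ambiguity codes B/Z/X). Parsing is case-insensitive,
`.` is read as a gap, and `*` (stop) is rejected; duplicate record ids are
rejected rather than suffixed, because the metadata join would otherwise be
ambiguous. Internally columns are 0-based half-open; every reported
position is 1-based, matching the 1..117 convention commonly used for Ig
constant-domain alignments. A per-column map can carry reference-PDB
author numbers and IMGT labels; these are *loaded* from a translation TSV,
never computed — IMGT numbering assignment is out of scope.

**Gap-column trimming** removes a column iff its gap fraction is **greater
than or equal to** the threshold (default 0.8). The closed bound is
deliberate: "gapped in 80% or more of the sequences" is the rule applied
literally, not a re-implementation of any particular trimming tool's
threshold semantics. Trimming is idempotent and reports removed columns in
original 1-based coordinates.

**Deduplication** collapses identical row strings within each
(domain_kind, isotype, animal_class) subset, keeping the first-seen id.
Rows are compared verbatim — no gap-normalisation — so two sequences that
differ only in gap placement are distinct; identical rows in different
subsets are both kept.

## Conservation scoring

Per-column conservation is the generalized Jensen–Shannon divergence
between the column's amino-acid distribution and a background, in bits
(log base 2, 0·log 0 := 0):

    JS_λ(p, q) = λ·KL(p‖r) + (1−λ)·KL(q‖r),  r = λp + (1−λ)q

with λ = ½ by default, which makes the score symmetric and bounded by
1 bit, hence in [0, 1]. The background defaults to the BLOSUM62
amino-acid frequencies (a `uniform` background and custom vectors are
accepted). Gaps are excluded from the column distribution and penalise the
score multiplicatively by (1 − gap_fraction); an all-gap column scores 0.
Ambiguity codes are redistributed over their member residues with equal
weight (B → N,D; Z → Q,E; X → all twenty) before the distribution is
formed, consistent with the property-scale averaging convention below.

Optional window smoothing mixes each column's base score with the mean
base score of its flanking columns: final = (1−w)·base + w·mean(neighbours
within half-width, excluding the column itself). Defaults are half-width 3
and w = 0.5 — the canonical choices for JSD conservation scoring — and
half-width 0 disables smoothing. Whether smoothing is wanted depends on
the analysis; all parameters are exposed.

Consequences worth knowing: the gap penalty makes the score monotone
non-increasing in added gaps at fixed residue composition, and because JSD
is convex in its first argument, a fully conserved gap-free column attains
the maximum score over all compositions for a fixed background.

## Property scales and profiles

Three scales ship with the package:

- **hydrophobicity** — Wimley–White transfer free energies (kcal/mol).
  The water→POPC-interface and water→octanol variants are both packaged;
  the interface scale is the default and profile outputs record which was
  used. Note the sign convention: more negative = more hydrophobic.
- **volume** — normalized van der Waals volumes (G = 0.00 … W = 8.08).
- **charge** — unsigned presence of a net charge: exactly {D, E, R, K} map
  to 1, everything else (including His) to 0. Signed-charge structure is
  expressible through the logo classes (acidic DE vs basic RKH) instead.

Ambiguity codes average their member residues' values (B = mean(N, D),
Z = mean(Q, E), X = mean of all 20); the gap has no value and is excluded
from every mean. Per-sequence normalized properties divide the summed
values by the number of non-gap positions. Group profiles average per
column within each group, recording the support (non-gap count); entries
with zero support are NaN and flagged, never silently zero.
Secondary-structure aggregation takes the support-weighted mean over an
element's columns, so sparsely occupied columns do not dominate. SSE
intervals and their orientation tags (interface / solvent / …) are
ingested annotation derived from a reference structure, not computed.

Logo tables are **frequency** (probability) stacks over gap-excluded,
renormalised columns, with the chemistry classes
apolar = AIFLMPVW, polar = CGSTY, amide = QN, acidic = DE, basic = RKH.
Information-content logos were not used.

Pair-composition tables at two coupled columns report, per group, the
fraction of the group's sequences carrying each ordered residue pair; the
threshold is strict (> 2% by default, so a pair at exactly 2% is dropped).
Sequences gapped at either column stay in the denominator — occupancy is
relative to the whole group, and a `nongap` denominator variant would
inflate fractions in gappy groups.

## Encoding and PCA

One-hot encoding emits one 24-wide binary block per column (feature index
= column × 24 + symbol rank; symbol order is the 20 amino acids
alphabetically, then B, Z, X, then the gap — any fixed order is equivalent
for PCA). PCA mean-centres only: unit-variance scaling on one-hot features
would give rare symbols enormous weight. The solver is deterministic full
SVD, and each component's sign is fixed so its largest-magnitude loading
is positive, making outputs exactly reproducible. Variance ratios are
σ²/Σσ² and sum to 1 over the full rank min(n−1, p).

## Coupling tables and the MI+APC scorer

External coupling tables are ingested with delimiter sniffing and header
synonyms (i/pos1, j/pos2, probability/prob/score_prob, score/cn); pairs are
normalised to i < j and duplicates collapse to the maximum probability.
The probability column is treated as an opaque value in [0, 1] — no
assumption about how the upstream inference calibrated it. Filtering keeps
pairs with probability **strictly** above the threshold (0.8 for
intradomain contact maps, 0.6 for interdomain candidates) and separation
j − i ≥ 5. The two conventional phrasings of the long-range rule ("at
least 4 apart" vs "more than 4 apart") conflict; this package uses
j − i ≥ 5 and exposes `--min-sep`.

The internal scorer is mutual information with the average-product
correction. Joint column counts receive a pseudocount (default 0.5 per
joint cell); MI is in bits; APC subtracts MI_i·  MI_·j / MI_mean computed
over off-diagonal entries, cancelling the entropic background that makes
variable columns look coupled to everything (a constant MI matrix corrects
to exactly zero). Gaps are excluded pairwise by default (complete-case per
column pair); a gaps-as-state mode exists. B/Z/X remain categorical states
here — redistribution is a conservation-module convention, and fractional
counts would complicate the estimator without changing rankings on
realistic ambiguity rates. This scorer is a ranking tool for synthetic
validation of the downstream stages, not a substitute for pseudo-likelihood
coupling inference, and it emits no probabilities.

## Contact maps and pair classification

Contacts use the minimum atom-pair distance at a 5.0 Å cutoff, heavy atoms
only by default (crystal structures lack hydrogens; `--atoms all` exists).
Structures are parsed with gemmi: first model, waters and non-amino-acid
heteroatoms dropped, alternate locations resolved to the highest-occupancy
conformer per atom name (ties to the first).

Pair categories are assigned with the precedence
intra_contact > inter_mutual > inter_shared_partner > unexplained. A pair
may satisfy several criteria; one label is reported and the supporting
distances (and the shared partner residue, when applicable) are retained.
Pairs referencing residues absent from the structure are flagged
`unmapped`, excluded from the `fraction_intra` denominator and counted in
the report. Classification is invariant to rigid-body motion and is tested
for exact agreement with a brute-force all-atom scan.

Interaction typing is deliberately simplified relative to full
contact-typing software — no angular criteria, hydrogens absent — with
first-match-wins rules: salt bridge (side-chain O/N of D/E within 4.0 Å of
a side-chain N of R/K/H), hydrogen bond (any N/O within 3.5 Å of an O/N),
π-stacking (aromatic ring centroids of F/Y/W/H within 7.0 Å), van der
Waals (heavy-atom minimum ≤ 5.0 Å), else none. Outputs should be read as
coarse geometric labels, and the thresholds are configuration values.

## Synthetic data and what it does (not) show

The generator draws sequences i.i.d. within groups: background columns are
uniform over the 20 amino acids (overridable), group-shifted columns draw
a charged residue (uniform over D/E/R/K) with probability `p_charged`, and
each planted pair (i, j) draws a joint codebook state with probability
`c` (default 0.9, 4-state codebook) and independent background residues
otherwise. Gaps are injected per cell after coupling sampling — so planted
MI is attenuated by gaps exactly as in real alignments, uncompensated —
followed by ambiguity codes. Identical seeds give identical outputs.

Defaults mirror the regime the analyses target: alignments of a few
hundred sequences per group over 60–117 columns, 5% gaps, strong planted
couplings. What the generator does **not** emulate: phylogenetic
covariance (sequences are exchangeable; real alignments carry tree
structure that inflates apparent coupling and is normally handled by
sequence reweighting), indel evolution, composition biases of real Ig
domains, and codebooks tied to physical contact chemistry. Passing the
recovery benchmarks therefore shows the estimator and plumbing are
correct, not that equally high precision is attainable on real,
phylogenetically structured data.

Toy dimers are pseudo-atom models: each chain is a line of backbone atoms
at 6.5 Å spacing, chains 12 Å apart, and each planned contact adds
side-chain pseudo-atoms at a private "meeting point" far from all other
residues (3 Å apart for contacts, an 8 Å end-to-end arrangement through a
4 Å-armed partner atom for shared-partner entries). Plan entries must use
disjoint residues at sequence separation ≥ 2; unsatisfiable plans raise a
construction error. Every model is verified against
`classify_coupled_pairs` before being returned — the self-check is part of
the construction contract, so a silently wrong fixture cannot exist.

## Numerical and benchmark choices

- JSD and MI in bits; 0·log 0 := 0 throughout; probability vectors
  validated to sum to 1 within 1e-9.
- The planted-coupling benchmark runs 5 seeds at n = 400, L = 60, 8 planted
  pairs, c = 0.9, 5% gaps, and reports mean precision@8 — sized so the
  whole benchmark suite completes in seconds on one CPU.
- The classifier benchmark uses 20 random dimers × 15 planned pairs across
  all four categories.
- PCA golden values use a two-cluster alignment differing at exactly one
  column, whose PC1 variance ratio is 1 by construction.
- `scripts/acceptance.py` derives every stream of randomness from its
  `--seed` argument (sub-seeds kept below 2³¹).

## Known limitations

- The conservation scorer implements JSD only; relative entropy or
  sum-of-pairs measures are out of scope.
- Coupling inference here is MI+APC; pseudo-likelihood methods, homolog
  search and identity-based sequence reweighting are upstream concerns and
  their output is ingested, not reproduced.
- Interaction typing has no angular terms and will over-call hydrogen
  bonds relative to full geometric typing.
- Analyses that depend on a specific curated Ig alignment and its
  reference structures (e.g. the intra-contact fraction of a real
  C<sub>H</sub>3 coupling analysis) are deterministic given those inputs
  but require external downloads; the pipeline supports them end-to-end
  while the packaged benchmarks remain fully synthetic.
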
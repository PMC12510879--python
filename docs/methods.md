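# Methods

This note documents the models, numerical conventions and design choices
behind profsearch, and what the synthetic benchmarks do and do not show.

## Alphabet and encoding

Sequences are encoded over a fixed 21-letter alphabet:
`ACDEFGHIKLMNPQRSTVWY` at indices 0–19 and the wildcard X at index 20.
Every non-canonical letter (B, Z, J, U, O, `*`) and lowercase (soft-masked)
input maps to X, so kernels only ever index 21 columns. X is scored with
the substitution matrix's own X entries (−1 almost everywhere in BLOSUM62);
this keeps single-sequence searches consistent with standard tools while
letting the low-complexity masker demote regions simply by rewriting
residues to X. A single wildcard index is deliberate: the search semantics
never distinguish *why* a residue is unknown.

The packed database stores one byte per residue, concatenated in ascending
length order (stable sort, ties keep input order for determinism). Length
sorting keeps same-length targets adjacent so the row-parallel filter pads
as little as possible; the `order_map` restores original record order for
reporting. Internal coordinates are 0-based half-open everywhere;
serialized m8 output is 1-based inclusive per the BLAST-tabular ecosystem.

## The gapless filter

The filter recurrence `M[i,j] = max(M[i−1,j−1] + Q[i,s_j], 0)` has only a
diagonal dependency, so one query row of the DP matrix can be computed from
the previous row with a single shifted vector operation. Four evaluation
strategies are implemented and tested for exact score identity:

- **Scalar oracle** — the literal cell loop (numba-compiled), the reference
  all others are checked against.
- **Batched row-parallel** — contiguous slices of the length-sorted packed
  database are padded to the slice maximum; padded cells are masked to zero
  after each row update rather than given sentinel scores, so they can
  never contribute to a maximum (cells are non-negative by construction,
  and a padded column only ever feeds other padded columns).
- **Saturating (8-bit)** — clamp-after-add at every cell, not only at
  output. Saturation is absorbing under this recurrence (a clamped cell can
  only be followed by further clamping), so the result equals
  `min(255, oracle)` exactly; 255 is treated downstream as "strong
  potential match" and always forwarded to the gapped stage.
- **Tiled** — query positions processed in consecutive tiles (default
  width 2,048). The carry between tiles is the DP row at the tile's last
  query position over all target prefixes (length n+1), zero-initialized
  for the first tile. Identity with the untiled oracle holds for every
  tile width and is tested at widths {1, 7, 128, 2048}.
- **Permuted layout** — within each block of c query columns, column j is
  packed with column j + c/2 (pairs (0,16), (1,17), … for c = 32), which
  aligns diagonal dependencies inside packed words: for full blocks the
  predecessor of every slot is uniformly two slots back, with only the two
  block-boundary lanes patched. The evaluator walks target residues
  updating all permuted slots per step; a trailing partial block simply
  drops pad columns (the permutation stays a bijection on [0, m)), which
  is equivalent to padding with never-contributing scores.

Evaluation order (row-parallel vs anything else) is contractually
irrelevant: only the diagonal predecessor is read, and the tests sweep
randomized instances with lengths 1–3,000 across all variants. Pair
lengths in the randomized sweeps are drawn log-uniformly over [1, 3000]
(1,000 pairs), which spans the stated range while keeping the expected
cell count per pair moderate; the suite completes in well under a minute
on one CPU.

## Gapped alignment

Stage 2 is local Smith–Waterman–Gotoh on profiles with affine gap cost
g(L) = open + (L−1)·extend; opening a length-1 gap costs `open`. Defaults
are open 11, extend 1 — the BLAST/MMseqs2 convention for BLOSUM62; the
choice of convention and defaults is ours, isolated in `GapPenalties`.
Alignment is local on both axes because the pipeline's purpose is local
homology retrieval. Scores accumulate in 64-bit integers, so overflow is
structurally impossible for any realistic profile.

Two evaluation orders are implemented: row-major (reference) and a
wavefront order along minor anti-diagonals that honours the same
left/up/diagonal dependencies; they are tested for exact equality.
Traceback ties are broken diagonal > up > left, and the start cell is the
first row-major maximum, making alignments fully deterministic. Every
alignment produced in tests is re-scored from its trace and must reproduce
the DP score.

## E-values and hit ranking

The E-value is the Karlin–Altschul-shaped `E = K·m·N·exp(−λS)` with
defaults λ = 0.267, K = 0.041 (published gapped BLOSUM62 11/1 constants).
These constants are a calibration choice, isolated in `compute_evalue` so
users can swap them; no finite-size or composition corrections are
applied. Stage 2 re-ranks by ascending E-value (ties by target id), which
for a fixed query is equivalent to ranking by raw gapped score.

Candidate selection in stage 1 ranks by (gapless score descending, packed
index ascending) and truncates to `max_seqs`; saturated scores (255) are
admitted past the cap. Partitioned search applies the same cap per
partition, then merges, re-applies the global ordering and truncates
again — since a global top-k restricted to a partition is at most k, the
merged candidate set, and hence the hit list, is bit-identical to the
unsplit search for any partition count. Streamed search only changes
which contiguous database slice the filter sees at a time and is trivially
invariant. Both invariances are tested as exact hit-list equality
(including traces).

## Profiles from hits

Iterative search converts one round's accepted hits (E ≤ 10⁻³ by default,
query self-alignment always included) into a PSSM. Per query column the
observed residue frequencies (hits uniformly weighted) are mixed with
matrix-derived pseudocount frequencies and converted to half-bit log-odds
against Robinson–Robinson background frequencies, rounded
half-away-from-zero and clamped to [−128, 127]:

    f′ = (1 − w_c)·f_obs + w_c·f_prior,
    f_prior(a|q_i) = p_a · 2^(S(q_i,a)/2),
    score(i,a) = round(2·log₂(f′/p_a)).

Because `f_prior` is the exact half-bit back-transform of the matrix
scores, the w = 1 limit and the zero-hit case reproduce the
single-sequence PSSM bit-for-bit. The per-column prior weight is
observation-scaled, `w_c = max(w, β/(N_c − 1 + β))` with β = 10
pseudocounts: with a handful of aligned sequences a fixed small weight
lets unobserved residues collapse to strongly negative scores and can
demote genuine remote homologs below decoys; scaling the prior with the
observation count (the PSI-BLAST approach) keeps sparse columns near the
substitution matrix and lets only well-populated columns sharpen. We
adopted the observation-scaled rule after observing exactly this failure
mode on the remote-homology benchmark. No sequence-redundancy weighting or
composition-based statistics are applied — a known limitation: profiles
built from few, highly similar hits are still mildly overconfident, and a
borderline member excluded from the profile can lose score between rounds.

## Low-complexity masking

A windowed Shannon-entropy masker replaces residues whose surrounding
window (default 12 residues, truncated at sequence ends) has composition
entropy below a threshold (default 2.0 bits) with X. This is a simple
stand-in for dedicated repeat maskers: it catches homopolymeric and
short-period repeats but not higher-order structure. Masking is off by
default for queries; databases can be masked at build time.

## Benchmarking machinery

- **TCUPS** = Σᵢ mᵢ·nᵢ / (t·10¹²) over the aligned pairs and elapsed time.
- **TPP** = (#SMs × results-per-cycle-per-SM × clock) / cycles-per-cell-
  update, with the clock in GHz and an explicit 10³ scaling from 10⁹ to
  10¹². At the L40S-class inputs (142, 64, 2.56 GHz, 1) the model yields
  23.26528 TCUPS (≈ 23.3 at three significant figures).
- **ROC1**: walking a query's ranked hits, a same-family target is a true
  positive, a decoy or different-fold target is a false positive, and a
  same-fold different-family target is ignored — the standard convention
  for the middle ground, which the truth rules alone do not dictate.
  ROC1 = (TPs before the first FP) / (query's total TPs in the database);
  if no FP occurs, all found TPs count. The aggregate is the unweighted
  per-query mean, queries without true positives excluded with a warning.

## Synthetic benchmarks

The generators draw residues i.i.d. from a uniform background (0.05 per
canonical residue) by default — the simplest null for score calibration.
Homologs are substitution-only: each position mutates independently with
probability 1 − identity to a different background residue, so length is
preserved and the true alignment is the full diagonal. Family benchmarks
place one ancestor per family (the designated query), members at graded
identities in the reference set, folds grouping two families, reversed
decoys derived from members and random decoys. Annotation TSVs are
consistent with the FASTA contents by construction, and all output is a
pure function of the seed (per-record streams derived from
(seed, record index)).

Two preset conditions are used throughout the tests: a high-identity
benchmark (4 families × 3 members at 90/80/70 % identity, seed 11) on which
a correct pipeline must reach mean ROC1 = 1.0, and a remote-homology
benchmark (6 families × 4 members at 30 % identity, lengths 150–250,
seed 7) for checking that a second profile round never lowers mean ROC1.

What these fixtures do *not* model: insertions/deletions in homologs,
realistic domain architecture, compositional bias of real proteomes, and
database scale. Passing them demonstrates the engine's internal
consistency and ranking behaviour under controlled conditions, not
sensitivity on real SCOP-annotated data.

## Problem sizes and determinism

The randomized suites use 1,000 pairs (log-uniform lengths 1–3,000) for
kernel-identity and dominance sweeps, a 1,000-sequence database for
pipeline completeness and split-invariance checks, and the preset
benchmarks above for sensitivity — sizes chosen so the full suite runs in
well under a minute on a single CPU while exercising every code path at
realistic lengths. All randomness is seeded; property-based tests run
derandomized.
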
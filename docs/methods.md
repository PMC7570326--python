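# Methods

## Scope and model of the data

`alnspace` operates on a protein MSA held in memory as equal-length rows
over the alphabet of the 20 standard amino acids plus `X` (unknown
residue) and `-` (gap). Input is normalized on read — uppercased, `.`
rewritten to `-` — and the original row order is preserved throughout;
every transformation returns index permutations rather than mutating the
alignment. The first row is the *reference*: the anchor for column
masking, identity calculations and coordinate reporting. All user-facing
positions are 1-based in the reference's ungapped coordinate system;
internal indices are 0-based, with conversion confined to the I/O
boundary.

## Conservation and logo statistics

Per-column frequencies exclude gaps and `X` from the denominator; both
are tallied separately (`gap_count`, `x_count`). This is a documented
convention: including gap rows would let gap-rich columns dominate the
entropy rather than the residue signal the logo is meant to show.

Information content uses a uniform background over the 20 amino acids
(the standard Schneider–Stephens logo convention): `I = log2(20) − H`,
clamped to ≥ 0, so values run from 0 (uniform column) to ≈ 4.3219 bits
(fully conserved). No small-sample correction is applied: the statistics
describe the alignment exactly as given. Logo letter heights are
`frequency × I` and sum to the column information to within 1e-12. The
conservation-bar track shows `I` itself; no separate conservation score
is defined. Consensus ties are broken alphabetically by one-letter code,
deterministically; an all-gap/`X` column yields `-` and zero bits.

Columns gapped in the reference are masked from display by default
(`--no-mask` disables this). The mask also fixes the mapping from
displayed column ordinal to 1-based reference position used when placing
coupling arcs.

## Identity and distance conventions

*Reference-relative identity* counts columns where reference and query
carry the same amino acid, divided by the residue count of the reference
(`first`) or of the query (`second`), × 100. `X` counts as non-gap in
denominators but never as a match, so a sequence of unknowns scores 0
rather than spuriously matching. A denominator sequence with no residues
raises an error rather than returning a number.

*Pairwise identity* divides by the count of mutually non-gap columns.
Only this denominator makes the matrix symmetric, which the heatmap
display presumes. Pairs sharing no non-gap column get 0 with a logged
warning. The diagonal is pinned to 100 (under the `X` rule a row
containing unknowns would otherwise be < 100% identical to itself).

*Hamming distance* is plain column-wise disagreement over the full
aligned strings: gap vs residue differs, gap vs gap and `X` vs `X` are
equal. Including indel structure is deliberate — the embedding should
separate sequences that differ by gaps as well as by substitutions.

Both matrices are computed as one-hot matrix products over int8 residue
codes (float32 accumulation; counts are integers well below float32's
exact range, so results equal the naive per-character tally exactly —
asserted against a brute-force oracle in the tests). A 5,000 × 200
family completes in a few seconds on one CPU. The library computes over
all columns by default; the CLI applies the reference mask by default,
matching the display convention.

## Sorting and filtering

Four sort modes (original, identity under either denominator, numeric
annotation) and two filters (inclusive identity bounds, maximum gap
fraction). The reference row is pinned first in every sort and exempt
from every filter: each statistic in the tool is defined relative to it,
so dropping or displacing it would invalidate the views. Sorts are
stable (ties keep original order), which makes sort-then-filter and
filter-then-sort commute. Default sort direction is descending identity
(most similar first). Categorical annotations can color views but cannot
be sorted on.

## Sequence-space embedding

UMAP over the precomputed Hamming matrix (`metric="precomputed"`), 2 or
3 components. Defaults `n_neighbors=15`, `min_dist=0.1` are the
published UMAP defaults; `n_epochs` is left to the library's automatic
choice. The random state is always seeded (default 42) so identical
input, config and seed reproduce coordinates bitwise — a deliberate
strengthening over interactive use. `n_neighbors` must be below the
number of sequences; violating configs are rejected with a suggestion
rather than a crash inside the optimizer.

A quality diagnostic, `neighbor_distance_preservation`, reports the mean
fraction of each sequence's k nearest Hamming neighbors recovered among
its k nearest embedding neighbors (chance level ≈ k/(N−1); ties broken
by index consistently in both spaces).

Known limitation: the UMAP optimizer's sampling streams depend on point
indices, so permuting the input rows permutes the *structure* but not
the exact coordinates — embeddings of permuted inputs are equivalent,
not bitwise equal. The tests assert the structural property
(within-subfamily distances below between-subfamily distances survive
permutation).

## Rendering

Rasters (pixel view, identity heatmap) are pure functions of their
inputs, built as numpy color-lookup arrays and emitted through PIL, so
identical inputs give byte-identical PNGs. The logo is drawn with
matplotlib glyph outlines stretched to the letter heights; stacks are
ordered smallest-at-bottom and their extents equal the column's
information content (asserted in tests).

Color constants are conventions of this package, fixed in
`palettes.py`: a Clustal-style physicochemical grouping for the
amino-acid-properties scheme, and the Kyte–Doolittle index mapped
linearly from +4.5 (red) to −4.5 (blue) for hydrophobicity. Gaps render
white, `X` gray. The mutation-vs-reference scheme keeps mismatches at
full saturation and blends matches 75% toward white; the reference row
stays fully saturated. The heatmap uses the `Blues` colormap (0% light
→ 100% dark). Coupling overlays draw the top-k pairs by score as arcs
above the displayed columns; pairs at masked-out positions are skipped
with a warning, and positions beyond the reference length are an error.

## Synthetic family generator

`generate_family` emulates an aligned domain family with subfamily
structure: a uniform-random root sequence; one ancestor per subfamily by
substituting each column with probability `root_divergence`; members by
substituting with probability `within_divergence`; gaps substituted in
place with probability `gap_prob` (shape preserved — the tool consumes
pre-aligned input, so no indel process is simulated). Substitutions are
uniform over the 19 alternative residues. The first sequence is kept
gapless and serves as the reference. Defaults — 3 subfamilies × 40
sequences, 80 columns, `root_divergence=0.5`, `within_divergence=0.05`,
`gap_prob=0.03` — give within-subfamily identities near 95% and
between-subfamily identities near 30%, a realistic mid-sized divergent
family whose subfamilies are recoverable but not trivial.

What the generator does *not* emulate: substitution-matrix biases,
rate heterogeneity across sites, phylogenetic tree structure within
subfamilies, indels, or alignment errors. Passing tests therefore show
that the statistics and the embedding behave correctly on cleanly
clustered data; they do not certify behavior on families with gradient
(non-clustered) structure or systematic alignment artifacts.

Coupling fixtures draw unique position pairs uniformly with standard
lognormal scores — heavy-tailed, like real coupling-score distributions,
purely so "top-k" selection is exercised on unequal scores.

## Numerical and interface choices

- Entropy uses only nonzero frequencies (no 0·log 0 terms); information
  is clamped at 0 against floating-point undershoot.
- Matrix kernels: int8 codes, float32 one-hot products, integer-exact
  results (verified against naive recounts).
- Annotation columns auto-type: numeric when every non-missing value
  parses as a real number, categorical otherwise.
- Couplings canonicalize to `i < j`; duplicates collapse keeping the
  highest score with a warning; self-pairs are errors.
- CLI exit codes: 0 success, 1 usage error, 2 data error; the effective
  config of each run is echoed at INFO level.

## Problem sizes used by the test-suite

The benchmark family is 120 × 80 (3 × 40 sequences); the oracle
equivalence checks use 50 random 8 × 12 alignments; the performance
checks use 1,000 × 120 (matrices, seconds) and 5,000 × 200 (full
stats/identity/pixel pipeline); embedding-quality checks repeat over 5
seeds. These sizes keep the default test run fast while exercising the
same code paths the tool uses at the tens-of-thousands scale.
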
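# Methods

This note records the models and procedures the toolkit implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic data do and do not demonstrate.

## Distances

Two pairwise metrics over aligned sequences, both with *pairwise deletion*:
a column contributes only when both sequences carry an unambiguous A/C/G/T
(case-insensitive). Gaps and IUPAC ambiguity codes are missing data, so
low-quality capture sequence cannot inflate distances.

* **p-distance** — differing / comparable columns; in [0, 1].
* **blastn-score distance** — with match +5 and mismatch −4 over the L
  comparable columns, S = 5·matches − 4·mismatches and the distance is
  1 − S/(5L), clamped to [0, 1]. 5L is the maximum attainable score, so
  identical sequences score 0; the clamp handles the (biologically absurd)
  regime below ~44% identity where S goes negative.

The medoid criterion uses the p-distance: it is bounded like the printed
thresholds (0.20/0.25/0.30) and matches the uncorrected-distance practice
of comparable universal-bait projects. The barcode skim uses the
blastn-score distance. Whether gap columns should instead be *scored* in
the barcode distance is genuinely open; skipping them is this package's
documented choice and is applied consistently on both sides of every
comparison.

## Marker selection (k-medoids)

Per gene, a PAM-style search over k = 1, 2, …, k_max:

* each restart draws k distinct random medoids, then alternates
  nearest-medoid assignment and within-cluster medoid updates until the
  medoid set is stable (the objective, the summed assigned distance, is
  non-increasing by construction);
* per (gene, k), `restarts` seeded restarts are run; the best restart is
  the one with the highest fraction of sequences within d_max of a medoid
  (ties: lower objective, then lower restart index);
* the gene *converges* at the smallest k whose best restart reaches the
  fraction f_conv, evaluated inclusively (0.95 means 0.95 exactly passes)
  and over all rows, medoids included (they sit at distance 0).

Defaults: d_max = 0.25, k_max = 70, f_conv = 0.95, restarts = 100. Genes
with alignments shorter than 600 columns are dropped before clustering.
Every tie (assignment, medoid update, equal-quality restarts) resolves to
the lexicographically smallest sequence id, and restart seeds derive
deterministically from (seed, gene id, k, restart index), so a run is
reproducible bit for bit. k is searched ascending because the point of the
exercise is the *smallest* representative set.

## Bait design

Sources are gap-stripped; maximal runs of 1–10 Ns are rewritten to Ts
(longer runs are left and any residual N later fails QC). Windows of
`bait_len` = 80 start at 0 with step `bait_len/tiling` = 40; when the last
regular window stops short of the end a flush window [L−80, L) is added, so
every base is covered at least once and interior bases exactly twice.

Flags (a bait passes iff unflagged):

* GC bounds are strict: gc ≤ 25% or gc ≥ 67% fails. A 25.0% bait fails;
  26.25% (the next value attainable at 80 bp) passes.
* Repeat content is the soft-masked (lowercase) fraction of the window —
  soft-masking being the standard carrier of repeat annotation in FASTA —
  with threshold *exceeding* 35% (35.0% passes); the same rule applies to
  the window extended ±80 bp ("region"), clipped to the source.
* Multi-hit: an internal seed-and-extend screen replaces an external BLAST
  dependency. Exact shared 16-mers propose alignment diagonals; on each
  diagonal the longest contiguous stretch with identity ≥ 0.90 and length
  ≥ 60 is a candidate locus; loci overlapping by more than one tiling step
  (40 bp) are merged; both strands of every genome are scanned, and
  hit_count ≥ 2 fails. Thresholds are explicit so the screen is testable
  against a brute-force all-diagonals scan. A precomputed hit table can be
  substituted where an external aligner is preferred.

## Tree machinery

**Neighbor joining** (Q-criterion) is the internal tree builder — a
consistent estimator on additive matrices, verified by recovering random
trees from their path-length matrices to 1e-9. Q-ties break on the
lexicographically smallest pair of cluster keys (a cluster is keyed by its
smallest leaf label); negative branch lengths clamp to 0. Bootstrap
supports come from column resampling: each replicate rebuilds the NJ tree
and an internal edge's support is the percentage of replicates containing
its bipartition; replicates with undefined distances are redrawn (≤ 10
attempts). NJ stands in for external ML inference; every consumer of a
tree accepts Newick from any source.

**Robinson–Foulds.** Trees are compared unrooted after pruning to shared
leaves (≥ 4 required). rf is the symmetric difference of nontrivial
bipartition sets; the normalization rf_max = |B₁| + |B₂| equals 2(n−3) for
binary trees and degrades gracefully for polytomies. Bipartitions are
stored canonically as the side not containing the smallest leaf label.

**Thompson-tau outlier screen.** Iteratively: compute mean and sample
standard deviation s; the point with the largest deviation δ is removed if
δ > τ·s with τ = t(n−1)/(√n·√(n−2+t²)), t the two-sided Student critical
value at α = 0.05 with n−2 df; recompute and repeat. Ties remove the larger
value; s = 0 stops immediately. Note the criterion is not
multiplicity-corrected — that is how the tau test is defined — so on clean
data it still removes a point in roughly a fifth of samples; it is a
screen, not a significance test. Gene-tree scores are each tree's mean nRF
to all other gene trees, plus the species tree as one extra comparator when
given (the weighting of that comparator is not canonical; equal weight is
this package's choice).

**Topology clusters.** Classical (Torgerson) MDS — double-centering of
−D²/2 and eigendecomposition, top-2 eigenvalues clipped at 0 since nRF
need not be Euclidean — followed by DBSCAN with eps defaulting to half the
median pairwise embedded distance. An all-zero matrix short-circuits to a
single cluster.

**Concordance.** For each species-tree bipartition, a gene tree restricted
to shared leaves (both sides ≥ 2) is concordant if it contains the
restricted bipartition, conflicting if it contains an incompatible one
(some pair of opposite intersections all nonempty), else uninformative;
the three counts always sum to the number of gene trees.

## Saturation analysis

Rate ordering uses a relative surrogate — the mean pairwise p-distance per
gene — instead of absolute calibrated rates: only the *ordering* matters
here, and the surrogate preserves it on simulated rate multipliers (checked
at ≥ 95% over seeded simulations). Missing sample×gene blocks pad with gaps
by default (N optional). The reference tree defaults to the full-set tree
from the same builder, so the final curve point is 0 by construction; a
published tree can be supplied instead.

## Capture filter

The depth condition compares the deepest copy against the *next deepest*
("at least 10× deeper than any other copy" ⇒ the max of the others), read
inclusively at exactly 10×. Coverage values are taken as given from the
input (assembler coverage definitions vary; only ratios are used).
Reference similarity for the default-mode fallback is the p-identity of a
global pairwise alignment (match +1 / mismatch −1, gap open 5, extend 1)
to the gene's reference sequence. Completeness is extracted non-gap length
over reference length, capped at 1 in the matrix with the raw ratio kept
in the CSV export.

## Barcoding

Queries are aligned into the database's fixed column space against the
alignment's majority consensus (same scoring as above); query insertions
relative to the profile are discarded so concatenation coordinates stay
stable. A query whose normalized alignment score (score / query length) is
negative has no credible homology to the gene and is skipped. Block
filtering drops columns with > 50% gaps, then surviving runs shorter than 3
columns. The skim takes database rows in ascending distance order (ties:
database order), greedily skipping rows beyond the 4-per-species cap,
until 20 are taken; the cap is applied during selection, so the reported
set always satisfies both constraints. The local tree is rooted at the most
distant selected neighbor and the sister statement is the species
composition of the query's smallest containing clade; equal-distance top
hits of different species are flagged as an unresolved tie (the
indistinguishable-species outcome).

## Synthetic data

Trees are pure-birth (Yule): with k lineages the next split waits
Exponential(k·λ), and tips extend by a final Exponential(n·λ) segment, so
the expected root-to-tip depth is (H_n − 1)/λ. Sequences evolve under
JC69: per branch of length t (times the gene's rate multiplier) each site
substitutes with probability ¾(1 − e^(−4t/3)), uniformly to another base.
Gene rate multipliers are log-uniform on [0.5, 2].

Copy tables rescale the sample tree to a root-to-tip depth of 0.15
substitutions/site — capture loci are conserved, and the marker-selection
criterion itself bounds sample-to-reference divergence near 0.25, so
saturated sequences would misrepresent the data this filter sees. Each
cell gets one target copy at the target coverage (100× by default); with
probability 0.31 contaminant copies (3 per gene in total by default,
diverged by 0.15, at 5×) are added. Coverages are deterministic means so
filter decisions are exact. The per-gene reference is the gene's medoid
row. Species complexes place species means at divergence `inter` from a
common root (each species branch mutating sites with probability inter/2)
and individuals at `intra` around their mean; one individual per species
is withheld as a query.

What this does not emulate: indels and alignment error (all simulated
alignments are gap-free; block filtering is exercised by constructed
gappy fixtures instead), selection, rate variation across sites,
base-composition bias, sequencing error, and real coverage noise. Passing
tests therefore demonstrate the *rules and algorithms* — boundary behavior,
oracle equivalence, recovery of planted structure under the stated models —
not field performance on real capture data.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to exercise every
code path with comfortably significant planted effects: gene sets of 6–15
genes × 150–700 bp over 4–10 taxa, databases of 4–8 species × 3–5
individuals, screening genomes of 3–20 kb, 10–100 bootstrap replicates,
and 10–20 seeds per recovery rate. All randomness flows from explicit
seeds; reruns are byte-identical.
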
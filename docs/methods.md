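# Methods

## Co-expression ranking

The atlas (genes × samples, TPM) is transformed to log2(TPM + offset)
with offset 1 by default; the offset keeps zeros finite and compresses
the heavy right tail typical of TPM data. No minimum-expression filter
is applied by default (an optional `min_expression` flag drops genes
whose maximum TPM falls below a threshold). Genes with zero variance
across samples — including all-zero genes, which the synthetic generator
can legitimately produce — are flagged *unrankable* with a logged
warning and carried through rather than assigned an arbitrary
correlation; any attempt to rank against them raises an error naming the
gene.

Pairwise similarity is Pearson correlation of the log2 matrix (the
default for bulk co-expression atlases and the conventional input to
mutual-rank statistics); Spearman is available for strongly non-linear
profiles. At least 3 samples are required — below that the sample
correlation is degenerate. Each gene's neighbours are ordered by
descending similarity with ties broken by ascending gene id; the
id-based tie rule makes the ordering deterministic and independent of
the row order of the input matrix. Ranks r(A→B) therefore form a
bijection onto 1..n−1 for every rankable gene A.

## Mutual rank and the KNN network

The mutual rank is the geometric mean MR(A,B) = √(r(A→B)·r(B→A)),
computed from the *full* orderings, not truncated at k: the KNN graph
decides which edges exist, but rank values beyond k remain meaningful
and are needed for edges contributed by only one direction. MR is
symmetric, ≥ 1, and equals 1 exactly for reciprocal rank-1 pairs.

The KNN network connects each gene to its top k = 500 most co-expressing
genes (k is truncated to n−1 on smaller matrices). Undirected edges are
the union symmetrisation — an edge exists when either endpoint lists the
other in its top k — and carry both directed ranks plus the mutual rank,
which a renderer can map to edge opacity. Union (rather than
intersection) symmetrisation matches the reading that every gene is
connected to its own top-k list.

## Candidate selection

Per bait, the ordered neighbourhood is scanned up to position k; genes
present in the regulator annotation are kept in encounter order and
truncated to the best `cap` = 10. The cap uses the bait's directed
neighbourhood rank, not the mutual rank, because the cap is a per-bait
"top 10 most co-expressing" notion. The candidate list is the union over
baits with every surviving (candidate, bait, rank) triple retained, so
|candidates| ≤ |baits| × cap (440 at the default 44 × 10) and overlap
between bait neighbourhoods strictly shrinks the union. A bait never
appears as its own candidate (it is absent from its own neighbour list),
but baits that are themselves annotated regulators can be selected for
*other* baits — regulators of one pathway branch are often co-expressed
with another branch's enzymes.

The relative-rank matrix (baits × candidates, entries r/k ∈ (0,1])
reproduces the familiar selection heatmap; pairs not recorded are
masked, never written as 0, since absence and rank are different facts.

## Screening-group design

Published screens group candidates by hand ("same or overlapping bait
profiles"); here the grouping is a deterministic greedy algorithm so
that runs are reproducible: candidates are represented by their bait
sets, ordered by descending association count (ties by id); each group
seeds with the first unassigned candidate and absorbs unassigned
candidates in descending Jaccard similarity of bait sets (only if
similarity > 0, ties by id) until `max_size` = 4. Disjoint bait profiles
therefore never merge. The manual nine-group design of any particular
study is not a reproduction target.

## qPCR quantification and the gate

Quantification is the Hellemans-style multi-reference scheme: per gene,
RQ(g,s) = E_g^(meanCq_g − Cq(g,s)) with the mean over all samples and
amplification efficiency E_g (fold per cycle; default 2.0 = 100%,
per-gene overrides supported); the per-sample normalisation factor NF(s)
is the geometric mean of the reference-gene RQs; NRQ = RQ/NF is finally
rescaled per gene so the control-condition arithmetic mean is exactly 1.
Gene-mean centring makes NRQs invariant to constant Cq shifts of any
single gene (reference or target), which the tests assert.

Fold changes between conditions are geometric-mean ratios,
2^(Δ mean log2 NRQ), tested with the classic equal-variance two-sample
Student's t-test on log2 NRQs (log2 rather than raw NRQ: multiplicative
noise is approximately log-normal, and the screen's published statistic
is computed on log2 data). When both groups have zero variance the
p-value is defined as 1 for a zero difference and 0 otherwise. No
multiple-testing correction is applied in the gate — a deliberate mirror
of screening practice, documented here as a caveat: the screen is a
triage step, not a confirmatory analysis.

The gate uses strict inequalities throughout (">5-fold", ">2-fold",
"p < 0.05"): a group advances when **every** introduced TF shows
overexpression > 5-fold and ≥ 1 target gene is up > 2-fold with
p < 0.05. Requiring all introduced TFs to clear the bar is this
package's choice for the multi-TF case (a group with a failed
overexpression is uninterpretable); targets missing from the
measurements are listed and treated as non-hits. The follow-up list is
the deduplicated, sorted union of members of advancing groups.

## Synthetic data

The atlas generator emulates the statistical structure the analysis
assumes, at the canonical compendium size of 82 samples:

- **Modules.** Each module (pathway branch) has a non-negative activity
  profile over samples; defaults are orthogonal block designs standing
  in for organ/treatment contrasts (root-high, induced, leaf-specific).
  Member genes and planted regulators get expression
  scale_g · activity(s), with scale_g log-uniform over 10–1000 TPM-scale
  units.
- **Noise.** Multiplicative log-normal noise, sigma = `noise_sd` in
  natural-log units (default 0.05, the low-noise regime in which planted
  regulators are reliably recovered), applied per gene per sample before
  TPM rescaling — the simplest model that preserves rank-based
  co-expression structure.
- **Background.** Independent log-normal profiles (sigma 1.0),
  uncorrelated with every module; 400 genes by default.
- **TPM closure.** Columns are rescaled to sum to 1e6 (±1e-6 relative).
- **Determinism.** A single integer seed fixes the output bit-for-bit.

With zero noise and no background, module genes are exact scalar
multiples of a shared two-level profile, so within-module Pearson
correlation of the log matrix is exactly 1 and between-module
correlation (orthogonal blocks) is ≤ 0 — an assertable anchor for the
ranking code.

The qPCR generator realises specified true fold changes as Cq shifts of
−log_E(F) cycles, adds Gaussian noise per technical replicate (sd 0.1
cycles by default, a typical plate repeatability) and averages two
technical replicates into one Cq per biological replicate before export,
as plates are usually reported. Reference genes are constrained to true
fold change 1.

**What the generator does not emulate:** library-size and batch effects,
count noise at low expression, correlated background modules,
annotation errors in the regulator list, amplification-efficiency
mis-specification, and inter-run qPCR calibrators. Passing tests
demonstrate that the machinery is correct under the assumed structure,
not that real atlases satisfy that structure.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately compact sizes chosen
to exercise every code path while staying interactive: oracle
comparisons on ≤ 20-gene random instances (20 seeds), recovery on the
460-gene / 82-sample study-scale atlas with k = n−1 (the 500-neighbour
setting saturates at atlas sizes below 501 genes), gate calibration on
200 simulated screens of 4 biological replicates. The candidate-count
bound is checked at the full 44-bait × cap-10 design (484-gene atlas).
Larger atlases scale as O(n²) memory for the similarity matrix and
O(n² log n) time for ranking; the implementation holds the full rank
matrix in memory, which is appropriate up to a few tens of thousands of
genes.

Edge lists, candidate tables and groups are written as header-ed TSV in
deterministic (lexicographic) row order; gene ids are treated as opaque
strings throughout. The pipeline manifest records all parameters and a
SHA-256 checksum of every output, so end-to-end determinism is
verifiable by comparing manifests.

## Known limitations

- Pearson-on-log2 is a choice, not a law; strongly bimodal organ atlases
  can favour Spearman (provided as an option).
- The greedy grouping is order-dependent by design (deterministic), and
  does not optimise any global objective.
- The gate inherits the screen's lack of multiplicity control and its
  all-TFs-overexpressed requirement; both are triage heuristics.
- Mutual ranks are computed on full orderings; a tool that ranks within
  truncated top-k lists only would disagree beyond rank k.
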
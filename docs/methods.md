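# Methods

## Model and procedure

`gnest` scores candidate gene neighborhoods — runs of consecutive genes on a
chromosome — by combining three ingredients into a Total Neighborhood Score
(TNS):

1. **Preprocessing.** Transcripts with overlapping genomic coordinates are
   collapsed to a non-redundant set. Overlap groups are the connected
   components of the pairwise coordinate-overlap graph (strand is ignored);
   within a group, selection is greedy — keep the transcript with the highest
   maximum expression across samples (ties: longest, then lexicographically
   smallest id), drop everything overlapping it, recurse on the remainder.
   Greedy component resolution is a design choice: only the pairwise rule is
   inherent to the problem, and the greedy order is deterministic and
   idempotent. "Highest expression" is interpreted as the row maximum, which
   matches the silence criterion's focus on peak expression.

   Silent genes are flagged, not removed: either fewer than
   `min_present_calls` (default 12) "P" detection calls across samples, or a
   row maximum strictly below `min_max_expression` (default 0.2, linear
   units such as RPKM). Both comparisons are strict, so a gene exactly at
   the boundary is expressed. Silence zeroes all the gene's correlations;
   the position is preserved because an unexpressed gene interrupting a
   window is informative.

2. **Correlation.** Pairwise Spearman rho with average ranks for ties,
   computed per chromosome (windows never span chromosomes, so only
   within-chromosome pairs are ever consumed; a genome-wide mode exists for
   diagnostics). Constant profiles get rho = 0 with all partners — rank
   correlation is undefined there and a flat profile carries no
   co-expression evidence, mirroring the silent-gene convention. The matrix
   path standardizes the rank rows once and takes a single matrix product;
   the scalar `spearman_rho` goes through scipy's implementation.

3. **Windows and ANC.** In gene-count mode, every run of W consecutive
   genes for W in `[min_size, max_size]` (default 2..10; window sizes above
   a chromosome's gene count are skipped). In base-pair mode, each start
   gene anchors the maximal run fitting the bp budget; a run satisfying
   several requested sizes is scored once, keyed by the smallest. The
   window span runs from the minimum member start to the maximum member
   end — the same span synteny is judged on. ANC is the mean of all
   distinct pairwise rho values among members, computed incrementally: the
   pair sum at (start, W) extends (start, W−1) by the W−1 new pairs. Tests
   pin the incremental path to a brute-force all-pairs oracle at 1e−12.

4. **Permutation null.** Gene positions are fixed; expression profiles
   (rows, with their detection calls and hence silence status) are permuted
   uniformly across the genome. The full enumeration and ANC computation
   are repeated per shuffle, and null ANCs are pooled across shuffles
   within each window-size class. Default 10 shuffles: pooling across the
   genome-wide windows yields thousands of null draws per size class even
   with few shuffles. p is the proportion of pooled null ANCs strictly
   greater than the observed ANC — no add-one correction, so the top
   observation gets p = 0 exactly; a `--pseudo-count` flag switches to
   (k+1)/(n+1). p-values are reported unadjusted and feed the gate as-is;
   an optional Benjamini–Hochberg column is reporting-only.

5. **Synteny.** A window is conserved in a comparison species when its span
   is contained in a *single* block's reference interval — containment, not
   overlap, because a span crossing a block boundary is not an unbroken
   segment in the other genome. Block orientation is irrelevant to
   conservation. SS = conserving species / total species, always an exact
   rational k/m.

6. **TNS.** `SS × ANC` when `p ≤ α` (inclusive, default 0.05), else exactly
   0. The score is a ranking device: |TNS| ≤ SS ≤ 1, and any window
   containing a silent gene is doubly demoted (zeroed correlations drag ANC
   down and the gate usually zeroes it outright; for 2-gene windows ANC is
   exactly 0). Per-gene summaries take the maximum TNS over containing
   windows; the non-redundant summary greedily picks the highest-TNS window
   above a threshold (ties: larger, then leftmost) and discards windows
   sharing members.

## Block builder

The anchor-chaining builder is a deliberately simple alternative to
uploading precomputed block tables. Anchors sorted by reference position
join one chain while reference chromosome and target chromosome match and
the inter-anchor gap is at most `max_gap` on *both* genomes (whether the
gap test applies to both genomes was an open choice; both-genomes is the
conservative reading). Chains with fewer than `num_mark` anchors or
reference span under `min_blk` are discarded; anchor orientation never
breaks a chain (local inversions are tolerated as inconsequential at
neighborhood resolution) and each block takes the majority orientation.
Defaults: `max_gap` 1 Mb, `min_blk` 100 kb, `num_mark` 2. Surviving chains
that still overlap on the reference are merged so the output satisfies the
non-overlap invariant of a block set.

## Annotations

- **Tau tissue specificity**: the unnormalized index
  `Tau = Σ_i (1 − x_i / max_j x_j)` over N samples — 0 for uniform
  expression, N−1 for expression confined to one sample. Note this is the
  0..N−1 form, **not** the common /(N−1) normalization to [0, 1]. Inputs
  must be non-negative linear-scale values; de-log log2 intensities first.
- **Orientation classes** of adjacent non-overlapping pairs: co-oriented
  (same strand), divergent (upstream gene on −, head-to-head), convergent
  (upstream gene on +, tail-to-tail).
- **Duplicate pairs**: any protein-alignment hit in either direction with
  e-value strictly below 1e−07 (self-hits ignored). Duplicate-free gene
  sets drop the lower-expressed member of each intact pair iteratively —
  in a chain A–B, B–C, removing the shared gene can resolve both pairs.

## Synthetic data

The generator emulates a tissue-atlas-shaped experiment: `genes_per_chrom`
genes per chromosome at fixed 50 kb spacing (10 kb genes, so nothing
overlaps), `n_samples` samples (default 20), expression from a latent-factor
model. Planted cluster members mix a shared latent sample profile with
independent noise at weight √r vs √(1−r), giving Pearson correlation exactly
r between members on the Gaussian scale; the Spearman value for bivariate
Gaussians is (6/π)·asin(r/2), within 0.02 of r over the range used, so the
configured `target_rho` (default 0.9) is approximately the expected pairwise
Spearman. Scores are exponentiated to a linear non-negative scale (monotone,
so rank correlations are untouched) and Tau/silence thresholds apply
directly. Silent genes get sub-threshold uniform values and "A" calls.

Synteny blocks are built by cutting each chromosome into segments:
non-conserving species get breakpoints at every adjacency inside a planted
cluster's span, conserving species are guaranteed unbroken there, and
background adjacencies break with probability `1 − background_conserved_prob`
(default 0.7 conserved, the typical fraction of adjacent mammalian gene
pairs syntenic across comparison genomes). A cluster configured with k of m
conserving species therefore gets SS = k/m exactly. Default comparison-set
size is 9 species.

What the generator does **not** emulate: microarray probe effects or
platform noise structure, varying gene density or gene length, overlapping
transcripts on real annotations, correlated background expression
(housekeeping programs), or partial/soft synteny loss. Passing recovery
tests therefore demonstrate the pipeline's mechanics — enumeration, null
calibration, conservation gating, rank ordering — not performance on real
atlases.

## Numerical and operational choices

- Coordinates are 0-based half-open everywhere (BED convention); GFF3 is
  converted on read, matching the emitted browser-track formats.
  Chromosome names are compared verbatim — a silent "chr1" vs "1" mismatch
  between location and block files is a classic failure mode, so no
  normalization is applied.
- Missing expression values are an error, never imputed.
- One integer seed drives a single reproducible generator stream per run;
  reports and tracks print 6 significant digits and are byte-identical
  across repeat runs with fixed inputs and seed.
- Tie-breaks everywhere are total orders (score, then length/size, then
  id/position), so results are independent of input ordering.
- Test and default problem sizes (hundreds of genes, ≤ 10 shuffles for the
  calibration suite, 50-replicate recovery runs on 30-gene chromosomes) are
  desk-scale choices that keep the full suite in a few seconds while
  leaving every code path exercised; real runs scale linearly in shuffles
  and quadratically in per-chromosome gene count.
- The `--no-synteny` mode (SS := 1 for every window) is an explicit
  extension for users without comparison-species data, not part of the
  standard scoring scheme.

## Known limitations

- The permutation p-values of overlapping windows are strongly dependent;
  the calibration guarantee is marginal uniformity, not joint.
- bp-mode windows enumerate only maximal runs per start gene; sub-runs are
  reachable through gene-count mode.
- The block builder is a simplified chaining heuristic, not a full synteny
  engine (no rearrangement-aware merging, no marker quality weighting);
  supply curated block tables for production comparisons.
- Tau's expression scale matters (log vs linear give different values);
  the package standardizes on linear non-negative input and leaves the
  transformation to the caller.
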
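# gnest

Gene neighborhood scoring for quantitative transcriptomes.

Spatial clusters of co-expressed genes ("gene neighborhoods") occur in every
genome studied, but definitions based on fixed window sizes, adjacency rules,
or expression cutoffs are arbitrary. `gnest` instead scores **every candidate
window of consecutive genes across all window sizes simultaneously**, for
biologists and computational biologists who want a ranked list of candidate
neighborhoods (co-regulated modules, shared chromatin domains, tandem
duplicate arrays) from bulk or single-cell expression data plus genomic
coordinates.

## The score

For a window of W consecutive non-redundant genes:

- **ANC** (Average Neighborhood Correlation): the mean of all W(W−1)/2
  pairwise Spearman correlations ρ between the members' expression profiles.
  Genes failing a minimum-detection or minimum-expression criterion
  ("silent" genes) keep their genomic position but have all their
  correlations set to 0.
- **p**: an empirical p-value from a position-preserving permutation null —
  expression profiles are shuffled across gene positions, the whole window
  enumeration is rescored, and p is the proportion of null windows of the
  same size with ANC greater than observed. Unadjusted by design: the scores
  are a ranking, not per-window significance claims.
- **SS** (Synteny Score): the fraction of comparison species in which the
  window's base-pair span lies inside a single unbroken syntenic block —
  k/m for k of m species.
- **TNS** (Total Neighborhood Score):

  ```
  TNS = SS × ANC   if p ≤ α  (default α = 0.05, inclusive)
      = 0          otherwise
  ```

Each gene's *best associated TNS* — the maximum over all windows containing
it — is exported as a UCSC bedGraph custom track.

## Worked example

Generate a synthetic bundle with one planted 3-gene co-expressed cluster
(target Spearman 0.9, conserved in all 9 comparison species), then score it:

```sh
gnest simulate --n-chromosomes 1 --genes-per-chrom 20 --n-samples 20 \
      --n-species 9 --cluster chr1:5:3:0.9 --seed 1 --out-dir sim
gnest score --genes sim/genes.bed --expr sim/expression.tsv \
      --blocks-dir sim/blocks --min-genes 2 --max-genes 4 \
      --permutations 10 --seed 2 --out-dir out
```

The top rows of `out/neighborhoods.tsv` sorted by TNS:

```
chrom  span_start  span_end  size_mode   size  member_gene_ids                          anc       p_value  ss        tns
chr1   250000      310000    gene_count  2     chr1_g005,chr1_g006                      0.896241  0        1         0.896241
chr1   250000      360000    gene_count  3     chr1_g005,chr1_g006,chr1_g007            0.828571  0        1         0.828571
chr1   300000      360000    gene_count  2     chr1_g006,chr1_g007                      0.798496  0        1         0.798496
chr1   200000      360000    gene_count  4     chr1_g004,chr1_g005,chr1_g006,chr1_g007  0.390977  0        0.777778  0.304094
```

The planted cluster (genes 5–7) dominates: its pairwise correlations are near
the 0.9 target, no shuffled transcriptome produced a higher same-size ANC
(p = 0), and the span sits inside one syntenic block in all 9 species
(SS = 1), so TNS = ANC. The 4-gene window extending the cluster is a
"shadow": its significance persists but an uncorrelated member dilutes ANC
and a block boundary in two species cuts SS to 7/9. Background windows
either fail the permutation gate (TNS = 0) or score near 0. `out/best_tns.bedGraph` holds the per-gene track and
`out/tns_matrix.tsv` the TNS-by-window-size matrix for heatmap rendering.

Other subcommands: `gnest synteny-build` chains marker anchors into syntenic
blocks (defaults: maxGap 1 Mb on both genomes, minBlk 100 kb, numMark 2);
`gnest annotate` emits Tau tissue specificity, adjacent-pair orientation
classes, and duplicate-pair flags from tabular protein-alignment hits.

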
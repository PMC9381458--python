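# Methods

This note records the models, parameter choices and numerical decisions
behind `scclone`, and what the simulation-based validation does and does
not demonstrate.

## Synthetic data generator

The generator is the package's specification of the data-generating
process it targets: FACS-sorted nuclei, whole-genome amplified (WGA),
sequenced shallowly (~0.15x; with 150 bp reads and 50 kb bins this is
~50 reads per bin), from tumours carrying 1–4 aneuploid clones related by
a clone tree, admixed with normal diploid cells, sampled in two regions.

**Counts.** For cell *c* (clone *k*) in bin *b*:

    X_cb ~ NegBin( mean = d_c · r · CN_kb / 2 · g_cb ,  size = θ )

- `r` (`reads_per_bin`, default 50) — mean reads per bin for a diploid
  bin at unit depth.
- `θ` (`nb_dispersion`, default 250) — negative-binomial size; larger is
  closer to Poisson. The default adds mild overdispersion on top of
  counting noise.
- `g_cb` — per-cell, per-bin lognormal WGA amplification factor with
  log-scale SD `wga_sd` (default 0.04). Together with θ this puts the
  per-bin log2-ratio SD of a diploid bin near 0.23, a regime in which
  under 5% of diploid bins stray beyond |log2| = 0.5 — quiet enough for
  single-copy events spanning tens of bins to be unambiguous, which is
  the premise of copy-number calling at this coverage.
- `d_c` — per-cell lognormal library-size factor (`depth_sd`, default
  0.15). Real single-cell libraries are sequenced toward a per-cell read
  target with substantial technical spread, so total depth varies between
  cells independently of ploidy. Without this factor, total read count
  would be a deterministic function of a clone's total copy number and
  the cohort bin-count filter would act as a ploidy filter rather than a
  technical-quality screen. Depth cancels in the pipeline's per-cell
  normalization.
- A fraction `outlier_fraction` (default 5%) of cells are low-quality:
  their WGA noise is multiplied by `outlier_noise_mult` (default 8) and
  their NB size divided by it. These are the cells the MAD filter is
  meant to remove.

**Mutations.** Clones carry named heterozygous mutations; member cells
are genotyped present/absent (Sanger-style). A carrier cell reads
*absent* with probability `dropout` (default 0.2) — one WGA allele lost
at random — so false negatives are expected and false positives are not
modelled. An optional `missing_rate` produces no-call entries.

**Allocation.** Cells are allocated to clones and to the normal-cell
remainder by deterministic largest-remainder rounding of the per-region
fractions, then shuffled with the run's seed. This makes clone sizes
exact (a 0.9-purity, 40-cell region contains exactly 36 tumour cells)
and eliminates empty-clone flakiness in tests.

**What is not simulated.** GC/mappability bias (the panel-of-normals
normalization would divide it out, so it is invisible to everything
downstream), doublets, read-level artefacts, allele-specific states, and
chromothripsis-style complex rearrangements. Passing tests on these
simulations therefore demonstrate the pipeline's statistical machinery
under its stated noise model, not robustness to every artefact of real
WGA libraries.

**Default genome.** Simulations run on a scaled-down seven-chromosome
genome (72.5 Mb, 1450 bins of 50 kb; chr1 = 20 Mb … chr7 = 6 Mb, p/q
boundary at 40% of each chromosome). The scale keeps a full two-region
tumour through CBS in seconds while still representing all four event
scales (whole-chromosome, whole-arm, subchromosomal > 15 Mb on chr1,
focal). Bin width, thresholds and statistics are identical to what a
full-genome run would use; only the number of bins is reduced.

## Quality control and normalization

- **Bin-count filter:** a cell fails when its mean bin count is strictly
  outside cohort mean ± 2 sample SDs (ddof = 1). Cohort statistics are
  computed once on the full cohort and never re-computed after
  exclusions, so the filter is idempotent when its frozen statistics are
  reused.
- **Noise score:** the derivative MAD — median absolute deviation of
  consecutive-bin differences of the depth-normalized profile — the
  convention of shallow-WGS QC. The failure cutoff defaults to cohort
  median MAD + 2 × MAD-of-MADs and is configurable; it reliably isolates
  the simulated outlier cells, whose bin-to-bin noise is several-fold
  inflated.
- **Panel of normals:** per-bin median of depth-normalized diploid
  control profiles. Bins with zero reference are masked and propagate as
  missing (NaN), never as zero. Per-cell log2 ratios divide by the cell's
  mean unmasked bin count and by the panel; zero-count bins receive a
  0.5-read pseudocount. The transform is invariant to rescaling a cell's
  counts.

## Segmentation and CNV events

- **CBS.** Per chromosome, the arc (i, j] maximizing
  |mean_in − mean_out| / (s·√(1/k + 1/(n−k))) is a candidate split,
  accepted when its within-chromosome permutation p-value estimate
  (exceedances / permutations) falls below `alpha = 1e-5`; the recursion
  continues on the pieces. Permutations (default 1000) run in growing
  batches with early stopping: a single exceedance already forces
  p ≥ 1/1000 > α, so null splits cost a handful of permutations while
  true splits pay the full budget. When the permutation count cannot
  resolve α a warning is issued and acceptance reduces to "no permutation
  reaches the observed statistic". No separate undo/prune step is
  implemented; short spurious segments are absorbed by merging.
- **Merging.** Adjacent segments merge when their integer copy numbers
  are equal or a Welch test on their bin-level values has p ≥ 0.01;
  merged means/CNs are recomputed from the bins and passes repeat to a
  fixpoint, so the result does not depend on scan direction. Segments
  with fewer than two bins can merge only via CN equality.
- **Integer CN.** Default rule `CN = round(2 · 2^m)` clipped to [0, 8].
  A literal single-copy-threshold mode (aberrant only at |m| ≥ 1) is
  provided for comparability, but note that a single-copy gain has
  expected ratio log2(3/2) ≈ 0.585, which that convention cannot call;
  the rounding rule is therefore the default.
- **Consolidation.** Aberrant segments from different cells group (per
  chromosome and direction) by transitive closure of a coordinate match:
  reciprocal overlap ≥ 0.8, or both boundaries within 2 bins (the
  disjunction lets short events, where overlap ratios are coarse, still
  group). Groups with ≥ 3 distinct supporting cells become events with
  median boundaries; smaller groups are discarded as non-reproducible.
  Scale labels: whole-chromosome (≥ 90% of the chromosome's bins), else
  whole-arm (≥ 90% of one arm), else subchromosomal (> 15 Mb), else
  focal.

## Clone inference

- Cells are embedded on the union of all segment breakpoints; Euclidean
  distances weight each segment by its bin count, which equals the
  per-bin distance at a fraction of the cost. Ward linkage, deterministic.
- **Choice of k** (k_max = 6, covering the observed 1–4 tumour clones
  plus a normal cluster): elbow (argmax of the second difference of
  within-cluster SS), silhouette (argmax mean silhouette, k ≥ 2), gap
  statistic (uniform-box reference, B = 50, seeded; smallest k with
  Gap(k) ≥ Gap(k+1) − s(k+1)) — majority vote, ties toward the gap
  statistic, the only criterion defined at k = 1. A k-means/PCA(2)
  cross-check reports the ARI against the hierarchical labels.
- **Minimum clone size.** Aberrant clusters smaller than the 3-cell
  reproducibility rule are merged into the nearest cluster by weighted
  centroid distance (all-diploid clusters are exempt — normal cells are
  defined by the absence of events). A single cell with one spurious
  segment otherwise occasionally seeds a singleton "clone" and inflates
  the substructure category; under the 3-cell detection rule such a
  cluster is not a detectable clone in the first place.
- Consensus CN per segment is the member majority, ties resolved toward
  diploid; clusters with an all-diploid consensus are normal cells.
  Purity = non-normal cells / passing cells. Substructure categories: 1
  tumour clone = none, 2 = moderate, ≥ 3 = extensive. Detection
  sensitivity is reported as min_cells/n, e.g. 3/31 ≈ 10%.

## Clonality, phylogeny, evolution modes

- A CNV is present in a clone when its supporters cover ≥ 50% of the
  clone's members (copy-number dropout at 0.15x makes unanimity too
  strict); a mutation is present on ≥ 1 positive member (Sanger dropout
  is one-sided). Clonal = present in every tumour clone; clonal events
  are assigned the *initiation* epoch, subclonal ones *later*. For an
  all-negative clone of size m the residual probability that dropout
  alone explains it, δ^m, is reported.
- Clone trees: classic Saitou–Nei neighbour joining on bin-weighted
  Euclidean distances between clone consensus profiles plus an
  all-diploid taxon; negative NJ branch lengths are clamped to zero with
  the deficit moved to the sister branch (path lengths preserved). The
  tree is re-rooted at the node subtending the normal leaf, which makes
  re-rooting idempotent.
- **Evolution modes** are assigned by explicit rules rather than by a
  mutation-tree sampler: one tumour clone → *no evolution*; event-set
  nesting (one clone's events a strict superset of another's) or an
  event loss (a carrier set that is not the leaf set of any subtree of
  the rooted tree — a Dollo-style convexity violation) → *gradual
  (branching)*; otherwise (clones share early events and differ only by
  private later ones) → *punctuated*. These are a faithful but
  independent operationalization of the three published trajectory
  descriptions; they are deterministic given the inferred clones and
  events.
- Fishplot tables give clone fractions per region at two pseudo-time
  points: *Later* is the observed admixture; *Earlier* collapses all
  tumour mass onto the founding lineage — the unique clone whose
  aberrant segments are shared by every other clone when one exists,
  otherwise a synthetic "ancestor" row. "Earlier" is qualitative
  pseudo-time, not calendar time.

## Spatial statistics

Two-sided Fisher exact tests use the "probability mass ≤ observed"
convention (as in R), with a 1e-7 relative tolerance when comparing table
probabilities to avoid floating-point boundary misclassification. The
2x2 path delegates to scipy; the r x c test enumerates all tables with
the observed margins recursively (seeded Patefield Monte-Carlo with 1e5
draws when enumeration would exceed ~2e6 states). BH-FDR is applied per
tumour, separately for the clone family and the CNV family — the most
conservative family definition consistent with reporting per-tumour
tables. Clones or events whose supporters all fall in one region are
flagged region-specific.

## Problem sizes used in validation

The test suite and acceptance script validate on: 20-seed three-clone
recovery studies (40 cells/region × 2 regions), 10-seed runs of each of
the three trajectory archetypes (25 cells/region), 100 single-changepoint
CBS-vs-oracle profiles (200 bins), 50–90 random additive trees of 4–8
taxa, a simulated 14-tumour cohort mirroring the studied risk
composition (25 cells/region), and 1000 random tables for exact-test
cross-validation. These sizes were chosen to match the scale of the
motivating cohort (~31 analysed cells per tumour; 1–4 clones) while
keeping a full validation run in minutes on one CPU.

## Known limitations

- Integer CN calls assume the cell's median state is diploid; whole-
  genome doubling would be mis-scaled (relative ratios cannot see it).
- No allele-specific or purity-corrected copy number; breakpoints are
  bin-resolution.
- The evolution-mode rules assume event presence/absence is reliable at
  the clone level; heavily subclonal or borderline events near the 50%
  presence threshold can flip a mode call.
- The r x c exact test is exponential in table size; very large tables
  fall back to Monte-Carlo with a seeded estimate.
- Sensitivity claims (clones detectable above ~3/n) are expectations
  under the noise model, not guarantees for arbitrary WGA artefacts.
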
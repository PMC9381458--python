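# scclone

Clonal reconstruction of tumours from **single-cell shallow whole-genome
sequencing** (sc-WGS) copy-number profiles.

Shallow sc-WGS (~0.15x per nucleus, read counts in fixed 50 kb genomic
bins) resolves the integer copy-number landscape of individual tumour
cells. `scclone` turns a bins x cells count matrix into a full clonal
portrait of each tumour: per-cell quality control and panel-of-normals
normalization, circular binary segmentation (CBS), integer copy-number
calls, consolidation of recurrent CNV events, clone deconvolution by
consensus clustering, clonal/subclonal assignment of CNVs and targeted
mutations (allelic-dropout aware), neighbour-joining clone phylogenies,
classification of each tumour's evolutionary trajectory, and exact-test
statistics for two-region spatial heterogeneity. It is aimed at
cancer-genomics analysts working with FACS-sorted, WGA-amplified nuclei —
the motivating setting is childhood medulloblastoma, where clonal
complexity tracks clinical risk — but nothing in the pipeline is
tissue-specific.

A first-class synthetic-data generator (`scclone.simulate`) emulates the
whole data-generating process (negative-binomial counts with lognormal
WGA noise, library-size variation, low-quality outlier cells, normal-cell
admixture, two sampled regions, Sanger-style mutation genotypes with
allelic dropout) and exports complete ground truth, so every stage of the
pipeline is validated end-to-end against simulations with known answers.

## The model in brief

For cell *c* in bin *b*, observed counts are modelled as
`X_cb ~ NegBin(mean = d_c * r * CN_cb / 2 * g_cb, size = theta)` with
per-cell depth `d_c` and per-bin WGA factor `g_cb` lognormal. The
pipeline normalizes each cell by its mean bin count and by a per-bin
reference (the median depth-normalized profile of diploid control cells),
yielding log2 ratios `m`. CBS splits each chromosome where the arc
statistic's permutation p falls below `alpha = 1e-5`; segments get
`CN = round(2 * 2^m)` clipped to [0, 8]. Recurrent aberrant segments
(>= 3 cells, consistent coordinates) become CNV events classified as
whole-chromosome / whole-arm (>= 90% coverage), subchromosomal (> 15 Mb)
or focal (< 15 Mb). Cells x unified-segments matrices are Ward-clustered
(Euclidean distances weighted by segment bin counts); the clone number is
the consensus of elbow, silhouette and gap statistics, cross-checked by
k-means on a 2-PC projection. An event is **clonal** when present in
every tumour clone, else **subclonal**; clone consensus profiles plus a
diploid taxon give a re-rooted neighbour-joining tree, from which each
tumour is assigned **no evolution**, **punctuated** or **gradual
(branching)** evolution by explicit rules over clone count, event-set
nesting and event loss. Two-region heterogeneity is tested with exact
Fisher tests (2x2 fast path and full r x c enumeration) under
Benjamini-Hochberg FDR control per test family.

## Worked example

Simulate a very-high-risk-like tumour (three nested clones, one lost CNV,
two sampled regions) and run the full pipeline:

```bash
scclone simulate --archetype gradual --cells-per-region 25 --seed 42 --out demo
scclone run --counts demo/counts.tsv --bins demo/bins.bed \
    --metadata demo/metadata.tsv --genotypes demo/genotypes.tsv \
    --out demo_out --seed 42
```

which prints

```
tumour  cells_in  cells_pass  purity_pct  n_clones  category              mode  sensitivity_pct
    T1        50          39        92.3         3 extensive gradual_branching              7.7
```

Of the 50 sequenced cells, 39 pass QC; 92.3% of those are aneuploid
(tumour purity), they split into 3 clones (an "extensive" substructure),
the trajectory classifies as gradual/branching evolution, and with 39
cells and the 3-cell reproducibility rule, subclones above ~7.7% of cells
are detectable. `demo_out/T1/` then contains the per-cell segments
(`segments.seg`, SEG format), the consolidated events with clonality
(`events.tsv/.json`), the clone table, the re-rooted NJ tree
(`clone_tree.nwk`):

```
(normal:17.33,B:6.96,(A:6.26,C:9.86):2.17);
```

fishplot-ready clone fractions per region at two pseudo-time points
(`clone_fractions.tsv`), and the two-region Fisher tests
(`spatial_tests.tsv`). The same analysis is available in-memory via
`scclone.pipeline.analyse_tumour`.

## Layout

| module | contents |
| --- | --- |
| `scclone.genome` | bin grids (`build_genome`, `default_genome`) |
| `scclone.simulate` | synthetic cohorts with ground truth; clone-tree archetypes |
| `scclone.qc` | cell QC (derivative MAD, 2-SD bin-count filter), normal panel, log2 ratios |
| `scclone.segment` | CBS, segment merging, integer CN calls, CNV consolidation, scale labels |
| `scclone.clones` | segment matrix, Ward clustering, optimal k, purity, detection sensitivity |
| `scclone.clonality` | clonal/subclonal events, dropout-aware mutation integration, biomarkers |
| `scclone.phylo` | neighbour joining, re-rooting, evolution modes, fishplot tables |
| `scclone.spatial` | exact 2x2 and r x c Fisher tests, BH-FDR, spatial report |
| `scclone.pipeline` / `scclone.cli` | orchestration, file I/O, cohort association tests |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
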
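# Methods

This note documents the models and procedures implemented in `linehet`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic benchmarks do and do not demonstrate.

## Data model and conventions

All genomic coordinates are 0-based half-open internally; GTF input
(1-based closed) is converted on read. scATAC fragment files are 4- or
5-column tab-delimited records (chrom, start, end, barcode[, duplicate
count]); a missing fifth column defaults to 1, and coverage computations
count each unique fragment once. A fragment is attributed to a genomic
window (a coverage bin or a TSS window) by its **midpoint**. Midpoint
assignment makes binning a partition — per cell and chromosome the
normalized bin coverages sum to exactly 10,000 — and makes window counts
unambiguous: a 150-bp fragment cannot be *contained* in a 101-bp TSS
window, and counting interval intersections would inflate the TSS score of
uniformly placed fragments by (window + fragment length)/window ≈ 2.5×.
Under midpoint counting the expected score of promoter-free chromatin is
the window-length ratio 101/4001 ≈ 0.025, which is what both the generator
and the caller's oracle tests assume.

## Quality control

RNA: keep cells with UMI > 1000 **and** detected genes > 500 (strict
inequalities). ATAC: keep barcodes with unique fragments ≥ 1000 and TSS
proportion ≥ 4, where TSS proportion = 100 × (fragments with midpoint
within ± 2000 bp of any TSS) / (total fragments of the barcode). The TSS
proportion is expressed as a percentage so the threshold of 4 is
dimensionally sensible. Filtering is idempotent and order-preserving;
"UMI" refers to deduplicated counts.

## Embeddings and clustering

RNA cells are embedded by the standard recipe — library-size normalization
to 10,000 counts, log1p, selection of the 2000 most variable genes
(dispersion-based), per-gene scaling clipped at 10, PCA (default 30
components, ARPACK, fixed random state) — via scanpy. ATAC cells are
embedded by latent semantic indexing: the cell × 100-kb-bin matrix is
binarized, TF-IDF transformed (log1p(tf · idf · 10⁴)) and reduced by
truncated SVD; the leading component is dropped when |r| > 0.9 against log
depth, and components are ordered by decreasing variance.

Clustering builds a k-nearest-neighbor graph (k = 20, Euclidean,
symmetrized union) and optimizes modularity with the Leiden algorithm
(RBConfiguration objective) at resolution 0.3 by default (0.15 available).
Labels are relabeled by decreasing cluster size with first-member
tie-break, so output is deterministic given the seed.

Markers use a one-vs-rest two-sided Wilcoxon rank-sum test on
log-normalized values with Benjamini–Hochberg correction across genes
within each cluster; log2 fold change uses a pseudocount of 1 on mean
normalized expression, which keeps it finite and exactly antisymmetric on
two-cluster problems. A gene is a marker when adjusted p < 0.01 **and**
log2FC > 0.5 (strict). Clusters with fewer than 3 cells are skipped.

The discrete/continuous pattern call makes the visual dichotomy
quantitative: *discrete* iff the clustering has ≥ 2 clusters and sampled
within-cluster pairwise distances are smaller than between-cluster ones by
a one-sided rank-sum test at p < 0.01 with median(within) <
median(between). Pair sampling uses a fixed internal seed (up to 20,000
pairs per class), so the call is reproducible.

Pooled-run cell-line assignment scores each cluster against each reference
bulk profile as |cluster markers ∩ top-200 reference genes| / |cluster
markers|, assigns the argmax when the score reaches 0.1, and reports the
margin over the runner-up as confidence. The overlap statistic is this
package's definition; the score threshold and top-N are exposed.

## Diversity score

Per line: restrict the embedding to its first 30 components, compute the
centroid (per-component mean over the line's cells), measure each cell's
Euclidean distance to the centroid, remove cells whose distance lies
outside mean ± 3 SD of the line's distance distribution, and average the
remaining distances. Removal is single-pass and the centroid is **not**
recomputed after exclusion — a deterministic reading of an ambiguous rule,
chosen because the distances are what the score averages. The outlier test
keeps cells with |d − mean| ≤ 3 SD (non-strict), so a zero-variance
distance distribution (e.g. a symmetric two-point configuration) keeps all
cells and the score has the closed form d. The score is
translation/rotation invariant and scales linearly with positive scaling;
lines with < 2 cells report a missing score. Group comparisons
(discrete vs continuous, differential vs indiscriminate) use a one-sided
Wilcoxon rank-sum test, exact for small tie-free samples.

## NMF expression programs

Per line (≥ 100 cells): log-normalize, z-score each gene, set negative
values to zero, and run NMF (nndsvd initialization, fixed seed, tolerance
1e-4) at k = 6, 7, 8, 9. Each factor contributes a program: its 50
top-loading genes. A program is **robust** when a program at a different k
shares ≥ 35 of its 50 genes (the 70 % convention); robust programs sharing
≥ 35/50 genes within a line are deduplicated keeping the smallest-k
representative. Across lines, programs are clustered by average-linkage
hierarchical clustering on 1 − Jaccard over gene sets, cutting the tree at
distance 0.9. The cut admits members with pairwise Jaccard well above the
random expectation (two random 50-gene sets from 20,000 genes share
Jaccard ≈ 0.006; implanted identical modules score ≥ 0.5) and is exposed
in the API. Clusters spanning ≥ 4 distinct lines (> 3) are **recurrent**;
their signature genes appear in strictly more than 25 % of member
programs.

Module scoring follows the binned-control scheme: genes are ranked by mean
log-normalized expression into 25 equal-size bins; each target gene draws
100 control genes from its bin — the whole bin when it holds ≤ 100 genes,
which makes the score exactly zero when the target set is the entire gene
universe; the score is the target mean minus the control mean per cell.
Program co-occurrence across lines uses the one-tailed hypergeometric test
on member-line overlap with BH correction across cluster pairs.

## CNV subclones

The CNV profile is a deliberate simplification of HMM-based tools, using
their stated core: genes are ordered by genomic position; expression is
normalized to counts-per-million and log2(x+1)-transformed (at CPM scale
typical values sit far above the pseudocount, so differences read as log2
dosage ratios — with the conventional 10⁴ target the mean normalized value
equals 10⁴/n_genes and the pseudocount flattens a 2× gain to ≈ 0.5);
genes with mean raw count < 0.1 are excluded (the external tool's cutoff);
each gene is centered on the reference-normal-cell mean; each cell is then
centered on its median residual — a gained block inflates the cell's
library and deflates every normalized value, and the median restores the
scale — and, because the cell-median of a skewed residual distribution is
itself biased, the per-gene zero is re-anchored on the identically
centered reference cells. Per cell, a moving average over a centered
400-gene window (truncated at chromosome ends) is taken and clipped to
± 3. On synthetic data a 2× gain over ≥ 400 genes yields a plateau of
≈ 0.85 in carrier cells, within the expected log2(2) = 1 up to residual
pseudocount compression.

Subclone detection: per chromosome arm (whole chromosomes when no cytoband
table is given), the mean profile value per cell is tested for bimodality
— a 2-component Gaussian mixture must beat 1 component by a BIC margin
> 10 with component means separated by > 0.2. If any arm is flagged, an
average-linkage hierarchy over the flagged-arm signal matrix is cut into
exactly 2 subclones (the cut rule is unstated upstream; two is the
conservative choice and is documented as a cap). Association typing:
**C** if one subclone; **A** if every subclone has ≥ 90 % of its cells in
a single transcriptomic subcluster; **B** otherwise. The hypergeometric
enrichment helper computes the exact upper-tail probability and is checked
against exhaustive enumeration for all margins ≤ 12.

## ecDNA detection

Parameters (all exposed in `EcdnaParams`, defaults in parentheses): bin
size (100,000 bp), relative-coverage threshold (6, strict `>`; the
inclusive reading is available via a flag), minimum supporting cells (15,
strict), TSS score maximum (0.25), TSS windows (± 50 / ± 2000 bp), PCC
threshold (0.3), merge fraction (0.7), vicinity (1 Mb), cluster divisor
(3), minimum nonzero bins per cell (50), KDE peak prominence (5 % of the
density maximum).

Per cell, the reference (two-copy) coverage is the location of the
lowest-coverage local maximum of a Gaussian KDE (Silverman bandwidth, 512
grid points, zero-padded ends) over its nonzero normalized bin coverages,
requiring prominence ≥ 5 % of the global maximum; constant input returns
the constant, and cells with < 50 nonzero bins are excluded from calling
(they also leave the cell-count denominator). Candidate bins need relative
coverage > 6 in > 15 counted cells; consecutive retained bins merge into
candidate fragments. The TSS filter pools the fragments of each
candidate's supporting cells inside its interval and scores
(midpoints within ± 50 bp of any interval-resident TSS) / (midpoints
within ± 2000 bp); candidates scoring ≥ 0.25 are promoter-like
(CNV/random chromatin) and are dropped; intervals without TSS fragments
score 0 — maximally non-promoter-like — and survive.

Merging: fragments are profiled by their per-cell mean relative coverage;
the Pearson correlation matrix feeds an average-linkage hierarchy on
1 − PCC cut into ⌈n/3⌉ clusters; a cluster merges into a single region
when > 70 % of its fragment pairs have PCC > 0.3 and all members lie
mutually within 1 Mb on one chromosome (the operationalization of
"neighboring"); other fragments pass through as singletons. A single merge
pass is performed (not iterated to a fixpoint). Merged regions span
min(start)–max(end), recompute their TSS score over the merged interval,
and must still satisfy the TSS and cell-count invariants. Downstream
statistics report per-region supporting-cell fractions, one-tailed
hypergeometric oncogene enrichment against the gene universe, and — when
an RNA matrix with shared barcodes is supplied — the Spearman correlation
between per-cell region coverage and summed resident-gene expression
(reported missing when either side is constant); with unmatched cells the
positive-cell fraction is compared against the high-expressing-cell
fraction (mean + 2 SD threshold).

## Cross-condition matching and label transfer

Anchor-based integration is replaced by a **joint-embedding stand-in**,
documented as such: the two condition matrices are restricted to their
shared genes, pooled for HVG selection, scaled per condition (z-scoring
within each condition removes global treatment shifts, the linear analog
of what anchor integration does), stacked, and embedded by PCA. Each
condition is clustered separately at resolution 0.3; the integrated data
are clustered at the coarser resolution 0.1, so treatment-induced
subclusters map back onto their parent population rather than fragmenting
it. Cluster a of condition A matches cluster b of B iff > 80 % of the
cells of each lie in one common integrated cluster. A cluster "divided
from one to more" by treatment surfaces as a **one-to-many match** — one
cluster sharing its integrated cluster with two or more counterpart
clusters — and is flagged *split*, as is a condition cluster occupying ≥ 2
integrated clusters at ≥ 20 % each; matched rows proper are one-to-one.

Label transfer computes a per-ATAC-cell gene activity (fragment midpoints
over the gene body extended 2 kb upstream, strand-aware — a simple
interval-overlap stand-in for distance-weighted scores), embeds activity
and expression jointly as above, and assigns each ATAC cell the majority
RNA cluster among its k = 25 nearest RNA neighbors iff the majority
fraction (the prediction score) exceeds 0.9. This k-NN purity score is an
analog of anchor-transfer prediction scores; the gate is exposed because
the two scores need not calibrate identically. Between-condition
differential expression within matched pairs uses the rank-sum test with
BH correction; significance requires adjusted p < 0.01 and |log2FC| > 2
(pseudocount 1 on mean normalized expression), with pairs under 3 cells
per side skipped.

## Synthetic data

RNA counts are Gamma–Poisson (negative binomial): per-gene baseline means
are drawn from Gamma(shape 0.25, scale 8) by default (a heavy-tailed,
UMI-like profile of ~2 counts/gene), each line upweights its own marker
block (100 genes × 8 by default — the pooled-run structure that
expression-based line assignment requires), CNV blocks multiply contiguous
gene ranges in subclone cells, programs multiply their gene sets by
2^log2-fold in a Bernoulli-sampled active fraction, and counts are drawn
Poisson(Gamma(dispersion 2, mean/dispersion)). Genes are laid out
contiguously on synthetic chromosomes so CNV windows are well defined.
ATAC fragments are Poisson per 100-kb bin (background 3 per bin per cell)
with multipliers over CNV/ecDNA intervals; ecDNA positivity is an
independent Bernoulli per cell (stochastic segregation); background
fragments land in ± 50 bp TSS windows with probability
`tss_concentration` (default 0.5), while ecDNA bins of positive cells
place fragments uniformly; fragment length is fixed at 150 bp since only
coverage enters downstream computations. Optional dropout intervals
suppress fragments to emulate mapping gaps. All generators are pure
functions of (config, seed).

Benchmark problem sizes — 500 cells over a 60-Mb two-chromosome genome for
the ecDNA caller, 6 lines × 800 cells × 1000 genes for program recovery,
600 + 600 cells × 2000 genes for CNV typing (depth ≈ 30,000 counts/cell,
mirroring real UMI depth at this gene count), 2 × 800 cells for condition
matching — are chosen so each stage's signal regime matches the real
data's (amplicon copy number ≥ 8 vs CNV 2.5 vs diploid background;
program activity in 30 % of cells at 4-fold; a latent responder module of
150 genes at 2.6-fold in half of one line, strong enough for the treated
data to support an extra subcluster yet weak enough for the integrated
clustering to keep the parent population together) while keeping the full
suite in minutes on one CPU.

**What the benchmarks do not show.** The generators make no attempt at
read-level realism: no sequence content, no doublets, no batch effects, no
peak structure beyond TSS concentration, Gaussian-free cluster geometry,
and independence across genes and bins given the programmed structure.
Passing them demonstrates that each algorithm recovers the structure it is
designed for under its own model assumptions — correctness and
calibration of the machinery — not that those assumptions hold in any
particular real dataset. On real data the ecDNA caller in particular
cannot distinguish high-copy, broadly accessible chromosomal amplicons
from true extrachromosomal circles without junction-read support, and its
calls should be treated as candidates for orthogonal validation.

## Known limitations

- The CNV module is a window-average re-implementation, not an HMM; it
  reports relative dosage signal, caps subclones at two, and requires
  user-supplied reference normal cells.
- The matching and transfer modules use linear joint embeddings; nonlinear
  batch structure between conditions or modalities is out of scope.
- GSEA-style annotation of program clusters reduces to hypergeometric
  overlap against user-supplied GMT collections; no gene-set database is
  bundled.
- The ecDNA merge is a single pass over the fragment correlation
  hierarchy; pathological fragment chains spanning > 1 Mb end-to-end are
  not re-merged transitively.
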
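# Methods

## Scope and data model

`clonotolerance` re-implements, as a tested library, a paired single-cell
transcriptome (5' scRNA-seq) plus T cell antigen receptor (scTCR-seq)
analysis of peripheral T cell tolerance in advanced mouse atherosclerosis.
The unit of analysis is the `CohortDataset`: a sparse gene-by-cell count
matrix, per-cell metadata over six tissues (wild-type renal lymph node,
Apoe-deficient renal lymph node, artery tertiary lymphoid organ [ATLO],
plaque, and the two blood compartments), and a paired TCR table keyed by
cell barcode.  All stages consume this object; nothing depends on a
particular clustering or embedding.

## Barcode pairing

A cell enters the paired TCR table only with at least one productive TRA
contig, at least one productive TRB contig, and a barcode present in the
expression matrix.  When a barcode carries multiple productive contigs of
one chain (double-alpha cells are common in droplet data), the highest-UMI
contig represents the chain; UMI ties break by lexicographic CDR3 amino
acid and then V gene, so pairing is invariant to input row order.  V
segments are canonicalized by stripping the allele suffix
("TRBV13-3*01" -> "TRBV13-3"); a `family` granularity ("TRBV13") is
available because the field uses both conventions and the clonotype
definition below depends on the choice.  Default: allele-free gene.

## Quality control

Cells with fewer than 200 detected genes are removed everywhere; cells
exceeding a tissue-specific detected-gene cap or mitochondrial percentage
are removed (blood: >3,000 genes or >10% mito; lymph nodes and ATLO:
>4,000 or >8%; plaque: >5,000 or >8%).  Removal is strictly ">" at every
boundary (a blood cell at exactly 3,000 genes or exactly 10% mito is
retained).  Mito percentage is mitochondrial counts / total counts x 100
with case-sensitive prefix `mt-`.  The gene filter (detected in fewer than
three cells) runs once, after the cell filters; the filters are not
iterated.  Note that on very small matrices a second application can
remove further cells because dropping genes lowers per-cell detected-gene
counts; at realistic cell numbers the filter is idempotent.
Normalization, where an operation calls for it, is library-size scaling to
10,000 counts per cell followed by log1p.

In the end-to-end pipeline on simulated cohorts the detected-gene floor is
scaled to 30 because the synthetic gene panel has ~120 genes; the
per-tissue caps and mito rules keep their genome-scale values.

## Clonotypes, expansion, sharing, twins

A clonotype key is the quadruple (TRA V, TRA CDR3 aa, TRB V, TRB CDR3 aa)
under exact string equality.  Clones with at least `min_clone_size = 2`
cells are called expanded; the threshold is configurable because the
source material states both ">= 2 cells" and "more than two cells" — the
two-cell twin pair treated as expanded settles it at 2.  Expansion
percentages are per tissue: clone sizes are computed within each tissue,
so a 1+1 cross-tissue pair makes neither cell expanded.  Global scope
(sizes across tissues) serves twin discovery — clonotypes occurring in at
least two tissues — and cross-tissue sharing.

Sharing between a source tissue and a target set is computed at the
alpha-chain, beta-chain, or paired level: the fraction of filtered source
cells whose CDR3 (at that level) occurs among the correspondingly filtered
target cells.  The denominator is cells, not clonotypes, matching how the
percentages are quoted; `expanded_only` and a parent-group filter restrict
both sides symmetrically.  The fraction is monotone in the target set.

V usage is reported per tissue as individual V count / total V count x
100; V-J pair counts for circos-style plots come from the contig records,
since the paired table does not retain J segments.

## Repertoire diversity

Shannon entropy H = -sum p_i log2 p_i (bits) and the Gini index
G = sum_i (2i - n - 1) x_(i) / (n sum x) over ascending-sorted clone sizes,
without small-sample correction (the n/(n-1) factor is an option).  Groups
are compared after repeated downsampling without replacement to a common
depth — default floor(0.95 x smallest group), always recorded — with 1,000
replicates by default, then a Kruskal-Wallis test per index and Dunn's
all-pairs post hoc z comparison (pooled mid-ranks, tie correction),
Bonferroni-adjusted.  Because replicates within a group are resamples of
one cell pool, the comparison is calibrated under the null exactly when
the groups' clone-size structures are identical; the test suite verifies
rejection at no more than the nominal rate in that setting.

A note on monotonicity: moving one cell from a singleton into the largest
clone raises Gini in the Pigou-Dalton sense only if the emptied clone is
retained at size zero; removing it from the distribution can lower the
index.  The property test uses the zero-retaining form.

## Subset annotation and the correction rule

Ten subsets are assigned by ordered first-match rules over raw-count
positivity (count > 0) of {Cd4, Cd8a, Foxp3, Cd44, Sell, Ccr7, Klrb1c,
Tcrg-C1, Trdc, Ly6c1, Gzmk}; the table ships as versioned YAML.  The
published marker combinations annotate Ccr7 as high/int/low; every pair of
subsets already differs in at least one binary marker, so the default
rules use binary predicates only, and Ccr7 tertile levels (computed among
Ccr7-positive cells on normalized expression, zero counts = low) are
reported rather than enforced.  `strict_ccr7` enables enforcement.  Ten
subsets collapse onto five parent groups: CD4 effector/memory (I), Treg
(II), CD8 effector/memory including NKT-like (III), naive (IV), gamma-delta
(V).

Clonally expanded cells are re-checked against six markers (Cd4, Cd8a,
Cd44, Sell, Ccr7, Gzmk).  Lineage: CD4 if Cd4+Cd8a-, CD8 if Cd8a+Cd4-,
else unchanged.  State: Tem if Sell-Ccr7- and (Cd44+ or Gzmk+); Tcm if
Sell+Ccr7+ and (Cd44+ or Gzmk+); naive if Sell+Ccr7+Cd44-Gzmk-; else
unchanged.  The rule is idempotent, reproduces all ten printed correction
rows exactly (including the Gzmk-driven Tcm call with Cd44 = 0 and the
keep-original fallbacks), and only applies to lineage-state labels —
Treg/NKT/gamma-delta labels pass through.  Positivity is raw count > 0,
consistent with the printed integer counts; the threshold is configurable.
Pairing accuracy is (1 - corrected/expanded) x 100.

## Treg-TH17 conversion

Treg cells are parent group II (effector plus central Treg).  For each of
the pairs (Foxp3, Rorc), (Nrp1, Rorc), (Il2ra, Rorc), a cell is double
positive when both raw counts exceed zero; percentages are reported to two
decimals per tissue, with explicit NA rows for tissues lacking Treg cells.

## Differential expression and the plaque-inducible signature

Per-gene two-sided Wilcoxon rank-sum tests run on log-normalized counts;
avg log2FC is log2(mean(expm1 x_A) + 1) - log2(mean(expm1 x_B) + 1), the
single-cell convention.  Significant genes need adjusted p < 0.05 and
|avg log2FC| > 0.25; both thresholds are parameters (the fold-change gate
is kept even where only the p gate is quoted, flagged rather than silently
chosen).  Adjustment is Benjamini-Hochberg or Bonferroni per call, never a
global setting, because different analyses in this design use different
corrections.

The plaque-inducible signature restricts to cells of clonotypes present in
the focal tissue and at least one reference tissue, then contrasts focal
members against pooled reference members; a per-clone mode recomputes fold
changes within each shared clonotype to check the signature is independent
of the particular TCR.  Swapping focal and reference negates every fold
change.

## APC checkpoint score and cross-species comparison

The antigen-presenting-cell score per tissue and gene is
sum over myeloid cell types of (mean raw expression in the cell type) x
(cell-type fraction of all leukocytes in the tissue).  Raw means keep the
score linear in counts (doubling every count doubles the score), which the
log transform would break.

For cross-species comparison, human genes are renamed through a two-column
ortholog map; unmapped genes are dropped and many-to-one collisions are
summed, conserving mapped counts.  Subset similarity is the Spearman
correlation between per-subset mean profiles over the union of each
pair's top-50 subset-specific genes.  "Subset-specific" is ranked by
one-vs-rest log2 fold change of profile means; a highest-mean mode exists
because the source material describes the ranking both ways.  The operation
takes mean profiles (not cells), so marker ranking from cell-level rank
tests is out of its contract; the profile-level one-vs-rest ranking is the
package's resolution of that ambiguity.

## Composition statistics

Composition differences use Pearson's chi-square followed by post hoc
two-sided Fisher exact tests on all 2x2 collapses (group i vs j, category
k vs rest) with Benjamini-Hochberg adjustment across collapses.  The
two-sided Fisher p sums tables with probability at most the observed
table's, the convention verified in the tests against direct hypergeometric
enumeration.

## Synthetic cohorts

The generator emulates the structure the analyses need, with full ground
truth, at desk scale:

- **Gene universe**: ~120 genes — the classifier markers, the tolerance
  panels (egress, activation, cytotoxicity, exhaustion, Treg, TH17,
  tissue-resident memory, APC costimulation/checkpoint), five
  mitochondrial decoys for QC, and housekeeping filler.
- **Counts**: negative binomial per gene per subset, dispersion theta = 5
  (variance m + m^2/theta); zeros arise naturally, no extra zero
  inflation.  Defining markers have mean 10, supporting genes 2.5, silent
  genes 0.02; broadly expressed activation/structural transcripts (Cxcr6,
  Lgals1, S100a6, S100a4, Reep5, H2-D1) carry a moderate baseline (0.8-1.2)
  so tissue-level fold changes act on a detectable floor.
- **Composition**: per-tissue subset fractions follow the published
  qualitative gradient — naive-rich lymph nodes, effector/gamma-delta-rich
  plaque; default cohort ~13,800 cells over four tissues (5,000 / 5,100 /
  2,400 / 1,300).
- **Clones**: per tissue, alpha/beta-paired cells (all but gamma-delta) are
  assigned clones by a Chinese restaurant process; the concentration
  parameter is the skew dial, with defaults (120,000 / 70,000 / 18,000 /
  4,000) chosen so realized expansion follows the published per-tissue
  gradient of roughly 4 / 7 / 11 / 21%.  Concentrations >= 1e6 are the
  exact all-distinct limit (realized expansion 0).  CDR3s follow the
  canonical C...F motif, length 10-18; V segments draw from per-tissue
  frequency tables planted with the published skews (plaque toward
  TRBV31/TRBV5, Apoe-deficient node toward TRBV13-3, ATLO toward
  TRBV19/TRBV16).
- **Sharing**: each plaque clonotype is re-used in the ATLO or
  Apoe-deficient node with probability `sharing_prob` (default 0.3) by
  overwriting one target clone's key, preferring expanded target clones so
  sharing concentrates among expanded cells on both sides.
- **Twins**: `twin_count` (default 5) clonotypes are planted as exact 1+1
  pairs across the Apoe-deficient node and plaque, never reusing a cell.
- **Conversion**: each Treg cell is planted as a TH17 double positive with
  a per-tissue probability (defaults follow the published Foxp3+Rorc+
  rates, 0.0037-0.0274); planted cells force Rorc, Foxp3, Nrp1, Il2ra >= 1
  and Rorc is otherwise silent, so detection recovers the planted set
  exactly and the three marker pairs coincide on synthetic data.
- **Plaque-inducible effect**: configured genes (default Cxcr6, Lgals1,
  S100a6, Reep5 at fold 3) have their means multiplied in every plaque
  cell.

What the generator does **not** model, and what passing tests therefore do
not show about real data: transcriptome-wide expression, doublets and
ambient RNA, batch effects, clone-phenotype coherence (subsets are drawn
per cell, so the cells of one clone span subsets, which dilutes
subset-filtered sharing percentages relative to real repertoires), and
nucleotide-level convergence.  Same config and seed give byte-identical
output.

## Problem sizes and numerical choices

The default end-to-end demonstration runs the full ~13,800-cell cohort
with 1,000 diversity replicates in well under a minute; unit tests use
cohorts of 200-2,000 cells, 100-replicate diversity runs, and 100-seed
null calibrations, sizes chosen to keep the whole suite in the tens of
seconds while leaving the planted effects unambiguous.  Probability-vector
sums are checked to 1e-9; usage percentages sum to 100 within 1e-9;
entropy uses base 2 throughout (base affects scale, not comparisons).
Degenerate inputs are contracts, not crashes: empty clone-size
distributions and sub-minimal groups raise domain errors, zero sharing
denominators return an explicit empty result, and tissues without Treg
cells yield NA rows.

## Known limitations

Clustering/embedding (t-SNE, SNN), anchor-based integration, ligand-
receptor interactome scoring, and hashtag demultiplexing are out of scope;
cluster labels are produced by the marker rules or accepted as input.  The
downsampling depth of 161 quoted for the original cohort cannot be
re-derived without the deposited data (95% of an unstated plaque cell
count); the default depth rule is therefore floor(0.95 x smallest group)
with an explicit override, and the depth used is always logged.
Full-scale reproduction of the deposited-cohort numbers (expansion
fractions, 61.1% alpha sharing, 81 shared CD8 cells) requires the public
deposit and is not exercised by the test suite.
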
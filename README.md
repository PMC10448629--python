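# clonotolerance

Paired single-cell transcriptome + T cell receptor analysis of peripheral
T cell tolerance checkpoints, built for the atherosclerosis setting:
atherosclerotic plaques, artery tertiary lymphoid organs (ATLOs),
aorta-draining renal lymph nodes (RLNs) and blood of aged wild-type and
*Apoe*-deficient mice.  It is aimed at immunologists with 10x-style
outputs in hand — a gene-by-cell count matrix (MTX + barcodes/features
TSV) and a `filtered_contig_annotations.csv` V(D)J table — who want the
repertoire and tolerance readouts as reusable, tested functions rather
than a notebook.

## What it computes

- **Barcode pairing** of productive TCRα/β contigs with expression
  (max-UMI representative per chain, deterministic tie-breaks).
- **Clonotypes and expansion**: a clonotype is the exact quadruple
  (TRAV, CDR3α aa, TRBV, CDR3β aa); clones with ≥ 2 cells are expanded.
  Expansion percentages are per tissue and per parent group
  (CD4 T_eff/mem I, T_reg II, CD8 T_eff/mem III, naive IV, γδ V).
- **Cross-tissue sharing** of CDR3 sequences at α, β or paired level, and
  **twin-like cells** — clonotypes spanning two tissues.
- **Repertoire diversity**: Shannon entropy H = −Σ pᵢ log₂ pᵢ and Gini
  index G = Σᵢ (2i − n − 1)·x₍ᵢ₎ / (n Σx) under repeated fixed-depth
  downsampling, compared by Kruskal–Wallis with Dunn's all-pairs post hoc
  test.
- **Marker-rule subset annotation** (10 subsets from Cd4/Cd8a/Foxp3/Cd44/
  Sell/Ccr7/Klrb1c/Tcrg-C1/Trdc/Ly6c1/Gzmk) plus the marker-consistency
  **correction rule** for clonally expanded cells and the pairing-accuracy
  estimate.
- **T_reg–TH17 conversion**: Foxp3⁺Rorc⁺, Nrp1⁺Rorc⁺ and Il2ra⁺Rorc⁺
  double-positive rates among T_reg cells per tissue.
- **Plaque-inducible signature**: Wilcoxon DEGs (|avg log₂FC| > 0.25,
  adjusted p < 0.05) of shared-clone cells in plaque versus their clone
  mates in ATLO/RLN.
- **APC checkpoint score**: (mean expression per myeloid cell type) ×
  (cell-type fraction of leukocytes), and **cross-species subset
  similarity** by Spearman correlation over top-50 subset-specific genes
  after human→mouse ortholog mapping.
- A **synthetic-cohort generator** with complete ground truth (planted
  expansion, sharing, twins, conversion, fold changes) so every stage is
  testable without any download.

## Worked example

Run the whole pipeline on a simulated ~13,800-cell cohort:

```bash
clonotolerance run --seed 7 --out demo_run
```

or equivalently from Python:

```python
from clonotolerance import RunConfig, SyntheticConfig, run_pipeline

report = run_pipeline(RunConfig(seed=7, out_dir="demo_run",
                                simulate=SyntheticConfig(seed=7)))
print(report.expansion_per_tissue.to_string(index=False))
```

which prints

```
  tissue  paired_cells  expanded_cells  pct_expanded
APOE_RLN          4928             318      6.452922
    ATLO          2223             234     10.526316
  PLAQUE          1106             261     23.598553
  WT_RLN          4892             154      3.147997
```

— the planted tissue gradient of clonal expansion: a few percent of cells
in wild-type lymph nodes sit in clones of ≥ 2 cells, rising through the
diseased lymph node and ATLO to roughly a quarter of plaque T cells.  The
same run reports the diversity mirror image of that gradient (plaque has
the lowest downsampled Shannon entropy, median 9.78 bits at depth 1,050,
and the highest Gini, median 0.110, against 10.03 bits / 0.003 in the
wild-type node), the T_reg–TH17 conversion table (e.g. 3.49% Foxp3⁺Rorc⁺
plaque T_reg cells versus 0.75% in the wild-type node in this simulation),
the correction report for expanded cells, cross-tissue sharing of expanded
CD8 cells, and the recovered plaque-inducible signature — the planted
genes head the DEG list:

```
  gene  avg_log2FC            p        p_adj direction
S100a6    1.555589 5.753092e-33 6.903711e-31        up
 Reep5    1.384936 3.539251e-31 2.123551e-29        up
Lgals1    1.363040 2.773575e-30 1.109430e-28        up
 Cxcr6    1.350134 1.871250e-21 5.613751e-20        up
```

All outputs land in `demo_run/` as TSV, alongside the serialized run
configuration; rerunning with the same seed reproduces them byte for byte.
Individual stages are available as subcommands (`simulate`, `qc`,
`clonotypes`, `diversity`, `phenotype`) and as plain library calls.

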
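# mpeco

Meta-program discovery and tumour-ecosystem analysis for multi-sample
single-cell RNA-seq.

Multi-patient tumour atlases show that malignant cells re-use a small set of
coordinated gene-expression programs — *meta-programs* (MPs) such as
epithelial differentiation, partial EMT, cell cycle or stress — and that the
balance between them, together with stromal and immune partners
(CAF subsets, SPP1⁺/C1Q⁺ macrophages, NK/T cells), organizes the tumour
ecosystem.  `mpeco` implements the full analysis chain for this kind of
study as a reusable, tested Python package:

1. **QC and normalization** — droplet-style cell filters (genes detected
   > 500, UMI ∈ [500, 10 000], mito < 20%, haemoglobin < 1%), per-sample
   exclusion below 100 cells, log-CPM normalization.
2. **CNV-based malignancy calling** — a simplified inferCNV-style caller:
   reference-subtracted residuals smoothed along the genome, per-cell CNV
   score and correlation, and a matched-filter mixture classifier
   calibrated on the reference cells' empirical null.
3. **Per-sample consensus NMF (cNMF)** — multiplicative-update NMF over
   many restarts; component density filtering, clustering and per-cluster
   median consensus; silhouette stability; rank (K) selection.
4. **Meta-program aggregation** — within-sample recurrence (> 50% top-50
   overlap between independent decompositions), cross-sample hierarchical
   clustering on 1 − Pearson, sharing floor max(⌈20%·n⌉, 3 samples),
   50-gene consensus signatures.
5. **Per-cell signature scoring** — UCell-style capped rank-sum scores in
   [0, 1], state assignment, ssGSEA for bulk profiles, and the
   Wilcoxon/BH/log2FC/detection-difference marker filter.
6. **Ligand-receptor testing** — CellPhoneDB-style limiting-subunit
   statistic with a shared-shuffle label-permutation null; top-100
   selection at p < 0.01.
7. **Ecosystem statistics** — NNLS bulk deconvolution onto a signature
   matrix, Spearman correlation (exact p at small n), Kruskal-Wallis with
   gatekept Dunn/FDR post-hocs, Kaplan-Meier/log-rank survival, and the
   maximally selected ("optimal cutpoint") stratification.

Because the original tumour cohorts are restricted-access, the package
ships a first-class **synthetic-data generator** that emulates their
structure — multi-sample NB counts with planted shared/private programs on
the usage simplex, chromosome-arm dosage clones, planted ligand-receptor
channels, bulk mixtures and survival outcomes — so that every stage is
validated against known ground truth.

## Worked example

An end-to-end run on a small synthetic cohort (4 samples × 220 cells ×
1200 genes, 2 shared programs planted, chr3q/chr7p gains, one planted
stromal→epithelial ligand-receptor channel):

```python
from mpeco import PipelineConfig, SimulationConfig, NMFConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimulationConfig(n_samples=4, cells_per_sample=220, n_genes=1200,
                         n_shared_programs=2, program_gene_size=80,
                         cnv_arms=[("chr3q", 2.0), ("chr7p", 2.0)],
                         lr_pairs_true=[("G1100", "G1101", "stromal", "epithelial", 8.0)]),
    nmf=NMFConfig(k_range=(3, 5), n_restarts=8, max_iter=150, tol=1e-4, k_scan_restarts=5),
    min_cells_per_sample=60, cnv_window=31, lr_n_perm=200, n_bulk=20, seed=5)
result = run_pipeline(cfg)
```

The run report (`result.report`) prints, abridged:

```
"cnv":          {"n_epithelial": 450, "n_malignant_called": 359}
"nmf":          {"chosen_k": {"S1": 3, "S2": 3, "S3": 3, "S4": 3},
                 "stability": {"S1": 0.927, ..., "S4": 0.928}}
"metaprograms": {"MP1": {"n_samples": 4, "n_members": 8},
                 "MP2": {"n_samples": 4, "n_members": 8}}
"scoring":      {"assigned": {"MP2": 205, "MP1": 154}}
"ecosystem":    {"deconvolution_mae": 0.0041, "optimal_cut_p": 0.00021}
```

Reading it: the CNV caller flags 359 of 450 epithelial cells as malignant
(the planted clone); per-sample cNMF settles on K = 3 (2 shared + 1 private
program) with stability ≈ 0.93; the two planted shared programs are
recovered as meta-programs present in all 4 samples; 359 malignant cells
are assigned to their dominant MP; and bulk deconvolution recovers the
planted mixing proportions to a mean absolute error of 0.004.  The per-cell
score correlation between the two recovered MPs is negative
(r = −0.41) — programs competing on the usage simplex — and the top
ligand-receptor hit is the planted stromal→epithelial pair
(mean score 10.5, p = 0.005 at 200 permutations).

The same run is available from the shell:

```bash
mpeco run-all --config cfg.yaml --seed 5 --out results/run1/
mpeco report results/run1/
```

Stage-wise subcommands (`simulate`, `qc`, `cnv`, `nmf`, `metaprograms`,
`lr`, `ecosystem`, `score`, `de`) expose the same pipeline piecemeal.

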
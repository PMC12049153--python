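# Methods

`mpeco` re-implements, as a tested and reusable pipeline, the analysis
pattern used to dissect intratumoral heterogeneity in multi-sample tumour
single-cell RNA-seq: call malignant cells from expression-inferred copy
number, decompose each sample's malignant cells into expression programs by
consensus NMF, aggregate recurrent programs across samples into
meta-programs (MPs), score cells for MP activity, test ligand-receptor
channels between compartments with a permutation null, and relate program
abundance to bulk composition, tumour stage and survival.  Every stage is
validated against a synthetic-data generator that plants known programs,
CNV clones, interactions and outcomes.

## Synthetic data model

Counts are Negative Binomial via a Gamma-Poisson mixture,

```
mu_cg   = libsize_c * sum_k usage_ck * spectra_kg * dosage_cg
count_cg ~ Poisson(Gamma(shape = 1/phi, scale = mu_cg * phi))
```

with a single dispersion `phi` shared across genes (default 0.3 — mid-range
for droplet data; per-gene dispersion would add realism but none of the
validated statistics depend on it).  The synthetic genome assigns genes to
chromosomes 1–22 in contiguous equal blocks with two arms per chromosome;
real genomic annotation is deliberately not used.

Study conditions (the generator defaults): 8 samples x 300 cells x 2000
genes; three compartments (epithelial 50%, stromal 25%, immune 25%); 3
shared expression programs plus 1 private program per sample, each with 100
dedicated genes elevated 5-fold over a lognormal baseline (unit-L1 spectra);
per-cell program usages Dirichlet(0.5) on the simplex; library sizes
lognormal(mean ln ≈ 8, sd 0.3), i.e. ~3000 UMI — inside the QC window so the
filters act only on genuine outliers; 85% of epithelial cells malignant,
carrying 1.5x dosage on chr3q and chr7p (arm-level gains typical of squamous
tumours).  Planted sign structure among shared-program usages is imposed by
a Gaussian copula on the Gamma variables underlying the Dirichlet draw:
with an identity target the construction reduces exactly to independent
Dirichlet sampling, and any monotone correlation target in between is
attainable with a controllable sign.  Ligand-receptor channels are planted
by elevating the ligand gene in the sender state's profile and the receptor
in the receiver's.

Bulk mixtures are linear combinations of pure state profiles expressed on
the log2-CPM scale (values ~0–8, matching real bulk matrices) plus
truncated Gaussian noise; survival times are Exponential with log-hazard
proportional to the z-scored bulk program score, with an independent
Exponential censoring time calibrated to the requested censoring fraction.
Stage (ordinal 1–4) derives from a noisy latent copy of the same score.

What the generator does *not* emulate: batch effects, doublets, ambient
RNA, UMI saturation, gene-specific dispersion, isoform structure, spatial
context.  Passing tests therefore demonstrate correctness of the
algorithms under a clean generative model, not robustness to every artifact
of real data.

## QC and normalization

Cell filters read the droplet-QC conventions literally: retain cells with
*more than* 500 detected genes, total UMI between 500 and 10 000
(inclusive), mitochondrial fraction strictly under 20% and haemoglobin
fraction strictly below 1%; samples with fewer than 100 cells are dropped.
All boundaries are configurable because the conventions themselves do not
fix open/closed endpoints.  General-purpose normalization is
log2(1 + 1e4 · count/total) (log-CPM, base 2, scale 1e4 — a convention
choice).  The CNV caller instead receives log2(1 + count · median-libsize /
total): at 1–3 counts per gene the 1e4 scale factor pushes values deep into
the log regime where a 1.5x dosage shift is compressed while the 0↔1 count
jump is not, roughly halving the per-gene dosage signal-to-noise ratio
(measured on the generator); median-library scaling keeps typical entries
near the linear part of log1p.

## CNV inference and malignancy calling

Per gene, the residual of normalized expression against the reference-cell
mean (stromal + immune cells) is clipped at ±3 and averaged over a
101-gene genomic window by default (51 on the synthetic ~90-gene
chromosomes) that never crosses a chromosome boundary; each cell's track is
then median-centred.  Summary statistics follow the Tirosh/Puram practice:
a CNV score (mean squared smoothed dosage) and a CNV correlation (Pearson
correlation with the mean track of the top 5% of cells by score).

Calling offers two modes.  The classic `threshold` rule — malignant iff
score > mean_ref + 2·SD_ref AND correlation > 0.3 — is retained and
configurable, but at desk scale it is ineffective: with ~45-gene arms and
~3000 UMI the matched-filter information bound for a two-arm 1.5x clone is
d' ≈ 3 per cell, while the mean-square score carries only z ≈ 1.5.  The
default `mixture` mode therefore operates near that bound: an aberration
template is seeded from the top-score query cells, refined once (template =
mean track of candidate tumour cells minus the query mean, masked to its
strongest 15% of positions), each cell's track is projected onto the
template, and the projection is standardized against the reference cells'
empirical null, giving an approximate z-score under the no-CNV hypothesis.
A two-component mixture with the null component pinned at N(0, 1) is fitted
to the query statistics by EM; no cell is called when the aberrant
component's mean falls below 2 null SDs (guarding aberration-free data),
and otherwise the threshold averages the 1D k-means midpoint with half the
aberrant-component mean — the two estimators fail in opposite prevalence
regimes (k-means overshoots when most cells are malignant, the pinned
mixture undershoots when few are).  At the study conditions this yields
mean sensitivity ≈ 0.93 and specificity ≈ 0.91 over seed sweeps, close to
the per-cell Bayes limit; on aberration-free data no cells are called.
Cluster-level calling could exceed the per-cell limit but is out of scope.

## Consensus NMF

Per sample, log-CPM is z-scored per gene and negatives are clipped to zero;
multiplicative-update NMF (squared Frobenius objective, per-iteration error
guaranteed non-increasing, tolerance on the relative error change) is run
from many seeded restarts.  Initialization draws random uniform usages and
solves one clipped least-squares step for the initial spectra — a choice
made so the algorithm is exactly equivariant under gene permutation.
Pooled unit-L1 spectra are density-filtered (components whose mean distance
to their k−1 nearest neighbours exceeds the 0.9 quantile are dropped),
grouped into k clusters by k-means on the 1−Pearson embedding, and each
cluster's element-wise median becomes a consensus spectrum; usages are
refit by per-cell NNLS.  Stability is the mean silhouette of the component
grouping; rank selection computes stability and relative reconstruction
error for each k in 4–10 and picks the most stable rank among those within
5% of the best error (ties to the larger k; pure noise falls back to the
range minimum).  Reconstruction error decreases monotonically in k, so a
"largest k above a stability floor" rule systematically overshoots — the
max-stability form was adopted instead after measuring that overshoot.

Defaults: 20 restarts for the final consensus; the pipeline profile runs
the rank scan with 8 restarts at a looser tolerance (3e-4) and the final
consensus at 200 iterations / 1e-4 (500 / 1e-5 in the library default) —
the scan needs only the stability ordering, not fully converged spectra.

Top-gene signatures are *not* read off the z-space spectra: the z-scoring
distorts the gene ranking (it divides out per-gene scale).  Instead each
program is re-expressed as gene scores `cov(log-CPM expression,
standardized usage)` across the sample's cells — the ranking that matches
an oracle ranking computed from the true planted usages (Jaccard 0.85–0.96
at the study conditions versus ~0.5 for spectra-weight rankings).

## Meta-programs

Programs from two independent consensus decompositions per sample (the
full-restart consensus and a half-restart replicate) feed the recurrence
filter: a program is kept when a program from the other decomposition of
the same sample shares strictly more than 50% of its top-50 genes.
Survivors are hierarchically clustered (average linkage) on 1−Pearson
correlation of their unit-L1 gene-score vectors restricted to the union of
top-50 sets (whole-genome weight vectors are noise-dominated); the tree is
cut at correlation 0.3.  A cluster becomes a meta-program when it spans at
least max(ceil(0.2·n_samples), 3) distinct samples — the 20%-sharing rule
and the three-case floor combined by maximum.  The MP signature averages
the members' unit-L1 gene-score vectors (equal weight per program, so
sample scale does not leak in) and takes the top 50 genes, ties broken by
gene identifier for reproducibility.

## Scoring

`ucell_score` is the capped Mann-Whitney U statistic: genes ranked by
descending expression with average ties, ranks beyond 1500 (and missing
signature genes) set to 1501, U' = Σ ranks − n(n+1)/2, score = max(0, 1 −
U'/(n·1500)).  It is invariant under monotone transforms of a cell's
expression and lives in [0, 1].  State assignment is argmax with a score
floor (default 0.2) and an optional winning margin; ties are unassigned.
`ssgsea_score` ranks genes by descending expression and accumulates the
difference between a rank-weighted in-set ECDF (weight (N−i+1)^0.25 at
position i) and the uniform out-set ECDF; matrix scoring min-max normalizes
across samples.  The DE filter is a two-sided Wilcoxon rank-sum per gene
(exact null for small tie-free groups, tie-corrected normal otherwise) with
Benjamini-Hochberg adjustment; survivors need p_adj < 0.05, log2 fold
change > 1.2 and detection-fraction difference d > 0.4.  The fold-change
threshold is read literally in log2 units (≈2.3-fold) and is configurable,
since the convention "1.2" is ambiguous between log2FC and FC in the wild.

## Ligand-receptor testing

The interaction statistic is the CellPhoneDB convention: ligand summary =
min over ligand subunits of mean normalized expression in sender cells
(a complex is as strong as its limiting subunit), receptor summary
analogous, statistic = their average, zeroed when either molecule is
detected in under 10% of its state's cells.  The null shuffles state labels
— one shared shuffle per round across all pairs, preserving the cross-pair
correlation structure — with add-one p-values p = (1 + #{perm ≥ obs}) /
(n_perm + 1), so p is never exactly zero.  Because the shared shuffles
correlate tests within a run, marginal calibration is validated on many
small independent datasets rather than one large correlated batch.
Selection keeps pairs with p < 0.01, ranks by the mean statistic
(descending, ties by pair id) and truncates to 100.  The "weighted average"
ranking used by some tools is not further specified anywhere authoritative;
the plain mean is used.

## Ecosystem statistics

Bulk deconvolution solves per-sample NNLS against a gene x state signature
matrix and renormalizes onto the simplex (an all-zero solution falls back
to uniform, flagged).  This is a deliberate simplification of
support-vector-regression deconvolution; the contract — bulk + signatures →
simplex proportions — is preserved.  Spearman correlation uses average-tie
ranks with an exact permutation p for n ≤ 9 and the t approximation above.
Stage comparisons are Kruskal-Wallis (tie-corrected) gatekeeping Dunn
post-hoc z-tests with BH adjustment: the pairwise table is only computed
when the omnibus p < α.  Survival uses the product-limit estimator and the
two-group log-rank test (hypergeometric variance, 1 df); the optimal
cutpoint scans distinct score values between the 10% and 90% quantiles and
maximizes the absolute standardized log-rank statistic.  The selected-
cutpoint p-value is reported uncorrected but flagged anti-conservative —
the package demonstrates the anti-conservatism in its test suite rather
than hiding it.

## Pipeline and determinism

Stages run in fixed order (simulate → qc → cnv → nmf → metaprograms →
scoring → lr → ecosystem); each stage's seed derives from the global seed
by a stable hash of the stage name, so stochastic stages are isolated and
two runs with an identical configuration are bit-identical (checked by
hashing every artifact into a run manifest).  A stage missing its upstream
artifact fails with an error naming the stage to run first.

## Validation scales

The acceptance computations use: 10-seed pipeline sweeps at the study
conditions for MP recovery and the anti-correlation sign structure; 10
seeds x 5 samples for rank selection (the rank-selection experiment runs
on truth-labelled malignant cells so that it measures select_k itself,
not the compounded CNV-calling error); 5 seeds at 30% malignant fraction for
CNV calling; 200 independent null datasets (n_perm = 1000) for
ligand-receptor calibration; 1000 replicates for the Kruskal-Wallis and
log-rank null rejection rates (log-rank at 100 subjects per replicate,
where the asymptotic chi-square reference is accurate); 50 noisy bulk
samples for deconvolution.  The determinism check runs the full
eight-stage pipeline twice on a reduced configuration (4 samples x 220
cells x 1200 genes) — determinism is a structural property and does not
depend on problem size.

## Known limitations

- The CNV caller is per-cell; it does not segment, infer allele-specific
  states, or pool evidence across cells, and its accuracy at desk scale
  sits close to the information bound rather than comfortably above it.
- Consensus NMF assumes the preprocessed data are well approximated by a
  small non-negative rank; strongly overlapping programs merge.
- The recurrence filter needs two decompositions per sample; with one it
  passes programs through with a warning.
- ssGSEA implements the rank-weighted running sum only, not the full KCDF
  estimator family.
- The survival layer covers two-group comparisons; no Cox regression or
  multivariable modelling.
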
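# Methods

This note documents the models, defaults and numerical choices behind
`plaquenet`, and what the synthetic benchmarks do and do not demonstrate.

## Synthetic single-cell model

Counts are gamma–Poisson (negative binomial): gene `g` in cell `c` draws
`x_gc ~ NB(mean = L_c · p_g(c), size = θ)`. Relative abundances `p_g(c)`
renormalize log-normal baseline means `λ_g ~ LogNormal(μ0=0, σ0=1)` after
multiplying the cell's type-marker and subcluster-marker genes by the marker
fold `φ` (default 4) and a per-donor log-normal factor (sd 0.1 on the log
scale, so composition tests see realistic donor clumping). No zero inflation
is added: at Smart-Seq2 depth (library sizes `L_c ~ LogNormal`, median 200k
reads, log-sd 0.35) the NB zero mass is already adequate for deep full-length
data; this is the simplest model consistent with such libraries.

Planted structure and artifacts:

* **Types and subclusters.** Five FACS-style major types (SMC 42%, MP 36%,
  EC 12%, T 6%, pericyte 4%) with 5/4/3/1/1 subclusters of linearly
  decreasing size. Each type carries 10 shared marker genes (the first named
  after canonical panels: MYH11/ACTA2/ACTC1, PECAM1/VWF/CLDN5, PTPRC/CD68,
  CD3E, PDGFRB/RGS5, so panel annotation works exactly as on real data) and
  each subcluster 30 disjoint markers. Defaults give 3,000 cells and 3,000
  endogenous genes — a deliberately scaled-down cohort whose smallest
  subcluster (~85 cells) matches the smallest subclusters real plaque
  studies report.
* **Sex.** Cell sex is Bernoulli(π_k) per subcluster; the default π pattern
  cycles (0.15, 0.85, 0.5, 0.2, 0.8), planting both strong biases
  (|π−0.5| ≥ 0.3) and true negatives. Donors: 7 female, 8 male.
* **QC failures.** Doublets (3%) are *sums* of two profiles whose component
  libraries are truncated high, so their totals exceed the 750k ceiling by
  construction; debris (2%) draws libraries uniformly in 5k–40k; dead cells
  (3%) have mitochondrial mass reassigned until the mito fraction lands in
  0.10–0.30. 92 ERCC spike-in genes receive a noisy ~3% per-cell fraction;
  13 mitochondrial genes carry ~4% of endogenous mass in healthy cells.
* **GRNs.** Twelve networks of 100 genes. Sex-biased subclusters are paired
  with networks in order; a paired network receives ⌈ρ·30⌉ of its partner's
  markers (ρ = 0.8 default) and fills up from the remaining endogenous pool,
  so at ρ = 0 the marker overlap is purely hypergeometric. Key drivers are
  the five top-out-degree hub nodes with ranks 1–5; in a paired network the
  rank-1 driver is a partner marker gene and is planted as a progression
  trend gene for the partner's dominant sex.
* **Phenotypes.** Each network has a per-sample latent factor; member genes
  load on it with per-gene loadings drawn once from U(0.4, 0.95) (stored in
  the truth, so independent cohorts share the same heterogeneous correlation
  structure — a module with *flat* correlations would have no recognizable
  cor.cor signature). Phenotypes are `y = Σ β_m f_m + ε`; defaults plant
  β = 1.5 on GRN1 for SYNTAX and β = 1.2 on GRN3 for Duke, with BMI null.
* **Mouse course.** Stages baseline/early/advanced with the group sizes
  8 (2 F, 6 M) / 18 (6 F, 12 M) / 20 (10 F, 10 M). Planted trend genes rise
  by δ = 1 noise-sd per stage in the target sex only; everything else is flat
  i.i.d. Gaussian.

What the generator does **not** emulate: read-level noise, FACS gating
artifacts, batch or plate effects, cell-cycle structure, ambient RNA,
cross-type transitional continua, and donor-level composition variation
beyond the multiplicative expression factor. Passing recovery tests therefore
demonstrates the pipeline's statistical machinery under its stated model, not
robustness to every artifact of real plaque data.

## Single-cell pipeline

Stage order is fixed (cells first, then genes) and documented rather than
commutative-by-construction. Boundary semantics: libraries at *exactly*
50,000 reads are removed (low ≤ 50k), as are ≥ 750k, mito ≥ 10% and spike
≥ 10%. Genes detected in < 3 cells or with cumulative count < 300 are
dropped (boundary 3/300 kept). Normalization is `ln(1 + 10⁴·x/L_c)` with
spike-ins excluded from `L_c` and dropped.

Feature selection bins genes into 20 equal-width bins of mean log-expression
and z-scores the dispersion (variance/mean) within bins; ties break
lexicographically by gene id. PCA centers and unit-scales genes, clips
z-values to ±10, uses a randomized SVD with fixed seed, and fixes signs so
each component's largest-magnitude loading is positive. Clustering builds a
Euclidean KNN graph (k = 20), re-weights edges by shared-nearest-neighbor
Jaccard similarity, prunes weights below 1/15, and maximizes
resolution-scaled modularity (Leiden, resolution 0.8, fixed seed);
cluster ids are relabeled by decreasing size. The number of PCs (50), k, and
resolution are explicit conventional defaults, exposed in `RunConfig` — they
are choices, not reproductions of any particular study's settings.

Annotation z-scores cluster-mean expression across clusters and assigns each
cluster the panel with the highest mean z; a top score below zero, or a
top-two gap under 1e-6, yields "unassigned".

## Markers

The rank-sum test uses the exact null when the pooled size is ≤ 12 with no
ties, otherwise the normal approximation with midranks, tie correction and
continuity correction. Fold change de-logs the group means
(`mean(exp(v) − 1)`) with pseudocount 1e-9 before log2 — the estimator is a
package choice, configurable, since "fold change" on log-normalized data is
underdetermined. Bonferroni m is the number of genes entering that
subcluster's test after QC. Significance: log2fc > 0.3 and Bonferroni
P < 0.005; down-regulated genes are reported with direction "down".

## Composition

Expected counts are (row total)(column total)/(grand total) — the standard
contingency construction. Per-subcluster bias uses one-vs-rest 2×2 tables
within the subcluster's own compartment; the compartment-level omnibus
chi-square is also reported, since printed per-cluster p-values in the
literature rarely state which contrast produced them. No continuity
correction by default (Yates available for 2×2). Percentages round
half-to-even to integers. A vectorized Monte-Carlo helper
(`null_rejection_rate`) checks type-I calibration of the one-vs-rest test.

## GRN integration

The enrichment universe is (genes expressed after QC) ∩ (union of network
genes) — conservative, since genes outside both can never contribute to an
overlap. BH runs jointly over all (set, network) pairs; 10% FDR flags
significance. Cell-type attribution assigns each network gene to the major
type with maximal cluster-mean z-scored expression, with z < 0.25 or absence
mapping to "ND"; 0.25 is the package's explicit operationalization of an
otherwise undefined "not determined" rule.

Network–phenotype association computes per-gene Pearson r with its exact
t-test, then aggregates member-gene p-values into one network-level p. The
default aggregator is **min-p with Šidák correction**
(`1 − (1 − p_min)^m`): member genes of a co-expression module are strongly
positively correlated, and measured on this generator's all-null condition
Fisher's combined statistic (which assumes independence) pushed ~17% of
networks below q = 0.05 while min-p/Šidák stayed calibrated (and still
saturates the score cap on planted signals). Fisher and Stouffer remain
available through `assoc_aggregation`. Scores are `min(100, −log10 q)` with
BH across the network collection per phenotype.

Key-driver prioritization ranks a network's drivers on three criteria —
the driver's own hierarchical network rank, −log10 p of target-sex-up
differential expression (zero unless upregulated in the target sex), and
−log10 of the one-sided increasing Spearman trend p in the target sex of the
staged course — and averages the three criterion ranks (unweighted; ties
break by network rank). Drivers missing from any evidence source are
reported "ND" and sort last.

## Network validation

Preservation implements four statistics — avg.cor (mean |pairwise r| in
test), cor.cor (Pearson r between vectorized off-diagonal discovery and test
correlation matrices), cor.degree (correlation of within-module weighted
degrees) and avg.contrib (mean |gene-to-summary r|, the summary being the
sign-aligned first principal component) — rather than a larger battery;
"preserved" requires *all* statistics permutation-significant, the
conservative rule. The null draws random same-size gene sets from the test
data's non-module genes; p-values carry the +1 correction, so 199
permutations bound p at 1/200.

Connectivity change compares the multiset of within-module pairwise
correlations between a condition and the control with an unadjusted
two-sided t-test. The GSEA ranking statistic is a Welch t on log2(CPM+1)
(condition minus control); the enrichment score is the classic weighted
(exponent 1) running sum, the null permutes gene labels (replicate counts of
perturbation experiments are far too small for sample permutation), NES
divides by the mean |permuted ES| of the same sign, and the p-value
conditions on the observed sign — the convention that keeps null p-values
uniform.

## Problem sizes and determinism

The default benchmark runs 3,000 cells × ~3,100 genes, 12 networks, 200
discovery and 200 test bulk samples, 199 preservation permutations, 100
random-module calibration draws, 100 perturbation power simulations and
1,000 composition null resamples — sizes chosen so the whole study runs in
about two minutes on one CPU while every planted effect remains comfortably
detectable. Every random stage derives its seed from the single run seed
salted with the stage name, so stages are reproducible in isolation and
whole runs are byte-identical under a fixed seed.

## Known limitations

* The reference contingency tables pool unreported subclusters into a
  "rest" row; one-vs-rest tests of the reported subclusters are exact, but
  per-subcluster results for the pooled ones are unavailable.
* Marker fold change with the 1e-9 pseudocount can be large for genes
  detected in essentially one group; the Bonferroni p gate, not the fold
  gate, is what controls false markers.
* GSEA requires at least two set genes in the ranking; singleton sets are
  rejected rather than scored.
* The phenotype-association score caps at 100, so rankings among saturated
  networks are not meaningful beyond the cap.
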
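# Methods

## Model and procedure

The pipeline treats a gene's expression change between tumor and
normal tissue as *epigenetically driven* when it co-occurs with an
opposite-signed promoter methylation change and the two layers are
negatively rank-correlated across samples. Stages:

1. **Promoter methylation.** A gene's promoter is the window
   [TSS − 800, TSS + 200] on the plus strand, mirrored on the minus
   strand (coordinates 1-based inclusive; strandedness is a flag,
   stranded by default). A probe belongs to every promoter window that
   contains it — overlapping promoters share probes rather than
   forcing an arbitrary tie-break. The gene-level promoter beta is the
   unweighted mean of its mapped probes. "Empty" probes are removed on
   two counts, logged separately: missing values beyond a threshold
   (default: any) and mapping to no promoter. Expression input may be
   declared TPM (used as-is) or FPKM (rescaled so each sample sums to
   10^6).
2. **Differential screens.** Unpaired two-sided Wilcoxon rank-sum
   tests per gene. The exact permutation distribution (midranks; the
   two-sided p is the probability of a U statistic at least as far
   from n₁n₂/2 as observed) is enumerated whenever both groups have
   ≤ 10 observations, ties included; larger samples use the normal
   approximation with tie and continuity corrections. Expression calls
   require |log2 FC| > 1 (strict) with log2 FC computed on
   pseudocounted group means, log2((mean_T + 1)/(mean_N + 1)), and
   Benjamini–Hochberg q < 0.05. Methylation calls use raw p < 0.05
   signed by Δβ = mean_T − mean_N, with no effect-size threshold.
   Although the simulated samples are paired, the tests are unpaired
   by design (a paired option is deliberately out of scope); pairing
   is recorded in the sample sheet for provenance.
3. **EI/ES classes.** EI = expression up & methylation down;
   ES = expression down & methylation up; everything else (including
   genes absent from either screen) is unclassified. Candidates are
   kept only if Spearman rho between promoter beta and expression,
   pooled over all tumor + normal samples, is strictly negative (the
   threshold is configurable; no significance cut on rho by default).
4. **Neighborhood enrichment.** For each candidate g with degree
   a + b in the interaction network (a = EI/ES neighbors, b = others;
   g never counts as its own neighbor), the one-sided Fisher exact
   p-value is the upper hypergeometric tail P(X ≥ a) with population
   N = all network genes, K = EI/ES genes present in the network, and
   a + b draws. K and N are computed from the data, never hard-coded.
   q-values are BH over all tested genes (Bonferroni selectable).
   Drivers: q < 0.05 and a/(a+b) > 0.10, both strict.
5. **Clinical validation.** Staining scores 1–2 map to marker-low,
   3–4 to marker-high (a quantile rule is available for continuous
   scores; ties at the cut go low). Association uses the Pearson 2×2
   chi-square with df = 1; the continuity correction is an explicit
   per-analysis argument rather than a global policy, with no
   correction as the default. Survival comparison uses Kaplan–Meier
   curves and the two-group log-rank test. Cox models maximize the
   partial likelihood with Efron tie handling; the multivariate model
   includes covariates whose univariate p < 0.05 (configurable).
   ROC AUC is the tie-adjusted Mann–Whitney probability.

## Numerical choices

- `fisher_enrichment_tail` accumulates the hypergeometric pmf by
  log-gamma factorials with a multiplicative recurrence for the tail
  sum (exact rational ratios evaluated in double precision); a
  log-sum-exp fallback covers pmf underflow below e⁻⁶⁰⁰. Agreement
  with exact rational enumeration over all margins with N ≤ 60 is
  within 1.5e-13 relative error.
- All threshold comparisons are strict inequalities (> 1, < 0.05,
  > 10%), so values exactly at a boundary are never called.
- Degree-zero test genes get proportion 0 and p = 1, flagged rather
  than dropped. Constant vectors have undefined Spearman rho, reported
  as missing and failing the negativity filter.
- BH adjustment is the standard step-up with cumulative minimum,
  clipped at 1; q ≥ p elementwise and the q-set is invariant to input
  order. (BH is not idempotent for general inputs and the package does
  not claim it.)

## Synthetic-data generator

The generator's defaults are the study conditions the analysis
assumes; they are fixed once and are not tuning knobs.

- **Cohort geometry.** 41 tumor/normal pairs; 2,000 genes with 1–5
  CpG probes each placed uniformly inside the gene's promoter window;
  100 planted EI and 50 planted ES genes.
- **Expression.** Log-normal per gene: baseline log2 level uniform on
  [3, 8], noise sd 0.5 (log2). Planted genes shift tumor means by
  ±`expr_effect` (default 2) on the log2 scale. Matches the positive
  skew of TPM data.
- **Methylation.** Logit-normal probes around a gene-level promoter
  mean (logit-scale sd 0.4, probe offset sd 0.15). Planted genes shift
  the tumor promoter mean by ∓`meth_effect` (default 0.3) on the beta
  scale; planted baselines are drawn from ranges that keep shifted
  means inside (0, 1), and configurations that cannot are rejected.
- **Coupling.** Planted genes share a per-sample standard-normal
  latent factor entering expression with weight +c and methylation
  with weight −c (c = 0.8), producing the negative Spearman
  correlation the filter selects on; null genes get independent noise.
- **Network.** Preferential attachment (Barabási–Albert) with 10,000
  nodes and m = 10, giving a heavy-tailed degree distribution with
  mean degree ≈ 20 and an EI/ES background fraction of ≈ 1.5% — a
  scaled-down version of the curated human interactome regime the
  analysis targets (≈17k nodes, ≈19.6 mean neighbors, ≈1.2%
  background). Node labels are permuted so planted genes are not
  systematically hubs. Each of the 4 planted drivers (drawn among
  EI/ES genes) has a fraction `driver_wiring` (default 0.5) of its
  neighbors rewired to EI/ES nodes, preserving degree and simplicity.
- **Cohort.** 160 patients, marker-high prevalence 0.6, staining
  scores uniform within the marker class. Event times are exponential
  with baseline median 48 months and hazard multiplied by
  exp(`marker_log_hr`) (default log 4.465) for marker-high; censoring
  is independent uniform on [0, 120] months. Late TNM stage is
  Bernoulli with base log-odds −2.75 shifted by +2.3 for marker-high
  patients; the other binary covariates use marginal frequencies
  typical of a resected liver-cancer cohort and are independent of the
  marker.
- **Determinism.** Every draw flows from `numpy.random.default_rng`
  seeded from the config (omics at seed, network at seed+1, cohort at
  seed+2), so identical configs reproduce byte-identical outputs.

What the generator does **not** emulate: array chemistry and probe
cross-reactivity, batch and purity effects, read-level counts,
copy-number or mutational confounding of expression, non-proportional
hazards, and informative censoring. Passing recovery tests therefore
show that the statistical machinery is correct under the assumed
generative structure, not that the pipeline is robust to real-data
artifacts.

## Problem sizes in the test and acceptance runs

Recovery and calibration experiments use 3 seeds of the full omics
simulation (2,000 genes × 82 samples), 20 seeds of the network
simulation, 20 simulated cohorts of n = 500 for Cox recovery (with
light censoring, horizon 360 months), and 300 null cohorts of n = 80
for log-rank calibration. These sizes give binomial/Monte-Carlo noise
well inside the asserted margins while keeping the default suite in
the minutes range.

## File formats

- **Matrices**: TSV, header row of sample ids, first column row ids
  (genes or probes). Betas in [0, 1]; expression non-negative.
- **Samples file**: TSV `sample`, `group` (`tumor`/`normal`),
  optional `pair`. Alternatively sample ids ending `_T`/`_N`.
- **Probe annotation**: TSV `probe_id`, `chromosome`, `position`
  (1-based). **Gene models**: TSV `gene_id`, `chromosome`, `tss`
  (1-based), `strand` (`+`/`-`).
- **Edge list**: TSV, first two columns gene symbols, extra columns
  ignored (HIPPIE dialect); undirected, deduplicated, self-loops
  dropped.
- **Clinical CSV** columns: `patient_id`, `staining_score` (1–4),
  binary covariates `age_gt55`, `male`, `hbv`, `alt_gt35`, `ast_gt31`,
  `tb_gt12`, `alb_gt40`, `tnm_late`, `tumor_gt5cm`, plus `time`
  (months) and `event` (1 = death).

## Known limitations

- The published staining-cohort total-bilirubin row is internally
  inconsistent (its printed stratum counts do not sum to the printed
  total), so that association is not part of the frozen checks.
- Real-cohort gene counts (thousands of differential genes, the exact
  EI/ES set sizes) depend on the original consortium matrices and are
  represented here by recovery properties on synthetic data instead.
- The multivariate Cox covariate screen is a simple univariate p
  filter; no shrinkage, interaction terms or proportional-hazards
  diagnostics are provided.
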
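# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the places where the design was genuinely open.

## Paired negative-binomial enrichment model

Counts for gene *g* in sample *s* are modelled NB(μ_gs, φ_g) with
Var = μ + φμ².  For one factor with R replicate pairs the design has R
replicate-block coefficients plus a single IP-role coefficient β_g; the
offset is the log effective library size.  The paired blocks absorb
culture-to-culture abundance differences, so β_g is the within-pair
log-enrichment; LFC_g = β_g/ln 2.

- **Normalization.**  TMM: each sample's factor is a precision-weighted
  trimmed mean of per-gene log-ratios against a reference column (the one
  whose log raw library size is closest to the mean), trimming the extreme
  30 % of M-values and 5 % of A-values; factors are rescaled to zero log
  sum.  Effective library size = raw column sum × factor.  TMM assumes the
  majority of genes are unenriched: a shift planted on *every* gene is
  absorbed into the factors (each factor's LFCs are identifiable only up to
  a common constant).  Recovery tests therefore either plant effects on
  minorities or compare within-factor-centered values.
- **Dispersion.**  The common φ maximizes the Cox–Reid adjusted profile
  likelihood (per-gene GLM refit at each candidate φ, penalty
  −½log|XᵀWX|) summed over genes and factors, searched on log₁₀φ ∈ [−6, 1]
  (bounded scalar minimization, tolerance 0.01 on the log scale; estimates
  below 2×10⁻⁶ are reported as exactly 0, the Poisson limit).  Per-gene
  maximizers on a 15-point log-spaced grid are shrunk toward the common
  value by residual degrees of freedom against a prior weight
  (`prior_df`, default 10):  φ_tag = (df·φ_g + prior_df·φ_common)/(df +
  prior_df), clipped to [0, 10].  As prior_df → ∞ every gene uses the
  common value.  This is a deliberately simple moderation; the weighted
  empirical-Bayes machinery of the R differential-expression stacks is out
  of scope, and equivalence is asserted at the calibration/recovery level
  (null p-values uniform, known φ recovered within [0.15, 0.25] at truth
  0.2), not at coefficient identity.
- **Testing.**  Likelihood-ratio test of β_g against the reduced
  (blocks-only) model, p from χ²(1), BH within factor.  Genes with mean
  count below 1 across all samples are excluded from fitting and testing
  (LFC = NA) — a floor that avoids degenerate fits; the scientific filter
  is applied later.  Under null simulations at the study scale the
  statistic is well calibrated (mean ≈ 0.99, rejection at nominal 0.05 ≈
  0.050); a residual caveat is that the χ² approximation, not an exact
  test, is used, so single-seed Kolmogorov–Smirnov checks inherit ordinary
  sampling variability.
- **IRLS.**  One design matrix shared by all genes lets the per-gene
  weighted least-squares systems be solved batched (einsum +
  `numpy.linalg.solve`); step-halving guards against deviance increases;
  linear predictors are clipped at ±40.

## Filtering and clustering

A transcript enters the universe iff FDR < 0.01 in ≥ 1 factor (either
direction) **and** its raw count strictly exceeds 20 in *every*
total-extract sample (the count clause is applied across all factors —
the conservative reading).  Universe order is the input gene order.

The LFC matrix uses 0 (no enrichment) for universe genes untested in some
factor.  Experiment similarity is Pearson R over all universe genes (R²
reported, D = 1 − R).  UPGMA is average linkage (scipy); leaf order puts
the subtree containing the smaller original index first; Newick export
uses half-height branch lengths so leaf-to-leaf path lengths equal
cophenetic distances.  k-means runs Lloyd's algorithm with k-means++ on
raw (unscaled) LFC rows, best of `n_starts` = 50 by inertia, fixed seed;
centers are recomputed as member means; cluster IDs 1..k follow the UPGMA
leaf order of the centers under 1 − Pearson distance, making "cluster 3"
reproducible across runs.  Whether to scale rows was open; raw rows are
the default of the heatmap tooling this mirrors, and scaling is trivially
applied by the caller if wanted.  `choose_k_diagnostics` reports inertia
and mean silhouette per k and deliberately selects nothing: the original
criterion is visual.

## Property comparisons

Cluster vs **all genes** (members included — one-vs-all, matching the
"all mRNA" reference category of the field's figures), two-sided
Mann–Whitney U.  Exact enumeration when n₁·n₂ ≤ 400 and the data are
tie-free, otherwise the normal approximation with continuity and midrank
tie correction; fully tied data returns U = n₁n₂/2, p = 1.  BH is applied
jointly across every (cluster × property) test of a run; stars at adjusted
0.05/0.01/0.001.  Boxes use linearly interpolated quartiles (position
1 + (n−1)q) and notch = median ± 1.58·IQR/√n.  Because the reference
includes the tested cluster, the null rejection rate is if anything
conservative; the tests verify ≤ nominal.

5′UTR adenosine: per-gene A fraction (zero-length UTRs excluded), and a
positional profile anchored at the start codon (position −1 = base
immediately 5′ of AUG), per cluster: enrichment(p) = f_cluster(p)/f_all(p),
reported missing when fewer than `min_coverage` = 25 UTRs span the
position or f_all = 0.  The ratio form and the start-codon anchoring are a
reconstruction — the source analysis never prints its formula — and are
flagged as such.

## tRNA adaptation index

Absolute adaptiveness W_c = Σ over pairings (1 − s)·tGCN with one wobble
partner per codon box (codon ··U ← anticodon G·· with s_G:U; ··C ← A··
(inosine) s_I:C; ··A ← A·· s_I:A; ··G ← U·· s_U:G; Watson–Crick s = 0).
Default penalties are the canonical published wobble values (0.41, 0.28,
0.9999, 0.68), configurable from file.  w = W/max W; codons with no tRNA
get the geometric mean of the nonzero weights.  Gene score = geometric
mean of w over CDS codons with start and stop excluded; a CDS with nothing
between start and stop is an error rather than NaN.  "Classical TE" is
exposed as an alias of the gene tAI: codon usage enters through each
gene's own composition, and no additional usage weighting is applied —
this identification is a documented choice, since the combining formula is
not restated in the source.  Initiator-specific tRNA handling (e.g. the
Ile AUA special case) is not modelled.

## Set overlaps

Pairwise: exact hypergeometric upper tail P(X ≥ x) (scipy's survival
function; verified against full enumeration for every N ≤ 12 grid point to
1e-10).  Multi-way: the null resamples *every* set uniformly without
replacement at its observed size — the open question of conditioning on
one observed set is resolved to the all-random variant, which agrees with
the conditional one under exchangeability and is verifiable by
enumeration.  It is realized by chained hypergeometric draws
(m₁ = |A₁|; m_{j+1} ~ HG(N, m_j, |A_{j+1}|)), distributionally identical
to explicit sampling and vectorizable to 10⁶ draws in milliseconds.
p = (hits + 1)/(draws + 1) keeps p > 0; the binomial standard error is
reported.  Term over-representation filters terms to 3–2000 universe
genes, BH per query set, and exports the dot-plot quantities
(enrichment ratio, adjusted p).  The PaxDB-style protein-fraction
aggregate is a plain per-cluster sum of the supplied column.

## Synthetic data: what it emulates and what it does not

`generate_truth` plants k cluster centers over factors as ternary
{−sep, 0, +sep} patterns (rejecting all-zero rows and rows closer than
`sep`, so every cluster is FDR-detectable; with sep = 0 — the null
configuration — all centers are zero and the pairwise-distinct invariant
is deliberately relaxed).  Per-gene LFC adds N(0, gene_noise_sd) in log2
space.  Baselines are lognormal.  Counts: total ~ NB(lib·baseline, φ),
IP ~ NB(lib·baseline·2^LFC, φ).  Defaults — 2000 genes, 12 factors, 3
replicate pairs, k = 7, separation 2, noise SD 0.3, φ = 0.1, mean count
200 — mirror the 12-dataset triplicate study design at reduced gene count,
with effect sizes at the scale of strong RIP enrichments.  Replicate
variance components of the real data are unpublished, so these values are
chosen for testability, not fitted realism.

Not emulated: raw reads, alignment or positional coverage; mapping bias;
correlated replicates; sample contamination; any coupling between a
transcript's sequence and its counts.  Passing tests therefore demonstrate
that the *pipeline* recovers planted structure under its own model class,
not that the model captures every feature of real RIP-seq libraries.
Annotations draw yeast-like lognormal region lengths (5′UTR ≈ 60 nt, CDS ≈
1200 nt, 3′UTR ≈ 120 nt medians), CDSs are ATG + stop-free codons + stop,
and per-cluster 5′UTR composition (optionally windowed) plants
adenosine-rich cohorts.  Property tables draw lognormal/normal values with
per-cluster location shifts.  The tGCN table used by the pipeline stage is
synthetic (sparse Poisson copy numbers over anticodons), not any
organism's.

## Pipeline

Seven stages (simulate → enrich → filter → cluster → properties → tai →
overlap) run from one YAML config (pydantic-validated: defaults filled,
unknown keys rejected, referenced paths checked before anything runs).
Per-stage seeds derive from SHA-256 of (global seed, stage name), so any
stage reruns independently yet reproducibly; the manifest records SHA-256
checksums of every output, and identical config + seed reproduce
bit-identical checksums (timestamps are recorded but excluded from the
determinism contract).  A stage failure aborts the run naming the stage;
earlier outputs are retained.

## Problem sizes in the test suite

Unit tests run at a few hundred genes; the acceptance checks run the
study-scale configuration (2000 × 12 × 3, ~8 s per full pipeline pass) and
repeat it across five seeds, keeping the default suite around a minute on
one CPU.
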
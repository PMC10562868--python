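# ripcohort

Integrative analysis of RIP-seq experiments: which mRNAs does each
RNA-binding protein or translation factor bind, and how do those binding
profiles partition the transcriptome into functional cohorts?

RIP-seq (RNA immunoprecipitation sequencing) quantifies, for a tagged
RNA-binding factor, each transcript's abundance in the immunoprecipitate
relative to a matched total-RNA extract from the same culture.  `ripcohort`
implements the full downstream pipeline for a panel of such experiments —
in yeast-scale studies, typically a dozen factors spanning translation
initiation (eIF4E, eIF4G, Pab1, eIF4A, Ded1, eIF2, eIF3), repression
(Caf20, Eap1) and mRNA decay (Lsm1, Pat1) — together with a synthetic-data
generator that plants known structure so every stage is testable without
any external download.

## The model

**Enrichment.**  For each factor, replicate *r* contributes a paired
(IP, total) sample.  Counts are negative binomial,
Var(y) = μ + φμ², with

&nbsp;&nbsp;&nbsp;&nbsp;log μ = log(effective library size) + βᵣ + β·1[role = IP]

so β is the natural-log IP enrichment and LFC = β / ln 2 the log₂(IP/total)
fold change.  Effective library sizes come from TMM (trimmed mean of
M-values, 30 %/5 % trims); dispersions from the Cox–Reid adjusted profile
likelihood (a common value maximized over all genes, per-gene values shrunk
toward it); significance from a likelihood-ratio χ²(1) test of β with
Benjamini–Hochberg FDR within each factor.

**Cohorts.**  The analysis universe is every transcript significantly
enriched *or* depleted (FDR < 0.01) in at least one factor and covered by
more than 20 reads in every total-extract sample.  Over this universe the
gene × factor LFC matrix is built; experiments are related by Pearson R
(reported as R², with dissimilarity D = 1 − R fed to UPGMA); genes are
partitioned into k = 7 interaction-profile clusters by k-means
(k-means++, best of 50 starts), with cluster IDs ordered by the UPGMA leaf
order of the cluster centers so numbering is reproducible.

**Characterization.**  Each cluster's distribution of any per-gene property
(transcript/UTR/CDS length, half-life, ribosome occupancy, 5′UTR adenosine
content, …) is compared against the all-gene distribution with the
two-sided Mann–Whitney U test (exact for small tie-free samples), BH
corrected jointly; boxplot notches are median ± 1.58·IQR/√n.  Codon
optimality is the tRNA adaptation index: per-codon weights from tRNA gene
copy numbers with wobble penalties, gene score = geometric mean over the
CDS.  Gene-set overlaps use the exact hypergeometric upper tail (pairwise)
and Monte-Carlo resampling of all sets (multi-way), with term
over-representation for clusters against annotation lists.

## Worked example

```python
from ripcohort import *
from sklearn.metrics import adjusted_rand_score

truth = generate_truth(800, n_factors=6, k=4, center_separation=2.0,
                       gene_noise_sd=0.3, seed=11)
data = simulate_counts(truth, NBParams(dispersion=0.1, n_replicates=3), seed=12)
experiment = CountExperiment(counts=data.counts, samples=data.samples)

results = RIPEnrichment(experiment).fit()
print(results.summary())
universe = results.filter_universe(fdr_max=0.01, min_total_reads=20)
profile = build_lfc_matrix(results.results, universe)
model = ProfileClustering(profile, k=4, n_starts=50).fit(seed=0)
print(model.summary())
print(adjusted_rand_score(truth.cluster_labels.loc[universe], model.labels))
```

prints

```
Paired NB enrichment (IP vs total)
  genes: 800  samples: 36  factors: 6
  testable genes (floor): 800
  common dispersion: 0.09824  (prior df 10.0)
  factor      tested  FDR<0.01     up   down
  F01            800       535    229    306
  F02            800       539    236    303
  ...
k-means interaction-profile clustering (k=4, 50 starts, seed=0)
  genes: 790  factors: 6  inertia: 1202
  cluster sizes: 1: 199, 2: 197, 3: 196, 4: 198
  center tree: (((1:0.555,2:0.555):0.041,3:0.596):0.127,4:0.723);
1.0
```

The true simulation dispersion was 0.1 and is re-estimated at 0.098; 790 of
800 genes enter the universe (the rest fail the FDR or the >20-reads
filter); the adjusted Rand index of 1.0 says the planted 4-cluster
structure is recovered exactly, and the center tree shows clusters 1 and 2
(the most similar planted profiles) merging first.

The same stages run from the shell:

```bash
ripcohort simulate --outdir run/ --seed 3
ripcohort enrich --counts run/counts.tsv --samples run/samples.tsv --out run/
ripcohort cluster --lfc run/lfc_matrix.tsv --k 7 --seed 3 --out run/
ripcohort run-all --config cfg.yaml     # everything, with a manifest
```

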
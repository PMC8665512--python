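# Methods

`liveromics` implements a proteogenomic integration workflow for
multi-omics cohorts of noncancerous liver tissue: per-gene mRNA–protein
correlation with pathway-level enrichment, unsupervised proteomic
subgroup discovery, permutation-tested metabolic pathway activity,
differential methylation with a Gaussian-mixture classification of
methylation-attenuated proteins, and recurrence-free-survival
association. Because cohorts of this kind are typically request-only,
the package ships a first-class synthetic cohort generator that
reproduces the statistical structure the analyses assume, with full
ground truth, so every stage can be validated end to end.

## Synthetic cohort model

All abundances are on a log2 scale. For gene *g*, sample *i* in
subgroup *c*:

- methylation latent `z_ri = mu_r + d_rc + a_ri` per region *r*, with
  beta value `sigmoid(z)` (the logistic transform keeps beta in [0,1]);
  a fraction of regions (`dmr_region_fraction`, default 0.15) carries a
  subgroup shift `d_rc` (`meth_dmr_shift = 1.2` latent units, roughly a
  0.2–0.3 beta difference), providing true DMRs.
- mRNA: `mRNA_gi = b_g − k_g·(z_gi − mean_i z_gi) + e_gi` with baseline
  `b_g ~ N(8, 1.5²)` and noise `e_gi ~ N(0, 1)`. The methylation
  coefficient `k_g` is `meth_effect = 1` for attenuated genes and 0
  otherwise, so hypermethylation depresses the transcript of exactly
  the attenuated set.
- protein: `protein_gi = b_g + u_gc + w_g·s_gi + f_gi`, where `s_gi` is
  the mRNA signal component, `f_gi ~ N(0, 1)`, and `w_g > 0` only for
  the planted positively-correlated genes. `w_g` is chosen analytically
  from the target rank correlation via the bivariate-normal identity
  `rho_S = (6/π)·asin(rho_P/2)`; the default `target_rho_pos = 0.6`
  against a near-zero background mirrors the empirical picture in liver
  tissue where most genes are post-transcriptionally buffered and a
  metabolic subset is strongly coupled. The exact `rho_S = 1` limit with
  zero protein noise is handled as a direct copy.
- subgroup structure: each of the 3 subgroups has
  `n_active_pathways_per_subgroup = 2` active pathways whose member
  genes receive a protein mean shift of `subgroup_shift = 2` within-group
  SDs in that subgroup. This single mechanism produces both the
  clusterable heterogeneity and pathway activity scores above 1.
  Two further pathways draw their members from the planted correlated
  genes, giving the KS enrichment stage a true positive signal.
  The three planted gene sets (correlated, attenuated, active-pathway)
  are disjoint by construction — otherwise a gene could not
  simultaneously have near-zero background correlation and
  methylation-independent protein noise.
- missingness: protein entries are removed completely at random at
  `missing_rate_protein = 0.05` plus an extra 0.20 probability on the
  lowest abundance decile, emulating the intensity-dependent dropout of
  isobaric-label MS. The clinical table draws recurrence times from
  exponential distributions with per-subgroup hazards
  (0.02/0.09/0.03 events·month⁻¹ — the middle subgroup relapses early),
  exponential censoring (0.01 month⁻¹), and subgroup-dependent TNM/AFP/
  thrombus/phenotype frequencies skewed toward the third subgroup.

Defaults (77 samples, proportions 0.40/0.34/0.26, 2,000 genes, 2,500
regions, 20 pathways of 40 genes) are calibration choices for a
realistic desk-scale cohort, not estimates of any real dataset. The
generator does **not** emulate batch/plex effects, isoform ambiguity,
probe-level methylation noise, enhancer regulation, or tumor-tissue
profiles, so passing tests demonstrate correctness of the statistical
machinery under the stated generative model — not performance on real
TMT data.

## Stage-by-stage notes

**Preprocessing.** A protein is removed when missing in strictly more
than `max_missing_fraction` (default 0.5) of samples — at n = 77,
missing-in-39 is removed and missing-in-38 kept. Default imputation is
shifted-minimum (per-feature observed minimum − 1 log2 unit),
reflecting abundance-biased MS missingness; correlation-kNN (affine,
sign-aware, k = 5) is the alternative. Variable-feature selection keeps
`ceil(0.25·n)` features by MAD (robust to heavy-tailed TMT ratios),
ties broken lexicographically by feature ID.

**Correlation screen.** Per-gene Spearman correlation (rank-based,
robust to the different monotone distortions of RNA-seq and TMT) across
pairwise-complete samples; two-sided p via the t approximation; BH
across testable genes; "significant positive" = adjusted p < 0.01 and
rho > 0, with the count and one-decimal percentage reported. The screen
runs on the filtered but un-imputed matrix: imputed values carry no
pairing information and only attenuate the estimate. Pathway enrichment
is a two-sample KS test of member vs non-member correlations
(min 5 scored members), BH-adjusted, with direction from the mean
difference; discordant (significantly negative) genes feed the same
machinery.

**Subgroup discovery.** Features are z-scored; samples are compared by
1 − Spearman correlation; for each K, the cohort is subsampled at 80%
and partitioned by seeded k-medoids (Voronoi iteration, single random
init per resample) for `n_resamples` rounds; the consensus matrix is
the co-clustering frequency among co-sampled pairs, and final labels
cut an average-linkage tree of 1 − consensus. K is selected from the
consensus-CDF area curve: the area grows mechanically with K, so the
package takes the **largest K whose relative delta-area is at least
0.15**. A pure argmax over delta-areas was rejected because a stable
over-merged K = 2 solution always dominates it (on planted 3-group
cohorts argmax returned K = 2; the elbow rule returns K = 3 with
ARI 1.0). The single random initialisation per resample is deliberate:
it lets an over-merged K express its instability in the consensus
matrix.

**Differential expression.** Kruskal–Wallis (tie-corrected, chi-square
reference with K − 1 df), BH across features. With two groups the
statistic is algebraically identical to the tie-corrected Wilcoxon
rank-sum chi-square; the suite asserts this to 1e-10. The same code
path serves the three-subgroup heatmap, single-protein comparisons
(e.g. p62), and the thrombus two-group screen.

**Pathway activity score.** Relative abundance of gene *g* in sample
*i* is its linear-scale value over the gene's cohort mean; PAS of
pathway *j* in subgroup *c* is the mean over member genes of their mean
relative abundance within *c*. Log input is exponentiated first (ratios
of logs are meaningless). The size-weighted mean of PAS over subgroups
is exactly 1 per pathway, and PAS is invariant to rescaling any gene —
both asserted. Significance: B = 999 permutations of sample labels
(preserving gene covariance), two-sided around 1 with the add-one rule
`p = (1 + #{|PAS_b − 1| ≥ |PAS_obs − 1|})/(B + 1)`. The unweighted mean
is the tested default; no outlier trimming is applied.

**Methylation.** Regions on sex chromosomes are dropped (autosome-only
calls). DMR testing uses Kruskal–Wallis on M-values
(`log2(beta/(1−beta))`, beta clipped to [0.001, 0.999]), BH, plus a
0.1 minimum max-pairwise mean-beta difference. Annotation is
strand-aware on 0-based half-open intervals: promoter =
overlap with [TSS − 1500, TSS + 1500), taking precedence over gene body,
multi-gene hits resolved by nearest TSS; intergenic DMRs are counted
but not linked (no enhancer map in scope). The attenuation statistic is
`r(meth, protein) − r(meth, mRNA)` (Spearman, per gene over mean beta of
its promoter/gene-body DMRs) — positive when methylation's negative
effect reaches the transcript but not the protein, transporting the
CPTAC copy-number-attenuation construction to methylation. A
two-component 1-D Gaussian mixture is fitted by EM (extreme-quartile
mean init, tol 1e-8 on log-likelihood, ≤ 1,000 iterations,
log-likelihood asserted non-decreasing each step); the component with
the larger mean is the attenuated class, called at posterior ≥ 0.5
(MAP). Fits with component weight < 0.01 or sd < 1e-6 fall back to a
single component, flag the result, and call nothing attenuated. At
least 20 scores are required — the mixture is unidentifiable at toy
sizes.

**Survival.** Early relapse = event within 24 months; patients censored
earlier without an event are indeterminate and excluded from Fisher
proportion tests (the only choice that uses no unobserved information).
Kaplan–Meier and the K-group log-rank apply administrative censoring at
the horizon. The multivariable Cox model (lifelines, Efron ties —
months-resolution data guarantees ties) adjusts subgroup indicators for
TNM stage (ordinal I–IV), AFP and thrombus; monotone likelihood is
detected post-fit from exploding coefficients/standard errors and
raised as an error. The marker screen is three-staged: MI-vs-MA
rank-sum with BH, median-split log-rank (ties to the low group;
degenerate splits skipped), and covariate-adjusted Cox; a marker must
pass all three at the chosen alpha. The MI/MA phenotype is an input
annotation, not recomputed.

**Contingency tests.** 2×2 tables use the exact hypergeometric test;
R×C tables are enumerated exactly over all tables with the observed
margins when the grand total is ≤ 500 **and** the enumeration space is
below ~5·10⁵ candidate tables; otherwise a chi-square approximation is
used and flagged in the output (`method = "chi2_approx"`).

**Orchestration.** `run_pipeline` runs the stages in dependency order
from a YAML config, logging feature/sample counts at each step; one
global seed fans out to per-stage seeds by fixed offsets (+101
clustering, +202 PAS, +303 mixture) so stages are individually
reproducible; a missing methylation branch is skipped with a logged
reason while the remaining sections still run. Identical config and
seed produce byte-identical tables.

## Problem sizes used in validation

The shipped test-suite and the acceptance script exercise the pipeline
at desk scale: cohorts of 77–200 samples, 200–2,000 genes, up to 2,500
regions and 334 pathways; consensus clustering with 100–500 resamples;
permutation tests at B = 999. These sizes were chosen so the full
validation runs comfortably on a single CPU while keeping every power
check (clustering ARI, attenuation sensitivity/specificity, PAS
detection, log-rank power) well away from its threshold.

## Known limitations

- Gene identity is a single shared symbol namespace; isoform collapse
  and ID mapping are out of scope.
- The consensus-K elbow threshold (0.15 relative gain) is a heuristic;
  cohorts with genuinely ambiguous structure may need `K_fixed`.
- The exact R×C Fisher test is enumeration-based and therefore limited
  to small tables; larger tables use a flagged chi-square.
- The xCell-style microenvironment scores are simplified mean-z
  aggregates without spillover compensation.
- No batch correction or cross-plex normalisation is provided.
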
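# Methods

`exermap` re-implements, as a tested library, the statistical machinery of
a repeated-measures multi-omic acute-exercise study: per-feature
difference-in-changes mixed models, a simulation harness for choosing
among longitudinal modeling strategies, multi-layer set enrichment,
weighted co-expression modules, fuzzy time-course clustering, and
secreted-factor endocrine-connectivity scoring. This note records the
models, their assumptions, the defaults, and the design decisions taken
where the design was genuinely open.

## Study design and the synthetic cohort

The design being modeled is a three-arm acute-exercise trial — endurance
(EE), resistance (RE) and non-exercising control (CON) — with adipose
biopsies at pre-exercise and at 45 min, 4 h or 24 h afterwards. To limit
repeat-biopsy artifacts, each participant is randomized to a *temporal
profile* and contributes exactly two samples: pre plus one post timepoint
(early → 45 min, middle → 4 h, late → 24 h). Every downstream model
assumes this structure, so the synthetic generator (`exermap.simulate`)
enforces it as an invariant.

`generate_omics` plants, with ground truth recorded per feature:

* **difference-in-changes effects** in a configurable fraction of
  features, applied only to post samples of the exercise arms, with
  random sign and (optionally) one of up to eight temporal archetypes
  scaling the effect across the three post timepoints;
* **sex effects** (male-shifted) in a second fraction;
* **co-expression modules** as equicorrelated feature blocks sharing a
  per-sample latent factor (default within-block correlation 0.8,
  blocks of 50);
* **within-participant correlation** via a participant latent intercept
  (default 0.5, the value used throughout the simulation study);
* **non-normal marginals** via a third-order polynomial (Fleishman)
  transform of a Gaussian copula, with intermediate correlations solved
  per pair (Vale–Maurelli) so the requested covariance survives the
  transform — defaults skewness 1, excess kurtosis 3;
* **counts** for the transcript ome by negative-binomial quantile mapping
  of the latent Gaussian values (dispersion 0.2, log-uniform means
  5–2000), giving the mean–variance trend the precision-weight machinery
  needs;
* **missingness** completely at random at a configurable rate (the
  profile design itself already induces the dominant, structural
  missingness).

What the generator does *not* emulate: batch structure, platform-specific
intensity distributions, instrument drift, missingness that depends on
abundance, and realistic pathway-level correlation beyond the planted
blocks. Passing recovery tests on these data therefore demonstrates that
the estimators implement their contracts, not that they are robust to
every artifact of real instruments.

Cohort covariates mirror the published cohort: 72% female, age 41 ± 15,
BMI 27.1 ± 4, three clinical sites, and temporal profiles allocated in
the study's 43:80:50 proportions by largest remainder.

## Differential analysis

Each feature is modeled as

y_ijt = mu_{g(i), t} + x_i' gamma + u_i + e_ijt,
u_i ~ N(0, tau^2), e ~ N(0, sigma^2 / w_ijt),

a *cell-means* parameterization with one mean per group × timepoint cell,
fixed covariates (age, sex, BMI, site by default), a participant random
intercept, and optional per-observation precision weights. Estimation is
REML with the variance ratio theta = tau^2/sigma^2 profiled by scalar
optimization; per-cluster Woodbury identities make each fit a few
milliseconds, which the simulation harness depends on. The engine is
validated against `statsmodels.MixedLM` (estimates agree to ~1e-6 on
fixtures).

Three contrast families are tested on the cell means:

* difference-in-changes: (mu_{g,t} − mu_{g,pre}) − (mu_{CON,t} −
  mu_{CON,pre}) — the primary exercise effect, immune to circadian /
  fasting / biopsy drift shared with the control arm;
* group-specific: mu_{g,t} − mu_{g,pre};
* modality: the EE change minus the RE change.

Contrast tests use Satterthwaite degrees of freedom computed from the
REML observed information (finite differences in (sigma^2, tau^2)); on
balanced paired data this reproduces the paired t-test exactly (df =
n−1). Singular fits (variance ratio at the zero boundary) fall back to
OLS with CR1 cluster-robust covariance and df = clusters − 1, flagged.
Sign conventions everywhere: post minus pre, exercise minus control, EE
minus RE, male minus female.

A feature × contrast is testable only if every involved group has at
least 3 participants with paired pre/post values. Benjamini–Hochberg
adjustment is applied within each (family, group, ome, timepoint)
stratum; significance at FDR 0.05. Baseline sex differences use a
single-covariate linear model (equivalent to a pooled two-sample t) with
BH across features.

Precision weights for counts follow the log-CPM mean–variance-trend
recipe: log2 CPM with a 0.5 offset, per-feature linear-model residual
sqrt-SDs, a lowess trend against average log2 count, and weights equal to
the inverse fourth power of the trend value at each observation's fitted
log2 count. Empirical-Bayes variance moderation is available behind a
flag (`moderate_var`): residual variances are shrunk toward a scaled
inverse-chi-square prior fit by log-scale moment matching, standard
errors rescaled and the prior df added to the test df. It is off by
default because no moderation parameters were externally fixed; the
weighted and unweighted random-intercept models are both available to
the simulation harness.

Z-score matrices for enrichment use z = sign(estimate) · Phi^{-1}(1 −
p/2), capped at |z| = 38 where p underflows; multiple features mapping to
one identifier are collapsed to the single most extreme z per contrast,
and multi-site phosphopeptide identifiers (`PROT_S1;S2`) are expanded
into one row per site before collapsing.

## Model-evaluation simulation

`exermap.simeval` regenerates the strategy-comparison experiment: null
(and optionally alternative) pre/post data are drawn from the
moment-matched generator at the cohort's actual group sizes (EE=63,
RE=73, CON=37) with the profile missingness pattern, and six strategies
are scored on the fraction of difference-in-changes contrasts (both
exercise arms × three post timepoints, pooled) rejected at alpha = 0.05:
paired/two-sample t on changes, OLS, the random-intercept mixed model
(weighted and unweighted), an unstructured-covariance GLS stratified by
profile, and a Gaussian GEE with AR(1) working correlation and sandwich
SEs (normal reference, per GEE convention).

Two design points deserve emphasis:

* **Sample sizes are not scaled down.** The small-sample behavior of the
  sandwich estimator is precisely what the experiment measures; at a
  third of the cohort size the GEE rejection rate roughly doubles, so
  shrinking the cohort would change the quantity itself. The in-package
  REML/GEE engines fit the full 173-participant design in ~0.02 s per
  replicate, so 20,000 replicates complete in minutes on one CPU. Only
  the replication count is reduced relative to the original
  multi-million-instance study.
* **AR(1) time positions** are the integer timepoint indices (pre=0,
  45min=1, 4hr=2, 24hr=3); with two observations per participant the
  working correlation at lag d is alpha^d.

Non-convergent replicates are excluded from denominators and counted;
strategies failing more than 5% of replicates are flagged unstable.
`summarize_moments` closes the loop by re-estimating, from any matrix and
design, the within-participant correlation and pooled marginal
skewness/kurtosis (bias-corrected; heavy-tail kurtosis remains
under-estimated at a few dozen pairs per subgroup — tests use wide
Monte-Carlo tolerances for it).

## Enrichment

The competitive pre-ranked test compares in-set vs out-of-set mean
z-scores with a pooled-SD two-sample t statistic, inflating the in-set
mean's variance by VIF = 1 + (m−1)·rho with rho = 0.01 by default (the
established convention; at rho = 0 the test is exactly the classical
pooled t, which the suite exploits as an oracle). The directional summary
z.std = sign(delta) · Phi^{-1}(1 − p/2) is derived from the two-sided p.
Over-representation uses the upper-tail hypergeometric. Sets must have at
least 5 members in the universe; gene-set collections additionally
require 70% retention of original membership (metabolite-class
collections are exempt). BH is applied within a collection; significance
0.05, relaxed to 0.1 for kinase/PTM-signature collections. One engine
serves pathways, cell-marker sets (100-gene convention when generated
synthetically), metabolite classes, kinase-substrate sets, and the
endocrine module's per-gene correlation enrichment (a z-scored
biweight-midcorrelation vector in place of differential z-scores).

## Co-expression networks

Signed adjacency a_ij = ((1 + cor_ij)/2)^beta; the soft power is the
smallest grid value whose connectivity distribution attains scale-free
fit R^2 ≥ 0.8 (equal-width log-binned regression, slope required
negative; if no power reaches the target the best fit is returned with a
flag). Modules come from average-linkage clustering of
topological-overlap dissimilarity with a height-based cut at the 0.5
quantile of merge heights and a minimum size of 30 (both configurable),
followed by iterative merging of modules whose eigengenes correlate above
1 − 0.3. A deliberately conservative (low) cut is used because
over-splitting is repaired by the eigengene merge step while
under-splitting cannot be repaired; at the originally contemplated
0.99-quantile cut, planted-block recovery collapses (ARI 0.15 vs 0.97).
Unassigned features carry label 0 and are excluded downstream. Eigengenes
are unit-variance first principal components with sign fixed to correlate
positively with their module on average; kME is each feature's
correlation with each eigengene. Module–trait association uses the
biweight midcorrelation (Tukey weights (1−u^2)^2, u = deviation /
(9·MAD), per-vector Pearson fallback at MAD 0) on z-scored traits, with
optional residualization of both sides on covariates, on baseline
samples.

Note on scale-freeness: equal-size equicorrelated blocks produce a
bimodal connectivity distribution that is *not* scale-free under any
power; the scale-free fit criterion is meaningful on hub-like
(heterogeneous-loading) structure, and the test suite distinguishes the
two cases.

## Trajectory clustering

Per-ome z-score matrices (global proteomics/phosphoproteomics excluded in
the original design because they lack the full timepoint coverage) are
row-stacked and each row divided by the sample SD of (0, 0, z_1, …, z_T):
the two zero columns temporarily stand in for the pre-exercise baseline,
anchoring the scale to departure-from-no-change, and are discarded before
clustering. Standard fuzzy c-means follows (alternating centroid /
membership updates, Euclidean distance, tolerance 1e-6), with the
fuzzifier set by the empirical Schwämmle–Jensen formula m(N, D) = 1 +
(1418/N + 22.05)·D^{-2} + (12.33/N + 0.243)·D^{-0.0406 ln N − 0.1134}.
The cluster count is chosen manually from a scree of minimum pairwise
centroid distances over c = 3…14; no automatic selection is performed.
Hard labels are the argmax membership where it reaches 0.3, otherwise
unassigned; centroids are sorted lexicographically so the arbitrary
cluster numbering is stable across runs.

## Endocrine connectivity

Candidate secreted factors are differential features intersected with the
union of a plasma-detected protein panel and a secreted-protein atlas,
deduplicated to genes; extracellular confidence is the maximum
compartment score (0–5) over the four extracellular categories (region,
space, exosome, vesicle). The Ssec score of an origin-tissue secretory
gene against a target tissue is sum_j −ln p(bicor(g, target_j)) divided
by the number of target genes; under independence p is uniform and
E[−ln p] = 1, giving the analytic null mean of 1 that the suite checks.
Natural log is the default (a base-10 switch rescales by a constant and
preserves ranks). Covariate adjustment (e.g. sex) residualizes both
matrices on an intercept + covariate model before correlating; bicor
p-values use the t approximation with df = n − 2, making Ssec fully
determined by the network module's correlation kernel. Ranks are
descending (1 = most connected); shifts of candidate ranks between
conditions are tested with Wilcoxon signed-rank (exact mode below 5
candidates) and paired t tests. A constant nonzero rank shift makes the
paired t degenerate; it is reported as p = 0.

## Preprocessing rules

* Metabolomics: average duplicate-ID rows → nonpositive values to
  missing → drop features > 20% missing → impute (KNN, k = 10, neighbors
  are samples, when more than 12 features remain; otherwise per-feature
  half-minimum) → log2(x+1). Half-minimum scope (per feature) and k are
  package choices; neither was externally fixed.
* Conditional median–MAD normalization is *blocked* when Kruskal–Wallis
  association of sample medians or upper quartiles with sex or
  sex-stratified group has p < 0.01 (normalizing would absorb biology);
  zero-MAD samples are centered at unit scale.
* PC outliers: samples outside Q1 − 5·IQR / Q3 + 5·IQR on any principal
  component explaining ≥ 1% variance.
* Cross-platform duplicates resolve to the platform with the lowest mean
  reference-standard CV; ties and missing CVs fall back to the
  lexicographically first platform, logged.
* RNA: the low-expression rule is implemented literally (remove a gene
  with CPM ≤ 0.5 in ≥ 10% of samples) with a `conventional` switch
  (keep genes exceeding 0.5 CPM in ≥ 10% of samples) because the literal
  text is extremely aggressive on real count distributions; TMM scaling
  uses the standard 30%/5% trims. Proteomics features quantified in
  < 30% of samples are removed (boundary inclusive).
* Technical residualization fits technical and protected (biological)
  covariates jointly and subtracts only the technical part; technical
  columns collinear with the protected design are skipped with a warning
  (the confounded-extraction-batch case).

## Problem sizes and tolerances

The default test and acceptance runs use 20,000 simulation replicates
(Monte-Carlo SE ≈ 0.15 percentage points on a 5% rate), 1,000-feature
single-ome matrices for power/FDR recovery, 400-feature networks, and
100-seed endocrine recovery — sizes chosen so the full suite runs in
minutes on a single CPU while keeping Monte-Carlo noise well inside the
stated tolerances. Numerical tie-breaks are deterministic (lexicographic
platform and centroid ordering, stable cluster relabeling by size), and
every stochastic routine takes an explicit seed.

## Known limitations

* The GEE AR(1) parameter is estimated by scalar least squares on
  residual cross-products; with two observations per cluster the AR(1)
  and exchangeable structures are only weakly distinguishable.
* The unstructured-covariance GLS uses a heuristic t reference
  (clusters − covariance parameters), adequate at the cohort's size but
  approximate in small samples.
* Kurtosis recovery by `summarize_moments` is biased low at realistic
  subgroup sizes; the generator's moment interface is exact only in the
  large-sample limit.
* The dynamic tree cut is a height-based variant, not the full iterative
  branch-analysis algorithm; its cut quantile is a tuning parameter.
* Phosphosite handling treats site strings syntactically; no sequence
  database lookups are performed.
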
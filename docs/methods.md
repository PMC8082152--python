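# Methods

This note documents the statistical procedures implemented in
`tmephenotyper`, the defaults chosen where the underlying workflow leaves
them open, what the synthetic cohorts do and do not emulate, and the
numerical conventions that make runs reproducible.

## ssGSEA enrichment scoring

Per sample, genes are ranked by expression with average ranks for ties
(rank N = highest). Walking the list from highest to lowest rank, the
in-set ECDF is weighted by rank^α normalized by the total in-set weight;
the out-of-set ECDF is the unweighted fraction of non-members reached. The
enrichment score is the sum over all N positions of (ECDF_in − ECDF_out).
Because only within-sample ranks enter, the score is invariant to any
strictly increasing per-sample transform of expression — which also makes
it robust to the scale differences the preprocessing steps cannot remove.

Choices:

- **α = 0.25** by default, the convention of the ssGSEA literature;
  exposed as a parameter. α = 0 gives the unweighted walk, under which a
  set occupying exactly half the genes scores the negative of its
  complement.
- **Ties** take average ranks for the weights; the *walk order* breaks
  expression ties by gene-id lexical order so results are bitwise
  reproducible across platforms.
- Genes of a set missing from the matrix are dropped per set (overlap
  logged); zero overlap, or a set covering every matrix gene (out-set ECDF
  undefined), is an error.
- Optional global min-max normalization maps the whole score matrix onto
  [0, 1]; off by default since downstream steps (z-scoring, ranks) do not
  need it.

ImmuneScore/StromalScore are ssGSEA on two user-supplied aggregate
signatures — the rank-based scoring core of purity-style estimators — and
higher values mean more immune/stromal signal. The tumor-purity polynomial
of the full ESTIMATE method is intentionally out of scope.

## Consensus clustering and k selection

The 24-signature score matrix is column z-scored; each of `reps`
repetitions draws ⌊0.8·n⌋ samples without replacement and runs k-means
(k-means++ initialization, best of 10 restarts, ≤ 50 Lloyd iterations).
The consensus entry for a pair is the fraction of co-sampled repetitions
in which it co-clustered. k is selected by minimal PAC — the fraction of
upper-triangle consensus entries in (0.1, 0.9) — with the CDF delta-area
reported as a diagnostic. Final assignment cuts an average-linkage tree of
1 − consensus at k.

Two behaviors worth knowing:

- **Exact PAC ties go to the larger k.** On cleanly separated data a merge
  of two true clusters is also perfectly stable, so PAC can be exactly 0
  at several k; the finer partition then carries strictly more stable
  structure. Without this rule nested clean structure would always
  collapse to k = 2.
- **On structureless (null) data PAC is high at every candidate k and
  *decreases* with k**, because fragmented partitions push consensus
  entries below the 0.1 floor. The selected k on null data is therefore
  meaningless by construction; PAC > 0.5 across all candidates is the
  practical signal that no stable structure exists, and the tests assert
  exactly that rather than any particular chosen k.

Cluster labels are renamed by ascending mean signature score: A = lowest
infiltration ("cold"), the last letter = highest ("hot"), so labels are
comparable across runs and cohorts. Defaults: reps = 1000 for production
use; the bundled tests and acceptance script use reps = 100, which on
cohorts of n = 150 already yields stable consensus matrices, to keep run
times in seconds.

## ICscore

Signature columns are z-scored and the first principal component computed
from the SVD of the standardized matrix (correlation PCA). A sample's
ICscore is its projection on PC1, with the component sign fixed so the
score correlates positively with the per-sample mean of z-scored
signatures — "high ICscore = high overall infiltration" is then literal.
One component only; the fraction of variance on PC1 is reported and is at
least 1/p for p signatures. Zero-variance signatures are dropped with a
warning. The fitted model (means, SDs, loadings, orientation) serializes
to JSON and projects onto new cohorts standardized by the *training*
moments, for applying a score trained on one cohort to another.
Dichotomization of the score is deliberately delegated to the
maximally-selected cutpoint below rather than a median split.

## Survival analysis

Kaplan–Meier estimation, the multi-group log-rank test and Cox fits are
delegated to lifelines; Cox uses Efron tie handling (better than Breslow
for discretized times), Wald 95% CIs, and one-hot encoding with first
level as reference for categorical covariates.

The **maximally-selected cutpoint** considers every midpoint between
consecutive distinct score values whose induced high/low groups both hold
at least `minprop` (default 0.1) of the samples, computes the standardized
two-group log-rank statistic (O − E)/√V at each, and returns the candidate
maximizing the absolute statistic (ties to the lower cut). The log-rank p
reported downstream for the induced groups is **not corrected for the
maximal selection** and is optimistic; this mirrors the common reporting
practice the pipeline reproduces, and is flagged here as a caveat rather
than silently adjusted.

A vectorized two-group log-rank (`logrank_two_group`) exists alongside the
lifelines-backed multi-group test; it implements the same hypergeometric-
variance statistic and is used where thousands of calls are needed (null
calibration), with agreement between the two routes covered by tests.

## Differential expression and group statistics

The moderated t shrinks per-gene variances toward a common prior:
s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g), t = logFC/(s̃·√(1/n1+1/n2)) on
d0 + d_g degrees of freedom. When (d0, s0²) are not supplied they are
estimated by matching moments of log s²_g (digamma/trigamma inversion), the
standard empirical-Bayes recipe; the implementation agrees with the
Bioconductor reference to ~1e-10 on test fixtures. d0 = 0 recovers the
ordinary pooled t, d0 → ∞ the fully shrunk statistic. logFC is a
difference of group means on the log2 scale. Significance applies both
filters: BH-adjusted p < 0.05 *and* |logFC| > 1. BH is the default
correction (Bonferroni available); the step-up implementation is checked
against statsmodels. Default DE contrasts are one-vs-rest per cluster.

Rank tests (Kruskal–Wallis with tie correction, rank-sum with exact
enumeration when both groups have ≤ 8 observations and a tie-corrected
normal approximation otherwise), Pearson chi-square without continuity
correction, and Spearman correlation follow their textbook definitions via
scipy. Degenerate inputs are guarded: all-identical values give H = 0 /
p = 1; zero contingency marginals and constant correlation inputs are
errors.

TMB is the raw count of nonsynonymous records per sample (no per-megabase
scaling, since no capture size is modeled); unknown variant classes are
excluded with a warning. Copy-number burden counts genes with calls > 0
(gain) and < 0 (loss), per focal/arm level and combined.

## Batch adjustment

ComBat in its parametric empirical-Bayes form: genes standardized by grand
mean and pooled variance (residuals around each sample's batch mean);
per-batch per-gene location γ and scale δ² estimated and shrunk toward
moment-matched priors (normal for γ, inverse-gamma for δ²) by the standard
iterative solution; effects removed and the grand scale restored.
Intercept-only design (no covariate preservation), matching a workflow
that corrects batches before any group labels exist; consequently strong
batch/biology confounding will remove signal, and the tests only promise
ARI preservation at < 50% confounding. Zero-variance genes pass through
with a warning; the non-parametric prior option is rejected at runtime
rather than half-implemented. Output matches Bioconductor `sva::ComBat`
to ~1e-8 on fixtures.

Quantile normalization replaces each sample's k-th order statistic by the
across-sample mean of k-th order statistics; tied values receive the mean
of their tied positions' targets, which makes the map idempotent and
rank-preserving. Default pipeline order: log2 → quantile → ComBat.

## Synthetic cohorts

The generator emulates the *statistical shape* the analysis assumes, with
defaults fixed once:

- 24 disjoint marker sets × 20 genes in a 5000-gene universe.
- Three phenotypes, default proportions 0.4/0.35/0.25: C has mean
  infiltration intensity 1 for all 24 cell types, A has 0, B has 1 for a
  designated subset of 8 types (the "mixed" cluster). Per-sample
  intensities add N(0, 0.25²) noise, truncated at 0.
- Marker-gene expression = 6 + N(0, 1) + effect_size × intensity on the
  log2 scale; background genes are pure noise; optional per-batch location
  shifts.
- Survival: exponential event times with log-hazard −0.43 per SD of mean
  infiltration (hazard ratio ≈ 0.65 per SD, favorable for hot tumors);
  administrative uniform censoring with a horizon calibrated by bisection
  to a 30% censored fraction.
- Response: Bernoulli with logit −1 + 1·z(mean infiltration) (≈ 27% base
  rate), CR/PR/SD/PD fine labels drawn within the binary classes.
- Mutation tables: per-sample Poisson counts with cluster-specific means;
  copy-number tables with per-cluster gain/loss rates.

Everything is driven by PCG64 streams spawned from a single seed, so
cohorts are bitwise reproducible.

What this does **not** emulate — and what passing tests therefore cannot
show: platform-specific array distributions, FPKM/TPM conversion, gene-gene
correlation beyond the planted cell-type structure, survival hazards that
differ *between* phenotypes beyond the infiltration axis (the real-data
observation that the mixed phenotype fares worst is not built in),
non-exponential baseline hazards, or informative censoring. Recovery
results on synthetic cohorts demonstrate correctness of the machinery, not
clinical validity on real cohorts.

## Problem sizes and numerical conventions

Bundled tests and the acceptance script run cohorts of n = 150 with 100
consensus repetitions, 50 Cox replicates of n = 500, 5000-replicate null
calibrations, and 2000-gene DE instances — sizes at which every planted
quantity is comfortably recoverable while the whole suite stays in the
low minutes. Tolerances: oracle equivalences at 1e-12 (ssGSEA walk) to
1e-6 (Cox coefficients); reference-implementation cross-checks at 1e-8.
Determinism everywhere is by explicit seeds; k-means restarts draw their
seeds from the same stream. Known limitations beyond those above: the
cutpoint p-value optimism already noted, intercept-only ComBat, and PAC's
degeneracy on null data.
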
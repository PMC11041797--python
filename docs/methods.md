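# Methods

This note documents the statistical procedures, the synthetic-cohort
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Case–control model and effect sizes

Group differences are estimated *within protocol* (one scanner + imaging
protocol combination) by ordinary least squares:

    volume ~ 1 + case + sex + age + ICV

For ICV as the outcome, and for laterality indices, the ICV covariate is
dropped — LI is a dimensionless ratio and including a volume covariate in a
ratio model is not meaningful; this is a declared choice, configurable at the
call site. Sex is coded 0/1 and age enters linearly.

The case coefficient's *t* is converted to Cohen's *d* on the pooled-SD
scale,

    d = t (n1 + n2) / (sqrt(n1 n2) sqrt(df)),
    se(d)^2 = (n1 + n2)/(n1 n2) + d^2 / (2 (n1 + n2 - 2)),

which folds the covariate adjustment into the standardized difference and is
the convention of the large neuroimaging consortia this pipeline follows. On
covariate-free data this agrees with the classical pooled-SD *d* to well
under 1% at n = 500 (tested). Protocols with fewer than `min_group_n`
(default 2) cases or controls are skipped for that diagnosis, mirroring the
gaps in multi-site demographic tables.

Degenerate fits (residual sum of squares below 1e-12 of the centered total
sum of squares) are flagged with a warning and reported with t = ±inf rather
than a spurious finite value.

## Random-effects pooling

DerSimonian–Laird moment estimation: fixed weights `w_i = 1/se_i^2`,
Cochran's `Q = sum w_i (d_i - d_fixed)^2`,
`tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`, random weights
`1/(se_i^2 + tau^2)`, and a two-sided normal reference for the pooled *z*.
`I^2 = max(0, (Q - (k-1))/Q) * 100`. DL was chosen because it is the
classical default of random-effects meta-analysis software and is fully
formula-specified; REML/Paule–Mandel and Hartung–Knapp adjustments are out
of scope. With a single eligible protocol the "pooled" row is that study,
flagged `single_study`.

Bonferroni families default to the number of measures per diagnosis — 17
for volumes (16 regions + ICV), 8 for laterality indices — at alpha = 0.05
two-sided; the family size is recorded in the output and configurable.

## Normative z-scoring

Per protocol, per region, OLS of volume on intercept + sex + age + ICV over
healthy controls only; all subjects of the protocol are scored as
`z = (observed - predicted)/residual SD`. The residual SD uses the model
degrees of freedom (n_hc - 4), so control z-columns have mean exactly zero
(least-squares identity) and sample SD `sqrt((n_hc-4)/(n_hc-1))` under the
n-1 convention — both asserted in tests. Protocols with fewer than `min_hc`
(default 10) controls are unusable and their subjects are excluded from
clustering with a warning. ICV is included for all 16 regions (unlike the
ICV-outcome case–control model) because the standardization controls for
head size. Clustering uses the 16 regional z-scores; ICV is not a feature.

## X-means clustering

k-means uses k-means++ initialisation, Lloyd iterations, and best-of-`n_init`
restarts; an emptied cluster is re-seeded at the farthest point. The X-means
driver alternates (a) a global Lloyd refinement with (b) a structure pass
that tentatively splits each cluster in two and accepts the split when the
local Bayesian Information Criterion of the children, evaluated on the
cluster's own points, beats the parent's. The alternation runs until no
split is accepted (so at convergence no cluster locally prefers splitting)
or k would exceed `kmax` (default 20, comfortably above the plausible
cluster count; `kmin` defaults to 1).

The BIC is the spherical-Gaussian form: pooled per-dimension variance
`sigma^2 = sum ||x - mu_c||^2 / (d (n - k))`, log-likelihood with hard
assignment terms `n_c log(n_c/n)`, parameter count `k (d + 1) + 1`, penalty
`(p/2) log n`; larger is better, zero variance yields -inf with a warning.
Candidate 2-way splits are generated by `n_init` k-means++ runs plus a
deterministic start at the centroid ± one SD along the first principal
component, and the candidate is selected by local BIC — not inertia —
because distinct local optima (outlier-peeling splits versus balanced
geometric cuts) order differently under the two scores and BIC is the
acceptance criterion. On the default paper-scale synthetic cohort this
yields between roughly 4 and 11 raw clusters depending on the seed, with
small outlier clusters appearing alongside the four planted profiles.

Clusters of size ≤ 1 are dropped afterwards (threshold configurable); their
members are marked unassigned and excluded from the association tests and
the classifier.

## Association tests and the biotype merge

Cluster–diagnosis association uses Pearson chi-squared on the retained
clusters with adjusted standardized residuals
`(O - E)/sqrt(E (1 - row/N)(1 - col/N))`; cells are flagged two-sidedly at
alpha divided by the number of cells (the per-cell Bonferroni is a
documented choice). Cluster–functioning association uses per-scale one-way
ANOVA plus Games–Howell pairwise tests (Welch–Satterthwaite degrees of
freedom, studentized-range reference with `q = t sqrt(2)`), chosen over
Tukey because group sizes and variances differ strongly across clusters.
Only per-scale F tests are produced; an omnibus multivariate statistic is
out of scope.

A cluster joins the functionally normal group iff its mean exceeds the
healthy-control reference mean minus one SD on **all** scales. Impaired
clusters become biotypes BB1, BB2, ... ordered by ascending mean full-scale
IQ (worst first; ties broken by size, larger first); the merged normal group
is the last-numbered biotype. A retained cluster with no functioning
observations cannot be classified by this rule; the pipeline excludes such
(invariably tiny) clusters from biotype assignment with a warning, while the
lower-level API raises by default.

## Classification and medication contrasts

LDA uses class means, pooled within-class covariance, and empirical priors
(class frequencies; uniform available) — empirical priors match the
"reassign to the original biotype" framing on an imbalanced cohort. A
singular pooled covariance receives a ridge of `1e-6 trace/dim`, flagged.
Leave-one-out validation downdates the class mean and pooled scatter by the
held-out observation (rank-one, exact — verified against brute-force
refitting) so the full cohort loop costs one 16×16 solve per subject. A fold
that removes the last member of a class predicts from the remaining classes
with a warning.

Medication doses are compared across biotypes with tie-corrected
Kruskal–Wallis (chi-squared reference, k-1 df; identical values give H = 0,
p = 1) and Dunn's rank-based pairwise post hoc with tie-corrected standard
errors and Bonferroni correction over the k(k-1)/2 pairs — the
rank-sum-consistent companion to Kruskal–Wallis.

## Synthetic-cohort generator

The generator exists so that every stage can be exercised and validated
against known ground truth; real data for this design are not shareable.

**Cohort bookkeeping.** The `paper-like` configuration encodes the
per-protocol sample sizes, male counts, and age means/SDs of the published
30-protocol cohort (3078 controls; 1500 SZ, 235 BP, 598 MDD, 193 ASD;
5604 subjects). The `toy` configuration uses 4 protocols of 50 subjects for
fast exercises, with functioning collected everywhere.

**Volumes.** For subject i, region r:

    volume = scale_p [ mu_r + b_sex sex + b_age (age - 40) + b_icv (ICV - 1.5e6)
                       + d(diag, r) sd_r + zshift(biotype, r) sd_r + eps ] + offset_p

with `eps ~ N(0, sd_r)` independent across regions (the downstream model is
OLS; correlated residuals are a configuration extension, not a default).
Healthy baselines (e.g. hippocampus 4200 ± 450 mm³, pallidum 1600 ± 250 mm³)
are typical adult FreeSurfer values. Scanner offsets and scales (~4%
location/scale) are drawn once from a fixed internal stream, so the default
configurations are identical across calls. ICV is log-normal (median
1.5 L, sigma 0.08) with a ~9% male shift — strictly positive with realistic
skew. Rare negative volume draws (ventricular tail) are floored at 1 mm³.

**Diagnosis effects.** Per-diagnosis Cohen's-d shifts mirror the published
*direction* pattern (ventricular enlargement in SZ/BP/MDD, hippocampal
reduction in SZ/BP, SZ-specific basal-ganglia enlargement and
amygdala/thalamus/accumbens reduction, etc.); the magnitudes (≤ 0.45) are
generator choices on the scale typical of such consortium reports, not
published values. The SZ pallidum laterality shift (+0.03 LI) is applied by
transferring volume between hemispheres at fixed structure total, which
isolates lateralization from total-volume effects and makes conservation
exactly testable.

**Biotypes.** Latent profiles in z-units: BB1 extreme limbic reduction with
ventricular enlargement (signature loads 2.0–2.8), BB2 the moderate version
(1.5–1.6), BB3 basal-ganglia enlargement (2.0), BB4 null. Impaired profiles
load their signature regions at ≥ 1.5 z so the planted four-cluster
structure is resolvable by BIC-guided clustering. Mixing defaults: controls
are 95% BB4 with small leakage into the impaired biotypes; patients are
enriched in BB1–BB3 (SZ most strongly). Because mixing differs by
diagnosis, the *marginal* case–control d exceeds the directly planted
per-region d under the defaults; planted-effect recovery tests therefore use
configurations with a single biotype.

**Functioning.** Scales use the published healthy-control references
(FIQ 112.7 ± 12.2, VC 111.4 ± 13.1, PO 108.2 ± 13.2, WM 110.7 ± 15.5,
PS 110.1 ± 14.0, UPSA-B Financial 48.7 ± 3.3, Communication 32.1 ± 8.3,
SFS 144.5 ± 17.4, weekly working hours 36.3 ± 18.5). Biotype shifts are
-2.4 / -1.8 / -1.6 / 0 SD for BB1–BB4 on every scale: decisively below the
-1 SD normality cutoff so that cluster-level means stay below it despite
assignment contamination, with BB1 severe and BB2/BB3 mild. The
diagnosis-independent base level is calibrated so the healthy-control
*marginal* mean equals the reference exactly (the printed control means are
marginal over the small control leakage into impaired biotypes). Scores are
unbounded Gaussians — no ceiling or floor effects are modelled. Functioning
and medications are generated only at designated sites (the three Osaka
protocols in the paper-like configuration), matching single-site
instrument collection.

**Medications.** Daily doses are zero-inflated log-normals per drug ×
biotype; impaired biotypes have both higher treatment probability and higher
dose medians than the normal biotype, so the normal biotype's distribution
is stochastically dominated under the defaults.

**What the generator does not emulate.** Correlated residuals across
regions and hemispheres, non-Gaussian volume distributions, site-specific
age ranges interacting with scanner effects beyond the encoded cells,
floor/ceiling effects in psychometric scales, medication effects *on*
volumes, and longitudinal change. Passing tests therefore demonstrate that
the pipeline recovers structure of the planted kind at the planted
signal-to-noise ratio — not that it would find the same structure, or the
same cluster count, in real clinical data.

## Problem sizes and reproducibility

The full paper-scale pipeline (5604 subjects, 16 features) runs in a few
seconds on one core; validation suites use 60-replicate null simulations for
type-I-error bands and 10-protocol, 100+100-per-arm cohorts for planted
effect recovery. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); identical (cohort, configuration, seed)
triples reproduce reports exactly. The number of raw X-means clusters on the
default cohort is seed-dependent (roughly 4–11, like any stochastic
clustering of overlapping mixtures); the merged biotype count is far more
stable — four in the large majority of seeds — because extra splits land
almost entirely inside the functionally normal region and are re-merged by
the functioning rule.

## Known limitations

- DerSimonian–Laird with few protocols (k ≤ 3) understates heterogeneity
  uncertainty; the normal reference is slightly anticonservative there.
- The spherical-Gaussian BIC treats clusters as equal-variance spheres in
  z-space; strongly elliptical substructure is split or merged accordingly.
- Games–Howell p-values use the studentized-range approximation, which is
  approximate for very small groups (n < 6).
- The biotype labels BB1–BBn are ordinal by severity within a run; they are
  comparable across runs only via their profiles, not their indices.
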
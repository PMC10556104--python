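# Methods

This note documents the models and numerical choices behind `cyclestage`,
the defaults that matter, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Spline curves

Per-gene expression curves are cubic regression splines in the cardinal
parameterization: coefficients are function values at the knots, knot
second derivatives follow from the tridiagonal continuity conditions, and
the penalty matrix S is the exact integrated squared second derivative of
the interpolating spline, so fitting minimizes ‖y − Xβ‖² + λ βᵀSβ. The
cyclic basis identifies the seam knot with the first knot, making value,
first and second derivative continuous across the period; its penalty null
space is the constants (so λ → ∞ shrinks a cyclic curve to the sample
mean), while the natural (non-cyclic) null space is the linear functions.

**Knots.** Cyclic bases use knots uniform over the period. This is the
robust choice when the training axis has only a handful of distinct values
— the whole-cycle fit sees 7 stage values under an 8-knot basis — where
data quantiles would collapse. Non-cyclic bases use quantiles of the
distinct observed times with the end knots clamped to the stated domain, so
prediction covers the whole domain (the 3-stage secretory model trains on
stages {5, 6, 7} but predicts over [4.5, 7.5]).

**Identifiability.** A cyclic basis with k knots has k − 1 free
coefficients; fits require at least as many distinct design points as free
coefficients (k − 1 cyclic, k non-cyclic). The penalty handles the rest.

**Smoothing selection.** λ is chosen per gene by GCV minimization over a
fixed grid of 41 log-spaced values from 1e−4 to 1e6 (configurable). A fixed
grid keeps the fit deterministic — refitting identical data is
bit-identical — and lets thousands of genes sharing one design be fit with
a handful of Cholesky solves. Ties on the GCV score keep the smallest λ.
When a single λ is explicitly requested, a saturated (interpolating) fit is
permitted. The adjusted R² reported per curve is
1 − (RSS/(n − edf)) / (TSS/(n − 1)), clipped at 0, and defined as 0 for
constant responses. No claim of numerical agreement with any particular GAM
package is made; the contract is the penalized-least-squares definition
above, and tests pin it to the normal-equations solution.

## Time assignment (the staging loss)

A sample with expression y is assigned the time d minimizing
L(d) = Σ_g (y_g − f_g(d))², evaluated on a dense grid and averaged over the
genes present (MSE). Grid steps default to 0.01 day on the 14-day
post-ovulatory axis, 0.005 stage units on the 3-stage and 7-stage axes, and
0.05 percentage points on the percentage axis; ties break to the smallest
grid time, deterministically. Samples must cover at least 50% of the model
genes; missing genes are dropped from the loss with a logged warning.
Genes are *not* variance-standardized in the loss by default — the residuals
are raw log2 units — but a `standardize` flag (inverse residual-variance
weights) exists for experimentation.

## Workflows

* **Secretory POD model** — training samples are those whose ≥2
  pathologist POD calls agree within 2 days (training time = their mean);
  non-cyclic k=3 curves on [1, 14]; every sample is then (re)assigned.
  The 3-stage variant uses stage labels 5/6/7 as numeric times on
  [4.5, 7.5].
* **Proliferative reassignment** — menstrual, proliferative and
  early-secretory samples are placed on the axis 0/1/2; non-cyclic k=3
  curves give each proliferative sample a continuous time; samples are
  split, in time order, into three contiguous groups as equal as possible
  (earlier groups take the remainder — an arbitrary but documented rule)
  and relabelled early/mid/late (stages 2/3/4).
* **Whole-cycle model** — stages 1..7 encoded as times 1..7 on a cyclic
  axis of period 7 (seam between stage 7 and stage 1, so the scale starts
  at menstruation); cyclic k=8 curves; continuous assignment on the cyclic
  grid. Absent stages warn; fewer than 3 distinct stages is an error.
* **Uniformization** — under the assumption that the cohort is uniformly
  spread around the cycle, samples are ranked from the cyclic origin and
  placed at 100·(rank − ½)/n. Ties break by sample identifier. The origin
  anchors at the earliest menstrual sample within the circular cluster of
  stage-1 training samples, putting 0% at menstruation onset; without an
  anchor the smallest model time starts the scale.
* **Percentage refit and normalization** — cyclic k=30 curves on the 0–100
  axis; normalized expression is residual + gene mean, which preserves
  per-gene means to machine precision. Normalization is idempotent at the
  pipeline level: curves refit to a normalized matrix are near-constant, so
  a second pass changes nothing materially (the *same* curve must not be
  subtracted twice).
* **Cross-validation** — seeded K-fold (default 5) over the eligible
  training samples of the secretory model; reports pooled and per-fold
  correlation of held-out times with pathology times next to the in-sample
  correlation. The folds, and hence the report, are reproducible from the
  seed.
* **Application to new cohorts** — model curves and incoming samples are
  per-gene centered on the gene intersection before assignment; medians by
  default, for tolerance to cross-platform outliers. Percentages are read
  directly off the model's percentage axis; optional re-uniformization
  re-ranks the new cohort instead.
* **Unsupervised route** — PCA (gene-centered, full SVD, deterministic
  sign convention) → k-means (k=5, n_init=10, seeded, with retry on an
  empty cluster) on the first two components → clusters ordered by the
  minimal-length open Hamiltonian path through their centroids (exhaustive
  over ≤8 clusters; the cyclic fit closes the loop) → cyclic k=6 curves on
  the ordered cluster index → MSE assignment → uniformization. "Ordered by
  distance" admits several readings; the shortest-path tour is this
  package's interpretation and is flagged as such. Origin and direction of
  the resulting scale are arbitrary, so comparisons first anchor the offset
  at the reference's earliest menstrual sample and try both orientations,
  reporting the pair maximizing the circular Pearson correlation (Pearson
  after unwrapping each estimate to its nearest circular representative
  around the reference). Truth-recovery statements use the Fisher–Lee
  circular correlation on circular ranks, which is invariant to rotation
  and reflection.

## Differential expression

Gene-wise OLS against a shared design; the cycle-time covariate enters as a
spline basis (default 8 columns, cyclic over 0–100; the constant direction
is removed so the columns sit next to an intercept; phase-stratified
analyses use a non-cyclic basis of default df 4 over the phase's
percentage range). Variance moderation follows the standard empirical-Bayes
moment matching of log s²_g to a scaled F distribution: the trigamma
identity is inverted by bracketed root finding; no spread beyond sampling
noise gives an infinite prior df with the pooled (mean) variance, and the
prior df can be overridden (0 recovers the ordinary t-test exactly). The
*treat* test against a minimum fold change τ (log2 of the 1.2 default used
by the window scan) uses the shifted-null construction
p = P(T > (|β| − τ)/se) + P(T > (|β| + τ)/se) on d0 + d_g df, which reduces
to the two-sided moderated t at τ = 0 and is conservative otherwise. Genes
with exactly zero residual variance get p = 1 (no effect) or p = 0 (effect
beyond τ) rather than NaN.

The sliding-window scan compares consecutive rank blocks — ranks
[i, i+w) versus [i+w, i+2w) for every start, giving n − 2w + 1 comparisons
— with the treat test and BH correction *within* each window. Each window
is attributed the percentage midpoint between its two blocks and hits are
pooled per phase; attributing by block span instead is available via the
windows table. The weighted Fisher combination gives study i weight
w_i = k·n_i/Σn (weights sum to the study count k), maps p_i to the upper
Gamma(w_i, scale 2) quantile and refers the sum to Gamma(k, scale 2);
equal weights reduce to classical Fisher, one study is the identity, and
zero p-values are clamped to the smallest positive float with a warning.
Signed/one-sided combination is out of scope.

## Preprocessing

Counts are filtered before normalization: a gene is removed iff its CPM
(raw library sizes) is below 0.5 in strictly more than 80% of samples.
TMM normalization uses the sample whose upper-quartile CPM is closest to
the mean upper quartile as reference, trims 30% of M-values and 5% of
A-values from each tail (rank-based, ties averaged), excludes genes with a
zero count in either sample, and takes an inverse-variance weighted mean of
the surviving M-values; factors are normalized to geometric mean 1. The
weights are computed on relative proportions (a fixed nominal per-million
library) rather than absolute library sizes: this preserves the
gene-to-gene weighting within each pair and makes the log2-CPM output
exactly invariant to rescaling any single sample's counts, at the price of
ignoring between-sample differences in count depth when weighting.
log2-CPM uses a prior count (default 2) scaled per sample by effective
library size in per-million units, for the same exact invariance. Array
data are accepted as already background-corrected, normalized log2
intensities; an optional detection-p mask keeps probes detected (p < 0.05)
in at least 20% of samples, and probe-level matrices collapse to genes by
keeping the probe with the greatest mean expression (ties keep the probe
first in the matrix).

## The synthetic generator

`simulate_cycle` draws true sample positions uniformly on the 0–100 cycle
(matching the staging model's uniformity assumption; a sub-range can be
requested, e.g. the secretory window). A configured fraction of genes is
cyclic: the mean curve is a sum of 1–2 Fourier harmonics with random
coefficients (1/h amplitude decay) and phases, rescaled so the
peak-to-trough amplitude equals a draw from the configured range; the rest
are flat. Observations add Gaussian log2 noise. Harmonic curves are a
different function family from the fitted splines on purpose, so recovery
tests cannot reward shared parameterization. Pathology labels jitter the
true percentage (Gaussian, wrapped) and bin it into menstrual [0, 8),
proliferative thirds of [8, 58) and secretory thirds of [58, 100);
secretory samples receive two independent noisy POD calls of
round(14·(t′ − 58)/42) clipped to [1, 14]. Age effects add
slope·(age − mean age) to chosen genes only inside a cycle window; a
constant batch shift can be applied to a sample subset. A Poisson count
mode (expected CPM = 2^mean-curve) exercises the filtering and TMM paths.

Defaults define the canonical benchmark cohort: 120 samples, 1500 genes,
30% cyclic, amplitudes U(0.5, 2) log2 units, noise sd 0.5, label jitter sd
4 percentage points, POD-call error sd 1 day. These sizes keep every
end-to-end check comfortably fast while leaving the recovery problem
non-trivial (labels are wrong by half a stage on average, and 70% of genes
are pure noise).

What the generator does **not** emulate: gene–gene correlation beyond the
shared cycle (residuals are independent), realistic count dispersion
(Gaussian log2 noise, or Poisson counts without overdispersion), platform-
specific probe behaviour, dropout, or real gene identities. Passing
recovery tests therefore demonstrates the machinery is correct under the
model's own assumptions — uniform sampling, smooth periodic means,
independent noise — not that real tissues satisfy those assumptions.

## Known limitations

* The uniformization step hard-codes the uniform-sampling assumption; a
  cohort recruited preferentially at one phase will have its percentages
  stretched there.
* The cycle direction and origin are not identifiable without labels; the
  unsupervised route needs an anchor (or a grid search) to compare with a
  supervised staging.
* The MSE loss weights all genes equally on the log2 scale; highly variable
  uninformative genes dilute it (mitigated in practice by the large cyclic
  signal; optionally by `standardize`).
* Batch correction is out of scope: input matrices are assumed
  batch-corrected (a per-batch mean-centering convenience is the most the
  package offers via the DGE design's batch dummies).
* Phase boundaries (8/58) are shipped as defaults appropriate for the
  menstrual cycle and are configurable, not estimated.
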
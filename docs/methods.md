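# Methods

## Scope and model

`exprshape` treats each gene's expression vector across a patient cohort as
an i.i.d. sample from one of six distribution families — Normal, Cauchy,
Lognormal, Gamma, Pareto, or a two-component Gaussian mixture ("Bimodal") —
plus an Unknown fallback. The family label then dictates how patients are
partitioned for survival comparison. All inference is per gene; no
between-gene covariance is modeled.

## Classification pipeline

**Bimodality first.** A two-component equal-variance Gaussian mixture is fit
by EM: initialization splits the sorted sample at the median and uses the
half-sample means, with the pooled within-half variance as the common σ and
π = 0.5; iteration stops when the log-likelihood improves by < 1e-8 or after
500 iterations. The Bimodality Index is BI = √(π(1−π))·|μ₂−μ₁|/σ, and
BI > 1.1 (the conventional cut) pre-empts all unimodal families. The
equal-variance constraint matches the standard Bimodality Index definition;
with free variances the index is not defined. For whole-matrix runs the EM
iterates all genes as rows of one array (converged rows freeze); results
are bit-identical to per-gene fits.

**Unimodal candidates.** Normal and Lognormal use Shapiro–Wilk p-values on
the data and its natural log (log only when every value is positive; the
test is valid for 3 ≤ n ≤ 5000 and larger cohorts are subsampled with a
seeded RNG). Cauchy, Gamma and Pareto use a parametric-bootstrap KS test in
the Lilliefors spirit: estimate parameters on the data, compute the exact KS
distance, then draw B samples from the fitted law, re-estimate on each draw,
and report p = (1 + #{D_b ≥ D_obs})/(B+1). The add-one estimator keeps p in
[1/(B+1), 1]. B defaults to 200; calibration at B = 200, n = 200 puts the
type-I rate of the Gamma test at its nominal 0.01 within binomial error.

**Estimators.** Gamma: Newton iteration on ln k − ψ(k) = ln x̄ − ln x̄︀
(method-of-moments start, relative tolerance 1e-10, ≤ 100 iterations), rate
= k/x̄. Pareto: x_m = min x, α = n/Σln(x_i/x_m) (closed form). Cauchy:
location = median, scale = IQR/2 by default because the Cauchy quartiles sit
at x₀ ± γ; `cauchy_scale="iqr"` uses the IQR itself for strict textual
replication of the median/IQR convention. Sample quantiles use linear
interpolation at positions (k−1)/(n−1); the convention is fixed because it
changes the Cauchy fit, and hence borderline classifications, at small n.

**Winner rule.** Among candidates with p > 0.01 the first in the precedence
order Normal, Lognormal, Cauchy, Gamma, Pareto wins. This is a deliberate
design choice over "largest p": the five p-values come from heterogeneous
tests and are not comparable as evidence, and on all-positive near-Gaussian
data several families are simultaneously adequate (a Gamma with shape
(μ/σ)² ≈ 25–100 is practically Normal), so a max-p rule assigns such genes
essentially at random among Normal/Lognormal/Gamma. Preferring the simplest
adequate family makes the Normal category stable and reproducible.

**Determinism.** Every gene's random stream (bootstrap draws, subsampling)
is seeded by a CRC of its id mixed with the configured master seed, so
classifications are independent of gene order and of any parallel schedule.

## Survival analysis

Splits by family: Normal/Cauchy → both `tail_fraction` tails (default
deciles) vs the middle; Lognormal/Gamma/Pareto → the single long-tail decile,
side chosen by the sign of the sample skewness (all three families in the
panel are right-skewed, so the upper tail dominates in practice); Bimodal →
membership of the upper mixture component at posterior ≥ 0.5. Ties exactly
at a quantile cut go to the non-extreme group, keeping extreme groups at or
below nominal size and deterministic. A k-means fallback for mode
assignment is available behind `use_kmeans_modes`, but the mixture
responsibilities are the default so each gene carries exactly one model.

The log-rank statistic is (ΣO − ΣE)²/ΣV with hypergeometric moments at each
distinct event time and a χ²₁ p-value. It is implemented in vectorized
numpy (the test-suite checks it to 1e-10 against a brute-force
hypergeometric-moment oracle on thousands of enumerated small fixtures and
against lifelines on random ones); Kaplan–Meier curves come from lifelines.
The genome-wide scan flags genes with p < 0.05; the random-assignment null
permutes group labels preserving group sizes and recounts significant genes
per permutation.

## Classifier comparison

Per repeat (default 100; the bundled benchmark uses 20): a seeded 2/3–1/3
partition shared by all three assumptions. Shape: classify genes on the
training portion only, scan with family splits, keep the k smallest
log-rank p-values (k = 100 default; size-matched across assumptions).
Symmetric: same with uniform two-tail splits and no classification. Random:
k genes uniformly without replacement. A random survival forest
(scikit-survival; log-rank split rule, bootstrap resamples, 1000 trees by
default) is trained on the selected genes' raw expression values, and test
patients are scored by ensemble mortality.

Good/poor outcome is dichotomized at the training-set median observed time
T_med: poor = death at or before T_med, good = observed time beyond T_med,
censored at or before T_med = indeterminate and excluded from the
denominator. Predicted poor = risk above the median training risk. This is
the only dichotomy derivable from training data alone; the exclusion rule
and threshold are config-exposed. Wins count repeats with shape rate ≤
symmetric rate (ties reported separately), with a paired Wilcoxon
signed-rank test and notched-boxplot summaries (median ± 1.58·IQR/√n).

## Synthetic cohorts

`simulate_cohort` draws each gene i.i.d. from its declared family; survival
times are exponential with per-sample hazard = baseline × Π(hazard ratio of
each prognostic gene whose risk group contains the sample). Risk groups are
the long-tail decile (tail-linked genes) or the upper mode (mode-linked).
Censoring is independent exponential calibrated per sample (c = h·r/(1−r))
so the expected censored fraction equals the requested rate exactly. The
baseline hazard ln2/500 d⁻¹ gives a realistic ~500-day median survival.

Presets: `classify` = 600 genes, 100 per family, n = 300 — Normal means
5–10 with sd 0.5–2 (log2-intensity-like), Cauchy locations 5–10 with scales
0.3–1, Lognormal log-sd 0.3–0.5 (moderate skew), Gamma shapes 1–5, Pareto
indices 2–4, bimodal separations 3–5σ with mixing 0.35–0.65. `survival` /
`compare` = 500 genes with 20 mode-linked bimodal + 10 tail-linked Gamma
prognostic genes at hazard ratio 3 and 30% censoring, n = 300. Parameters
cycle over fixed grids so different seeds change only the sampled values,
never the design.

What the generator does **not** emulate: gene–gene correlation, batch
effects, platform noise, non-proportional hazards, and informative
censoring. Passing tests therefore demonstrate the statistical machinery
under clean conditions, not performance on any real cohort.

## Problem sizes and numerical choices

The bundled benchmark and test-suite run the comparison at 20 repeats,
k = 50, 200 trees and B = 100 bootstrap replicates, and calibration
simulations at 200–500 replicates; these sizes were chosen so the whole
suite completes on a single CPU while leaving the binomial error bands
informative. EM degeneracies (a component weight collapsing) freeze the
fit at the last valid state; zero-variance genes classify as Unknown with a
warning; bootstrap estimator failures (e.g. zero IQR in a resample guard)
mark that family untestable for the gene rather than aborting.

## Known limitations

* With 30 planted prognostic genes acting multiplicatively on the hazard,
  each gene's marginal effect is diluted (a frailty effect), so per-gene
  log-rank power in the `compare` preset is deliberately moderate —
  mirroring the regime where gene selection matters.
* Heavy-skew unimodal samples (Pareto with index 2–4, Gamma with shape ≈ 1,
  Lognormal with log-sd ≳ 0.6) are flagged bimodal at substantial rates by
  the equal-variance mixture — a property of the Bimodality Index itself,
  reproduced by the reference mclust implementation, not an artifact of
  this EM. Consequently Pareto-like genes are systematically absorbed into
  the Bimodal category at n = 300, and the panel's Pareto/low-shape-Gamma
  diagonal recovery sits well below that of the other families. This is
  consistent with Pareto being empirically absent in published cohort
  classifications.
* The Box-Cox sweep applies the transform to the matrix on whatever scale
  it is supplied; genes containing non-positive values are outside the
  transform domain and are skipped with a count.
* Clinical records with zero survival time are retained; the log-rank test
  handles them as the earliest risk set.
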
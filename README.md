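# exprshape

Distribution-shape analysis of gene-expression cohorts: classify each gene's
expression profile into one of six distribution families, use the inferred
shape to stratify patients for survival analysis, and benchmark whether
shape-aware gene selection predicts patient survival better than the usual
one-size-fits-all symmetric assumption.

## Who this is for

Analysts of bulk transcriptomic patient cohorts (microarray log-intensities
or RNA-seq counts, 150–600 samples) who want to go beyond the default
assumption that every gene is Normally distributed across patients. In
tumor cohorts a large fraction of genes are skewed (Gamma, Lognormal,
Pareto), heavy-tailed (Cauchy), or split into two expression modes
(Bimodal); the shape carries biological and prognostic information that
symmetric methods discard.

## The method

**Classification (bimodality first).** For each gene with expression vector
*x* over patients:

1. Fit a two-component equal-variance Gaussian mixture by EM and compute the
   Bimodality Index BI = √(π(1−π))·|μ₂−μ₁|/σ. If BI > 1.1 the gene is
   **Bimodal** and no unimodal family is considered.
2. Otherwise test five candidates at α = 0.01: Shapiro–Wilk on *x*
   (**Normal**) and on ln *x* (**Lognormal**, only if all values are
   positive); and a Lilliefors-style parametric-bootstrap Kolmogorov–Smirnov
   test for **Cauchy** (median/IQR fit), **Gamma** (Newton MLE) and
   **Pareto** (closed-form MLE), re-estimating parameters on every bootstrap
   resample so the null distribution of the KS distance is honest.
3. The winner is the first adequate family in the order Normal, Lognormal,
   Cauchy, Gamma, Pareto; a gene fitting nothing is **Unknown** and drops
   out.

**Shape-aware survival splits.** Symmetric families contrast the two deciles
of both tails against the middle; skewed families use the single long-tail
decile; bimodal genes are split at the mixture posterior into their two
modes. Groups are compared with the standard log-rank test (α = 0.05) and
Kaplan–Meier curves.

**Classifier benchmark.** Repeatedly split the cohort 2/3 train / 1/3 test;
select the top-k prognostic genes on the training portion under the shape,
symmetric, or random assumption; train a random survival forest; score the
held-out third by misclassification of good vs poor survival (dichotomized
at the training-median observed time). The three assumptions share each
partition, so their rates are paired.

Auxiliary analyses: a Box-Cox sweep ((x^λ−1)/λ, λ = −10…10) counting
Shapiro-Normal genes per λ, and tumor-purity association (per-gene
correlation, Benjamini–Hochberg, Fisher's exact test against the Normal/
non-Normal classification).

## Worked example

`python examples/shape_survival_split.py` simulates one bimodal gene whose
upper expression mode triples the death hazard and prints:

```
bimodality index: 2.07 (threshold 1.1)
mode split:     groups 141/159, log-rank chi2 = 79.5, p = 4.89e-19
two-tail split: groups 60/240, log-rank chi2 = 1.5, p = 2.17e-01
median survival (high mode): 160 days
median survival (low mode): 571 days
```

The mode split recovers the planted structure decisively (median survival
160 vs 571 days) while the symmetric two-tail split of the very same gene
sees almost nothing — the core point of shape-aware analysis. The other
examples cover family classification (`classify_families.py`), the
forest benchmark (`compare_classifiers.py`, where the shape assumption's
mean misclassification beats the symmetric one), and the Box-Cox/purity
screens (`boxcox_purity.py`).

## Command line

A thin CLI wraps the library for file-based runs:

```bash
exprshape simulate --preset classify --seed 7 --out sim/
exprshape classify --expr sim/expression.tsv --out calls/
exprshape survival --expr expr.tsv --clinical clin.tsv --assumption shape --out scan/
exprshape compare  --expr expr.tsv --clinical clin.tsv --out bench/
exprshape boxcox   --expr expr.tsv --out sweep/
exprshape purity   --expr expr.tsv --clinical clin.tsv --out purity/
```

Inputs are plain TSV/CSV (genes × samples with a header of sample ids;
clinical tables with `sample_id  time_days  event  [purity]`). Every output
directory gets a manifest with config, input digests and seed, so runs are
reproducible byte for byte.

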
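"""Split patients by a bimodal gene's expression modes and compare survival.

Simulates one bimodally expressed gene whose upper mode triples the death
hazard, partitions the cohort at the mixture posterior, and tests the two
Kaplan-Meier curves with a log-rank test.  The printed p-value shows the
mode split recovering the planted prognostic structure; the Normal two-tail
split of the same gene is far weaker because it mixes the two modes.
"""

import numpy as np

from exprshape import (
    SurvivalTable,
    fit_two_component_mixture,
    km_estimate,
    logrank_test,
    split_patients,
)
from exprshape.distributions import Family

rng = np.random.default_rng(3)
n = 300
upper_mode = rng.random(n) < 0.5
x = np.where(upper_mode, 4.0, 0.0) + rng.standard_normal(n)

hazard = np.where(upper_mode, 3.0, 1.0) * np.log(2) / 500  # HR 3, median 500 d
time = rng.exponential(1 / hazard)
censor = rng.exponential(1 / (hazard * 0.3 / 0.7))  # ~30% censoring
surv = SurvivalTable(
    [f"P{i}" for i in range(n)],
    np.minimum(time, censor),
    (time <= censor).astype(int),
)

mixture = fit_two_component_mixture(x)
print(f"bimodality index: {mixture.bi:.2f} (threshold 1.1)")

mode_split = split_patients(x, Family.BIMODAL, mixture, sample_ids=surv.sample_ids)
res = logrank_test(mode_split, surv)
print(f"mode split:     groups {res.n1}/{res.n2}, log-rank chi2 = {res.statistic:.1f}, p = {res.p:.2e}")

tail_split = split_patients(x, Family.NORMAL, sample_ids=surv.sample_ids)
res2 = logrank_test(tail_split, surv)
print(f"two-tail split: groups {res2.n1}/{res2.n2}, log-rank chi2 = {res2.statistic:.1f}, p = {res2.p:.2e}")

curves = km_estimate(surv, np.where(mode_split.in_group1, "high mode", "low mode"))
for label, curve in curves.items():
    median = curve[curve <= 0.5].index.min()
    print(f"median survival ({label}): {median:.0f} days")
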
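"""Shape-aware patient stratification and survival testing.

The split rule follows the gene's distribution family: symmetric families
(Normal, Cauchy) contrast both tails against the centre; right-skewed
families (Lognormal, Gamma, Pareto) use the single long-tail side, chosen by
the sign of the sample skewness; bimodal genes are split at the mixture
posterior into their two modes.  Group survival curves are compared with the
standard two-group log-rank test (chi-square, 1 df).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .classify import BimodalFit, DistributionCall
from .data import AnalysisConfig, ExpressionMatrix, SurvivalTable
from .distributions import Family

logger = logging.getLogger(__name__)

__all__ = [
    "SplitRule",
    "Assumption",
    "PatientSplit",
    "LogRankResult",
    "split_patients",
    "logrank_test",
    "logrank_from_arrays",
    "km_estimate",
    "prognostic_scan",
    "random_split_null",
]


class SplitRule(str, Enum):
    TWO_TAIL = "TWO_TAIL"
    ONE_TAIL_UPPER = "ONE_TAIL_UPPER"
    ONE_TAIL_LOWER = "ONE_TAIL_LOWER"
    MODE = "MODE"


class Assumption(str, Enum):
    SHAPE = "shape"
    SYMMETRIC = "symmetric"
    RANDOM = "random"


@dataclass
class PatientSplit:
    """Binary sample partition: group1 is the extreme (or upper-mode) group."""

    sample_ids: list[str]
    in_group1: np.ndarray  # boolean per sample
    rule: SplitRule
    cut_points: tuple[float, ...]

    def __post_init__(self) -> None:
        self.in_group1 = np.asarray(self.in_group1, dtype=bool)
        if self.in_group1.shape != (len(self.sample_ids),):
            raise ValueError("group mask length does not match sample count")
        n1 = int(self.in_group1.sum())
        if n1 == 0 or n1 == len(self.sample_ids):
            raise ValueError("both patient groups must be non-empty")

    @property
    def n1(self) -> int:
        return int(self.in_group1.sum())

    @property
    def n2(self) -> int:
        return len(self.sample_ids) - self.n1


@dataclass
class LogRankResult:
    statistic: float
    p: float
    n1: int
    n2: int
    events1: int
    events2: int


def split_patients(
    x,
    family: Family,
    bifit: BimodalFit | None = None,
    tail_fraction: float = 0.10,
    sample_ids: list[str] | None = None,
) -> PatientSplit:
    """Partition samples into extreme vs non-extreme groups by family shape.

    Ties exactly at a quantile cut point go to the non-extreme group, keeping
    the extreme group at or below its nominal size.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 20:
        raise ValueError("patient split needs at least 20 samples")
    ids = sample_ids if sample_ids is not None else [f"S{i}" for i in range(n)]

    if family in (Family.NORMAL, Family.CAUCHY):
        lo, hi = np.quantile(x, (tail_fraction, 1.0 - tail_fraction))
        mask = (x < lo) | (x > hi)
        rule, cuts = SplitRule.TWO_TAIL, (float(lo), float(hi))
    elif family in (Family.LOGNORMAL, Family.GAMMA, Family.PARETO):
        if stats.skew(x) > 0:
            hi = np.quantile(x, 1.0 - tail_fraction)
            mask = x > hi
            rule, cuts = SplitRule.ONE_TAIL_UPPER, (float(hi),)
        else:
            lo = np.quantile(x, tail_fraction)
            mask = x < lo
            rule, cuts = SplitRule.ONE_TAIL_LOWER, (float(lo),)
    elif family is Family.BIMODAL:
        if bifit is None:
            raise ValueError("bimodal split requires the mixture fit")
        mask = bifit.component2_members()
        rule, cuts = SplitRule.MODE, (0.5,)
    else:
        raise ValueError(f"no split rule for family {family}")

    if mask.sum() in (0, n):
        raise ValueError(
            f"{rule.value} split left a group empty (ties at the cut point?)"
        )
    return PatientSplit(list(ids), mask, rule, cuts)


def logrank_from_arrays(time, event, in_group1) -> LogRankResult:
    """Two-group log-rank test from raw arrays.

    At each distinct event time the observed group-1 events are compared with
    the hypergeometric expectation given the risk sets; the statistic is
    (sum O - sum E)^2 / sum V with a chi-square(1) p-value.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    if event.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")

    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], g1[order]
    n = t.size
    # risk set sizes just before each distinct time
    uniq, start = np.unique(t, return_index=True)
    at_risk_total = n - start
    cum_g1 = np.concatenate(([0], np.cumsum(g)))
    at_risk_g1 = g.sum() - cum_g1[start]
    # events at each distinct time
    d_total = np.add.reduceat(e, start)
    d_g1 = np.add.reduceat(e * g, start)
    has_event = d_total > 0
    nj = at_risk_total[has_event].astype(float)
    n1j = at_risk_g1[has_event].astype(float)
    dj = d_total[has_event].astype(float)
    d1j = d_g1[has_event].astype(float)

    expected = dj * n1j / nj
    with np.errstate(invalid="ignore", divide="ignore"):
        var = dj * (n1j / nj) * (1.0 - n1j / nj) * (nj - dj) / (nj - 1.0)
    var = np.where(nj > 1, var, 0.0)
    o_minus_e = float(np.sum(d1j - expected))
    v = float(np.sum(var))
    statistic = o_minus_e**2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(statistic, df=1)) if v > 0 else 1.0
    return LogRankResult(
        statistic=float(statistic),
        p=p,
        n1=int(g1.sum()),
        n2=int((~g1).sum()),
        events1=int(event[g1].sum()),
        events2=int(event[~g1].sum()),
    )


def logrank_test(split: PatientSplit, surv: SurvivalTable) -> LogRankResult:
    """Log-rank test between the two groups of a patient split."""
    if split.sample_ids != surv.sample_ids:
        surv = surv.subset(split.sample_ids)
    res = logrank_from_arrays(surv.time, surv.event, split.in_group1)
    if res.events1 == 0 or res.events2 == 0:
        logger.debug("log-rank with an event-free group (n1=%d, n2=%d)", res.n1, res.n2)
    return res


def km_estimate(surv: SurvivalTable, group=None) -> dict[str, pd.Series]:
    """Kaplan-Meier product-limit curves, one per group label.

    Returns a mapping from group label ("all" when no grouping is given) to a
    survival-probability series indexed by time.
    """
    from lifelines import KaplanMeierFitter

    if group is None:
        group = np.array(["all"] * surv.n_samples)
    group = np.asarray(group)
    curves: dict[str, pd.Series] = {}
    for label in pd.unique(group):
        mask = group == label
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask])
        curves[str(label)] = kmf.survival_function_.iloc[:, 0]
    return curves


def _split_for_gene(
    x,
    call: DistributionCall | None,
    assumption: Assumption,
    tail_fraction: float,
    sample_ids: list[str],
) -> PatientSplit:
    if assumption is Assumption.SYMMETRIC:
        return split_patients(x, Family.NORMAL, None, tail_fraction, sample_ids)
    if call is None or call.family is Family.UNKNOWN:
        raise ValueError("shape split needs a non-unknown classification")
    return split_patients(x, call.family, call.bimodal_fit, tail_fraction, sample_ids)


def prognostic_scan(
    m: ExpressionMatrix,
    calls: list[DistributionCall] | None,
    surv: SurvivalTable,
    cfg: AnalysisConfig,
    assumption: Assumption | str = Assumption.SHAPE,
) -> pd.DataFrame:
    """Genome-wide log-rank scan for prognostic genes.

    Under the shape assumption each gene is split by its classified family
    (unknown genes are skipped); under the symmetric assumption every gene
    gets the same two-tail split.  Per-gene split failures are logged and
    skipped rather than aborting the scan.
    """
    assumption = Assumption(assumption)
    if m.sample_ids != surv.sample_ids:
        raise ValueError("expression and survival tables must be aligned first")
    if assumption is Assumption.SHAPE and calls is None:
        raise ValueError("shape scan requires classification calls")
    call_by_gene = {c.gene_id: c for c in calls} if calls is not None else {}
    rows = []
    for i, gene in enumerate(m.gene_ids):
        call = call_by_gene.get(gene)
        if assumption is Assumption.SHAPE and (call is None or call.family is Family.UNKNOWN):
            continue
        try:
            split = _split_for_gene(
                m.values[i], call, assumption, cfg.tail_fraction, m.sample_ids
            )
            res = logrank_test(split, surv)
        except ValueError as exc:
            logger.debug("gene %s skipped in scan: %s", gene, exc)
            continue
        rows.append(
            {
                "gene_id": gene,
                "family": call.family.value if call is not None else "",
                "rule": split.rule.value,
                "n1": res.n1,
                "n2": res.n2,
                "chisq": res.statistic,
                "p": res.p,
                "significant": res.p < cfg.alpha_survival,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "family", "rule", "n1", "n2", "chisq", "p", "significant"],
    )


def random_split_null(
    surv: SurvivalTable,
    splits: list[PatientSplit],
    n_perm: int,
    seed,
    alpha: float = 0.05,
) -> np.ndarray:
    """Random-assignment null: permute group labels, recount significant genes.

    For each permutation every gene's group labels are shuffled preserving
    the group sizes; returned is the count of genes with log-rank p < alpha
    per permutation.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_perm, dtype=int)
    time, event = surv.time, surv.event
    for b in range(n_perm):
        c = 0
        for split in splits:
            perm = rng.permutation(split.in_group1)
            try:
                res = logrank_from_arrays(time, event, perm)
            except ValueError:
                continue
            if res.p < alpha:
                c += 1
        counts[b] = c
    return counts
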
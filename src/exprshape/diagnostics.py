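"""Box-Cox normality sweep and tumor-purity association analyses.

The Box-Cox sweep asks whether a power transform (x^lambda - 1)/lambda
(ln x at lambda = 0) can turn non-Normal expression profiles Normal: for
every lambda on an integer grid the per-gene Shapiro-Wilk test is rerun and
the Normal gene count recorded.  The purity analyses correlate expression
with pathologist purity per gene (BH-adjusted) and test, with Fisher's exact
test, whether Normally-distributed genes are over- or under-represented
among the purity-correlated ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import DistributionCall
from .data import ExpressionMatrix
from .distributions import Family

logger = logging.getLogger(__name__)

__all__ = [
    "BoxCoxSweepResult",
    "PurityResult",
    "box_cox_transform",
    "box_cox_sweep",
    "fisher_exact_p",
    "purity_scan",
    "purity_association",
]


def fisher_exact_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail mass)."""
    _, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return float(p)


@dataclass
class BoxCoxSweepResult:
    lambdas: list[float]
    normal_gene_count: list[int]
    untransformed_count: int
    n_genes_tested: int
    n_genes_skipped: int  # genes with non-positive values (outside the domain)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambdas, "n_normal_genes": self.normal_gene_count})


@dataclass
class PurityResult:
    per_gene: pd.DataFrame  # gene_id, coefficient, p, p_adjusted, significant
    table: np.ndarray | None = None  # 2x2 {Normal, non-Normal} x {purity-sig, not}
    fisher_odds_ratio: float | None = None
    fisher_p: float | None = None


def box_cox_transform(x, lam: float) -> np.ndarray:
    """(x^lambda - 1)/lambda, with the analytic ln(x) limit at lambda = 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if lam == 0:
        return np.log(x)
    # expm1 form is stable for small |lam|, where x**lam - 1 underflows
    return np.expm1(lam * np.log(x)) / lam


def _shapiro_p(x: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def box_cox_sweep(
    m: ExpressionMatrix, lambdas=None, alpha: float = 0.01
) -> BoxCoxSweepResult:
    """Count Shapiro-Normal genes (p > alpha) at each lambda and untransformed.

    Genes containing non-positive values fall outside the transform domain
    and are skipped (counted).  lambda = 1 is an affine map, so its count
    always equals the untransformed one.
    """
    if lambdas is None:
        lambdas = list(range(-10, 11))
    lambdas = [float(l) for l in lambdas]
    if not lambdas:
        raise ValueError("empty lambda grid")
    positive = np.all(m.values > 0, axis=1)
    n_skipped = int((~positive).sum())
    if n_skipped:
        logger.info("box_cox_sweep: skipped %d gene(s) with non-positive values", n_skipped)
    rows = m.values[positive]
    if rows.size == 0:
        raise ValueError("no genes with all-positive values to sweep")
    untransformed = int(sum(_shapiro_p(r) > alpha for r in rows))
    counts = []
    for lam in lambdas:
        transformed = box_cox_transform(rows, lam)
        counts.append(int(sum(_shapiro_p(r) > alpha for r in transformed)))
    return BoxCoxSweepResult(lambdas, counts, untransformed, int(positive.sum()), n_skipped)


def purity_scan(
    m: ExpressionMatrix,
    purity: np.ndarray,
    method: str = "spearman",
    alpha_adj: float = 0.001,
) -> PurityResult:
    """Per-gene correlation of expression with tumor purity, BH-adjusted."""
    purity = np.asarray(purity, dtype=float)
    if purity.shape != (m.n_samples,):
        raise ValueError("purity must be aligned with the matrix samples")
    have = np.isfinite(purity)
    if have.sum() < 10:
        raise ValueError("need purity for at least 10 samples")
    p_vals = purity[have]
    if np.all(p_vals == p_vals[0]):
        raise ValueError("constant purity: correlation undefined")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    coefs, pvs = [], []
    for row in m.values[:, have]:
        if np.all(row == row[0]):
            coefs.append(0.0)
            pvs.append(1.0)
            continue
        if method == "spearman":
            r, p = stats.spearmanr(row, p_vals)
        else:
            r, p = stats.pearsonr(row, p_vals)
        coefs.append(float(r))
        pvs.append(float(p))
    _, adj, _, _ = multipletests(pvs, method="fdr_bh")
    frame = pd.DataFrame(
        {
            "gene_id": m.gene_ids,
            "coefficient": coefs,
            "p": pvs,
            "p_adjusted": adj,
            "significant": adj < alpha_adj,
        }
    )
    return PurityResult(per_gene=frame)


def purity_association(
    calls: list[DistributionCall], purity_significant: dict[str, bool] | pd.Series
) -> PurityResult:
    """Fisher's exact test: Normal classification x purity significance.

    Builds the 2x2 table {Normal, non-Normal} x {purity-significant, not}
    over genes present in both inputs; p-value by two-sided hypergeometric
    enumeration, odds ratio by conditional MLE.
    """
    if isinstance(purity_significant, pd.Series):
        purity_significant = purity_significant.to_dict()
    table = np.zeros((2, 2), dtype=int)
    rows = []
    for call in calls:
        flag = purity_significant.get(call.gene_id)
        if flag is None:
            continue
        i = 0 if call.family is Family.NORMAL else 1
        j = 0 if flag else 1
        table[i, j] += 1
        rows.append({"gene_id": call.gene_id, "normal": i == 0, "purity_significant": bool(flag)})
    if table.sum(axis=1).min() == 0:
        raise ValueError("need at least one Normal and one non-Normal gene")
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    odds = stats.contingency.odds_ratio(table, kind="conditional")
    return PurityResult(
        per_gene=pd.DataFrame(rows),
        table=table,
        fisher_odds_ratio=float(odds.statistic),
        fisher_p=float(fisher_p),
    )
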
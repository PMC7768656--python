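"""Benchmarking shape-aware gene selection for survival prediction.

Protocol: repeatedly split the cohort 2/3 train / 1/3 test; on the training
portion select the top-k prognostic genes under the shape assumption
(classify genes on training data only, split by family, log-rank), under the
symmetric assumption (uniform two-tail splits), or uniformly at random; train
a random survival forest on the selected genes; score the held-out third by
misclassification of good vs poor survival.  The three assumptions share the
identical partition within a repeat, so their rates are paired.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_matrix
from .data import AnalysisConfig, ExpressionMatrix, SurvivalTable
from .survival import Assumption, prognostic_scan

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatResult",
    "ComparisonSummary",
    "select_genes",
    "fit_predict_survival_forest",
    "misclassification_rate",
    "run_comparison",
    "summarize_comparison",
    "results_to_frame",
]


@dataclass
class RepeatResult:
    repeat_index: int
    assumption: Assumption
    selected_gene_ids: list[str]
    misclassification_rate: float
    n_test_evaluable: int
    partition_hash: str
    error: str | None = None


@dataclass
class ComparisonSummary:
    """Paired shape-vs-symmetric summary over repeats.

    ``wins`` counts repeats where the shape rate was less than or equal to
    the symmetric rate (ties counted inside wins, reported separately).
    Box statistics per assumption follow the notched-boxplot convention:
    median, IQR, and median +/- 1.58 * IQR / sqrt(n).
    """

    n_repeats: int
    rates: dict[str, np.ndarray]
    wins: int
    ties: int
    wilcoxon_p: float
    box_stats: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "wins_shape_le_symmetric": self.wins,
            "ties": self.ties,
            "wilcoxon_p": self.wilcoxon_p,
            "mean_rates": {k: float(np.mean(v)) for k, v in self.rates.items()},
            "box_stats": self.box_stats,
        }


def select_genes(
    train_expr: ExpressionMatrix,
    train_surv: SurvivalTable,
    cfg: AnalysisConfig,
    assumption: Assumption | str,
    seed,
) -> list[str]:
    """Pick the k genes fed to the forest, using training data only.

    Shape: classify the training matrix, scan with family-specific splits,
    take the k smallest log-rank p-values.  Symmetric: same but uniform
    two-tail splits and no classification.  Random: k genes uniformly
    without replacement.
    """
    assumption = Assumption(assumption)
    k = cfg.n_selected_genes
    if assumption is Assumption.RANDOM:
        rng = np.random.default_rng(seed)
        k = min(k, train_expr.n_genes)
        return list(rng.choice(train_expr.gene_ids, size=k, replace=False))
    if assumption is Assumption.SHAPE:
        calls, _ = classify_matrix(train_expr, cfg)
        scan = prognostic_scan(train_expr, calls, train_surv, cfg, Assumption.SHAPE)
    else:
        scan = prognostic_scan(train_expr, None, train_surv, cfg, Assumption.SYMMETRIC)
    if scan.empty:
        raise ValueError(f"no testable genes under the {assumption.value} assumption")
    scan = scan.sort_values(["p", "gene_id"], kind="stable")
    if len(scan) < k:
        logger.warning(
            "only %d testable genes for k=%d under %s; using all",
            len(scan), k, assumption.value,
        )
        k = len(scan)
    return list(scan["gene_id"].iloc[:k])


def _fit_forest(train_X: pd.DataFrame, train_surv: SurvivalTable, n_trees: int, seed: int):
    from sksurv.ensemble import RandomSurvivalForest
    from sksurv.util import Surv

    if train_X.shape[1] < 2:
        raise ValueError("survival forest needs at least 2 features")
    if train_surv.n_samples < 10 or int(train_surv.event.sum()) < 2:
        raise ValueError("survival forest needs >= 10 training samples with >= 2 events")
    y = Surv.from_arrays(train_surv.event.astype(bool), train_surv.time)
    forest = RandomSurvivalForest(
        n_estimators=n_trees, random_state=int(seed) % (2**31 - 1), n_jobs=1
    )
    forest.fit(train_X, y)
    return forest


def fit_predict_survival_forest(
    train_expr_subset: pd.DataFrame,
    train_surv: SurvivalTable,
    test_expr_subset: pd.DataFrame,
    n_trees: int,
    seed: int,
) -> np.ndarray:
    """Train a random survival forest; return a risk score per test sample.

    Trees are grown on bootstrap resamples with a log-rank split rule and
    random feature subsetting; the score is the ensemble mortality (higher
    means worse predicted survival).  Deterministic given the seed.
    """
    forest = _fit_forest(train_expr_subset, train_surv, n_trees, seed)
    return np.asarray(forest.predict(test_expr_subset), dtype=float)


def misclassification_rate(
    risk: np.ndarray,
    test_surv: SurvivalTable,
    t_med: float,
    risk_threshold: float,
) -> tuple[float, int]:
    """Fraction of evaluable test patients whose good/poor call is wrong.

    Observed label: poor if the patient died at or before ``t_med`` (the
    training-set median observed time); good if their time exceeds ``t_med``
    (dead or censored); censored at or before ``t_med`` the status is
    indeterminate and the patient is excluded.  Predicted label: poor iff
    risk exceeds ``risk_threshold`` (the median training risk).
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (test_surv.n_samples,):
        raise ValueError("risk must be defined for every test sample")
    observed_poor = (test_surv.event == 1) & (test_surv.time <= t_med)
    observed_good = test_surv.time > t_med
    evaluable = observed_poor | observed_good
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise ValueError("no evaluable test samples (all censored before the cutoff)")
    predicted_poor = risk > risk_threshold
    errors = int(np.sum(predicted_poor[evaluable] != observed_poor[evaluable]))
    return errors / n_eval, n_eval


def _partition_hash(train_ids: list[str]) -> str:
    return hashlib.sha1("\x1f".join(sorted(train_ids)).encode()).hexdigest()[:12]


def run_comparison(
    expr: ExpressionMatrix, surv: SurvivalTable, cfg: AnalysisConfig
) -> list[RepeatResult]:
    """The full repeated train/test protocol for the three assumptions.

    Per repeat: one seeded 2/3-1/3 sample partition shared by all three
    assumptions; per assumption: gene selection on the training portion,
    forest fit, misclassification on the held-out third.  Failures inside a
    repeat are recorded as flagged results, not raised.
    """
    if expr.sample_ids != surv.sample_ids:
        raise ValueError("cohort must be aligned before comparison")
    n = expr.n_samples
    if n < 60:
        raise ValueError("comparison protocol needs at least 60 samples")
    ss = np.random.SeedSequence(cfg.rng_seed)
    repeat_seeds = ss.spawn(cfg.n_repeats)
    results: list[RepeatResult] = []
    for r in range(cfg.n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        perm = rng.permutation(n)
        n_train = (2 * n) // 3
        train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
        train_ids = [expr.sample_ids[i] for i in train_idx]
        test_ids = [expr.sample_ids[i] for i in test_idx]
        phash = _partition_hash(train_ids)
        train_expr = expr.subset_samples(train_ids)
        test_expr = expr.subset_samples(test_ids)
        train_surv = surv.subset(train_ids)
        test_surv = surv.subset(test_ids)
        t_med = float(np.median(train_surv.time))
        sel_seed, forest_seed = rng.integers(0, 2**31 - 1, size=2)
        cfg_r = cfg.with_(rng_seed=int(sel_seed))
        for assumption in (Assumption.SHAPE, Assumption.SYMMETRIC, Assumption.RANDOM):
            try:
                genes = select_genes(train_expr, train_surv, cfg_r, assumption, int(sel_seed))
                train_X = train_expr.subset_genes(genes).to_frame().T
                test_X = test_expr.subset_genes(genes).to_frame().T
                forest = _fit_forest(train_X, train_surv, cfg.n_trees, int(forest_seed))
                risk_train = np.asarray(forest.predict(train_X), dtype=float)
                risk_test = np.asarray(forest.predict(test_X), dtype=float)
                rate, n_eval = misclassification_rate(
                    risk_test, test_surv, t_med, float(np.median(risk_train))
                )
                results.append(
                    RepeatResult(r, assumption, genes, rate, n_eval, phash)
                )
            except ValueError as exc:
                logger.warning("repeat %d %s failed: %s", r, assumption.value, exc)
                results.append(
                    RepeatResult(r, assumption, [], float("nan"), 0, phash, str(exc))
                )
    return results


def summarize_comparison(results: list[RepeatResult]) -> ComparisonSummary:
    """Pair shape and symmetric rates per repeat; count wins, test with Wilcoxon."""
    by_assumption: dict[str, dict[int, float]] = {}
    for res in results:
        if res.error is None:
            by_assumption.setdefault(res.assumption.value, {})[res.repeat_index] = (
                res.misclassification_rate
            )
    shape = by_assumption.get(Assumption.SHAPE.value, {})
    sym = by_assumption.get(Assumption.SYMMETRIC.value, {})
    common = sorted(set(shape) & set(sym))
    if not common:
        raise ValueError("no repeats with both shape and symmetric results")
    s = np.array([shape[i] for i in common])
    y = np.array([sym[i] for i in common])
    wins = int(np.sum(s <= y))
    ties = int(np.sum(s == y))
    diffs = s - y
    if np.all(diffs == 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(s, y).pvalue)
    rates = {
        k: np.array([v[i] for i in sorted(v)]) for k, v in by_assumption.items()
    }
    box_stats = {}
    for k, v in rates.items():
        q1, med, q3 = np.percentile(v, (25, 50, 75))
        iqr = q3 - q1
        notch = 1.58 * iqr / np.sqrt(len(v))
        box_stats[k] = {
            "median": float(med),
            "iqr": float(iqr),
            "notch_low": float(med - notch),
            "notch_high": float(med + notch),
        }
    return ComparisonSummary(
        n_repeats=len(common),
        rates=rates,
        wins=wins,
        ties=ties,
        wilcoxon_p=wilcoxon_p,
        box_stats=box_stats,
    )


def results_to_frame(results: list[RepeatResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "repeat": r.repeat_index,
            "assumption": r.assumption.value,
            "k": len(r.selected_gene_ids),
            "rate": r.misclassification_rate,
            "n_evaluable": r.n_test_evaluable,
            "partition_hash": r.partition_hash,
            "error": r.error or "",
        }
        for r in results
    )
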
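"""Classifier-comparison protocol: selection, forest, misclassification,
paired repeats and summary."""

import numpy as np
import pandas as pd
import pytest

from exprshape.compare import (
    RepeatResult,
    fit_predict_survival_forest,
    misclassification_rate,
    run_comparison,
    select_genes,
    summarize_comparison,
    results_to_frame,
)
from exprshape.data import AnalysisConfig, ExpressionMatrix, Scale, SurvivalTable
from exprshape.survival import Assumption


def _planted_cohort(rng, n=90, n_noise=8):
    """Small cohort with one strongly prognostic bimodal gene."""
    ids = [f"S{i}" for i in range(n)]
    comp = rng.random(n) < 0.5
    planted = np.where(comp, 8.0, 0.0) + 0.6 * rng.standard_normal(n)
    noise = 10 + rng.standard_normal((n_noise, n))
    values = np.vstack([planted, noise])
    genes = ["planted"] + [f"noise{i}" for i in range(n_noise)]
    h = np.where(comp, 5.0, 1.0) * 0.01
    time = rng.exponential(1 / h)
    surv = SurvivalTable(ids, time, np.ones(n, dtype=int))
    return ExpressionMatrix(genes, ids, values, Scale.LOG2), surv, comp


class TestSelectGenes:
    def test_random_selection_deterministic(self, fast_cfg, rng):
        expr, surv, _ = _planted_cohort(rng)
        a = select_genes(expr, surv, fast_cfg, Assumption.RANDOM, 3)
        b = select_genes(expr, surv, fast_cfg, Assumption.RANDOM, 3)
        assert a == b
        assert len(a) == fast_cfg.n_selected_genes

    def test_shape_selection_finds_planted_gene(self, fast_cfg, rng):
        expr, surv, _ = _planted_cohort(rng)
        genes = select_genes(expr, surv, fast_cfg, Assumption.SHAPE, 3)
        assert "planted" in genes

    def test_shape_and_symmetric_differ_on_bimodal_signal(self, fast_cfg, rng):
        expr, surv, _ = _planted_cohort(rng)
        cfg = fast_cfg.with_(n_selected_genes=2)
        shape = select_genes(expr, surv, cfg, Assumption.SHAPE, 3)
        sym = select_genes(expr, surv, cfg, Assumption.SYMMETRIC, 3)
        assert shape != sym or shape[0] == "planted"


class TestForest:
    def test_risk_tracks_planted_group(self, rng):
        expr, surv, comp = _planted_cohort(rng, n=120)
        X = expr.to_frame().T
        train, test = X.iloc[:80], X.iloc[80:]
        risk = fit_predict_survival_forest(
            train, surv.subset(list(train.index)), test, n_trees=100, seed=5
        )
        from scipy.stats import spearmanr

        rho = spearmanr(risk, comp[80:]).statistic
        assert rho >= 0.5

    def test_seed_determinism_and_order_equivariance(self, rng):
        expr, surv, _ = _planted_cohort(rng, n=100)
        X = expr.to_frame().T
        train, test = X.iloc[:70], X.iloc[70:]
        tr_surv = surv.subset(list(train.index))
        r1 = fit_predict_survival_forest(train, tr_surv, test, 50, seed=9)
        r2 = fit_predict_survival_forest(train, tr_surv, test, 50, seed=9)
        assert np.array_equal(r1, r2)
        perm = rng.permutation(len(test))
        r3 = fit_predict_survival_forest(train, tr_surv, test.iloc[perm], 50, seed=9)
        assert np.allclose(r3, r1[perm])

    def test_no_events_rejected(self, rng):
        expr, surv, _ = _planted_cohort(rng, n=60)
        X = expr.to_frame().T
        dead_surv = SurvivalTable(surv.sample_ids[:40], surv.time[:40], np.zeros(40, dtype=int))
        with pytest.raises(ValueError):
            fit_predict_survival_forest(X.iloc[:40], dead_surv, X.iloc[40:], 20, 0)


class TestMisclassification:
    def _surv(self, times, events):
        return SurvivalTable(
            [f"S{i}" for i in range(len(times))],
            np.asarray(times, float),
            np.asarray(events, int),
        )

    def test_perfect_and_flipped(self):
        surv = self._surv([1, 2, 10, 20], [1, 1, 1, 1])
        risk = np.array([9.0, 8.0, 1.0, 2.0])  # poor, poor, good, good
        rate, n = misclassification_rate(risk, surv, t_med=5.0, risk_threshold=5.0)
        assert rate == 0.0 and n == 4
        rate, _ = misclassification_rate(risk[::-1], surv, t_med=5.0, risk_threshold=5.0)
        assert rate == 1.0

    def test_censored_before_cutoff_excluded(self):
        surv = self._surv([1, 2, 10], [0, 1, 1])  # first censored pre-cutoff
        risk = np.array([0.0, 9.0, 0.0])
        rate, n = misclassification_rate(risk, surv, t_med=5.0, risk_threshold=5.0)
        assert n == 2 and rate == 0.0

    def test_all_censored_before_cutoff_is_error(self):
        surv = self._surv([1, 2], [0, 0])
        with pytest.raises(ValueError, match="evaluable"):
            misclassification_rate(np.array([1.0, 2.0]), surv, 5.0, 0.5)


class TestRunComparison:
    @pytest.fixture(scope="class")
    def results(self):
        rng = np.random.default_rng(77)
        expr, surv, _ = _planted_cohort(rng, n=90)
        cfg = AnalysisConfig(
            rng_seed=4, n_repeats=2, n_selected_genes=3, n_trees=25, n_bootstrap=49
        )
        return run_comparison(expr, surv, cfg), cfg

    def test_three_assumptions_per_repeat_rates_valid(self, results):
        res, cfg = results
        assert len(res) == 3 * cfg.n_repeats
        for r in res:
            if r.error is None:
                assert 0.0 <= r.misclassification_rate <= 1.0

    def test_partitions_shared_within_repeat(self, results):
        res, _ = results
        by_repeat = {}
        for r in res:
            by_repeat.setdefault(r.repeat_index, set()).add(r.partition_hash)
        for hashes in by_repeat.values():
            assert len(hashes) == 1

    def test_bit_reproducible_given_seed(self, results):
        res, cfg = results
        rng = np.random.default_rng(77)
        expr, surv, _ = _planted_cohort(rng, n=90)
        res2 = run_comparison(expr, surv, cfg)
        for a, b in zip(res, res2):
            assert a.misclassification_rate == b.misclassification_rate or (
                np.isnan(a.misclassification_rate) and np.isnan(b.misclassification_rate)
            )
            assert a.selected_gene_ids == b.selected_gene_ids


class TestSummary:
    def _mk(self, shape_rates, sym_rates):
        res = []
        for i, (s, y) in enumerate(zip(shape_rates, sym_rates)):
            res.append(RepeatResult(i, Assumption.SHAPE, ["g"], s, 10, "h"))
            res.append(RepeatResult(i, Assumption.SYMMETRIC, ["g"], y, 10, "h"))
        return res

    def test_identical_vectors_all_ties(self):
        s = summarize_comparison(self._mk([0.2] * 5, [0.2] * 5))
        assert s.wins == 5 and s.ties == 5
        assert s.wilcoxon_p == 1.0

    def test_uniform_shift_wins_everywhere(self):
        rng = np.random.default_rng(0)
        sym = rng.uniform(0.3, 0.5, 20)
        s = summarize_comparison(self._mk(list(sym - 0.1), list(sym)))
        assert s.wins == 20 and s.ties == 0
        assert s.wilcoxon_p < 0.01

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = list(rng.uniform(0.2, 0.6, 10))
        b = list(rng.uniform(0.2, 0.6, 10))
        s1 = summarize_comparison(self._mk(a, b))
        s2 = summarize_comparison(self._mk(b, a))
        assert s2.wins == 10 - s1.wins + s1.ties

    def test_notch_statistics_follow_convention(self):
        rates = list(np.linspace(0.1, 0.5, 20))
        s = summarize_comparison(self._mk(rates, rates))
        box = s.box_stats["shape"]
        q1, med, q3 = np.percentile(rates, (25, 50, 75))
        assert box["median"] == pytest.approx(med)
        assert box["notch_high"] == pytest.approx(med + 1.58 * (q3 - q1) / np.sqrt(20))

    def test_results_frame_schema(self):
        frame = results_to_frame(self._mk([0.1], [0.2]))
        assert list(frame.columns) == [
            "repeat", "assumption", "k", "rate", "n_evaluable", "partition_hash", "error"
        ]
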
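"""Patient splitting, log-rank (vs brute-force and lifelines oracles),
Kaplan-Meier, prognostic scans and the permutation null."""

import itertools

import numpy as np
import pytest

from exprshape.classify import fit_two_component_mixture
from exprshape.data import AnalysisConfig, ExpressionMatrix, Scale, SurvivalTable
from exprshape.distributions import Family
from exprshape.survival import (
    Assumption,
    SplitRule,
    km_estimate,
    logrank_from_arrays,
    logrank_test,
    prognostic_scan,
    random_split_null,
    split_patients,
)

from oracles import km_by_hand, logrank_brute_force


class TestSplitPatients:
    def test_two_tail_sizes_on_distinct_data(self, rng):
        x = rng.permutation(np.arange(100, dtype=float))
        split = split_patients(x, Family.NORMAL, tail_fraction=0.10)
        assert split.rule is SplitRule.TWO_TAIL
        assert split.n1 == 20  # 10 lowest + 10 highest
        extreme = set(np.argsort(x)[:10]) | set(np.argsort(x)[-10:])
        assert set(np.flatnonzero(split.in_group1)) == extreme

    def test_one_tail_upper_for_right_skew(self, rng):
        x = rng.gamma(2.0, 1.0, 100)
        while len(np.unique(x)) < 100:  # pragma: no cover
            x = rng.gamma(2.0, 1.0, 100)
        split = split_patients(x, Family.GAMMA, tail_fraction=0.10)
        assert split.rule is SplitRule.ONE_TAIL_UPPER
        assert split.n1 == 10
        assert set(np.flatnonzero(split.in_group1)) == set(np.argsort(x)[-10:])

    def test_one_tail_lower_for_left_skew(self, rng):
        x = -rng.gamma(2.0, 1.0, 100) + 100.0  # left-skewed positive data
        split = split_patients(x, Family.LOGNORMAL, tail_fraction=0.10)
        assert split.rule is SplitRule.ONE_TAIL_LOWER
        assert split.n1 == 10

    def test_mode_split_recovers_components(self, rng):
        comp = rng.random(200) < 0.5
        x = np.where(comp, 10.0, 0.0) + rng.standard_normal(200)
        fit = fit_two_component_mixture(x)
        split = split_patients(x, Family.BIMODAL, bifit=fit)
        assert split.rule is SplitRule.MODE
        clear = np.abs(x - 5.0) > 2.0  # away from the posterior boundary
        assert np.array_equal(split.in_group1[clear], comp[clear])

    def test_unknown_family_and_tied_cut_errors(self, rng):
        with pytest.raises(ValueError):
            split_patients(rng.standard_normal(50), Family.UNKNOWN)
        with pytest.raises(ValueError):
            split_patients(np.ones(50), Family.NORMAL)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.ones(6, dtype=int)
        g1 = np.array([True, True, True, False, False, False])
        res = logrank_from_arrays(time, event, g1)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_toy_example_matches_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        g1 = np.array([True, True, True, False, False, False])
        res = logrank_from_arrays(time, event, g1)
        chi2, p = logrank_brute_force(time, event, g1)
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-10)

    def test_rank_invariance_under_time_doubling(self, rng):
        time = rng.exponential(1.0, 40)
        event = rng.random(40) < 0.7
        g1 = rng.random(40) < 0.5
        if event.sum() == 0 or g1.all() or not g1.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        a = logrank_from_arrays(time, event, g1)
        b = logrank_from_arrays(2.0 * time, event, g1)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_matches_brute_force_with_ties_and_censoring(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 25))
            time = rng.integers(1, 6, n).astype(float)  # many ties
            event = (rng.random(n) < 0.6).astype(int)
            g1 = rng.random(n) < 0.5
            if event.sum() == 0 or g1.all() or not g1.any():
                continue
            res = logrank_from_arrays(time, event, g1)
            chi2, p = logrank_brute_force(time, event, g1)
            assert res.statistic == pytest.approx(chi2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(10):
            time = rng.exponential(10.0, 60)
            event = (rng.random(60) < 0.7).astype(int)
            g1 = rng.random(60) < 0.5
            res = logrank_from_arrays(time, event, g1)
            ll = ll_logrank(time[g1], time[~g1], event[g1], event[~g1])
            assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-9)
            assert res.p == pytest.approx(ll.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_from_arrays([1.0, 2.0], [0, 0], [True, False])

    def test_split_interface(self, rng):
        from exprshape.survival import PatientSplit

        ids = [f"S{i}" for i in range(30)]
        surv = SurvivalTable(ids, rng.exponential(5, 30), (rng.random(30) < 0.8).astype(int))
        split = PatientSplit(ids, np.arange(30) < 10, SplitRule.TWO_TAIL, (0.0,))
        res = logrank_test(split, surv)
        assert res.n1 == 10 and res.n2 == 20


class TestKaplanMeier:
    def test_three_events_by_hand(self):
        surv = SurvivalTable(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1])
        curve = km_estimate(surv)["all"]
        assert curve.loc[1.0] == pytest.approx(2 / 3)
        assert curve.loc[2.0] == pytest.approx(1 / 3)
        assert curve.loc[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        surv = SurvivalTable(["a", "b"], [5.0, 7.0], [0, 0])
        curve = km_estimate(surv)["all"]
        assert np.all(curve.values == 1.0)

    def test_censoring_shrinks_risk_set_without_step(self):
        surv = SurvivalTable(["a", "b"], [1.0, 2.0], [0, 1])
        curve = km_estimate(surv)["all"]
        assert curve.loc[2.0] == pytest.approx(0.0)  # risk set of 1 at t=2

    def test_matches_hand_product_limit(self, rng):
        time = rng.exponential(5.0, 50)
        event = (rng.random(50) < 0.6).astype(int)
        surv = SurvivalTable([f"s{i}" for i in range(50)], time, event)
        curve = km_estimate(surv)["all"]
        t_oracle, s_oracle = km_by_hand(time, event)
        for t, s in zip(t_oracle, s_oracle):
            assert curve.loc[t] == pytest.approx(s, abs=1e-12)


class TestPrognosticScan:
    def _cohort(self, rng, n=120):
        ids = [f"S{i}" for i in range(n)]
        comp = rng.random(n) < 0.5
        bimodal = np.where(comp, 8.0, 0.0) + 0.7 * rng.standard_normal(n)
        normal = 10 + rng.standard_normal(n)
        h = np.where(comp, 4.0, 1.0) * 0.01
        time = rng.exponential(1 / h)
        expr = ExpressionMatrix(["bim", "nor"], ids, np.vstack([bimodal, normal]), Scale.LOG2)
        surv = SurvivalTable(ids, time, np.ones(n, dtype=int))
        return expr, surv, comp

    def test_shape_scan_flags_planted_bimodal_gene(self, fast_cfg, rng):
        expr, surv, _ = self._cohort(rng)
        from exprshape.classify import classify_matrix

        calls, _ = classify_matrix(expr, fast_cfg)
        scan = prognostic_scan(expr, calls, surv, fast_cfg, Assumption.SHAPE)
        row = scan[scan.gene_id == "bim"].iloc[0]
        assert row["rule"] == "MODE"
        assert row["significant"]

    def test_symmetric_scan_uses_two_tail_everywhere(self, fast_cfg, rng):
        expr, surv, _ = self._cohort(rng)
        scan = prognostic_scan(expr, None, surv, fast_cfg, Assumption.SYMMETRIC)
        assert set(scan["rule"]) == {"TWO_TAIL"}
        assert len(scan) == 2

    def test_shape_and_symmetric_agree_for_normal_genes(self, fast_cfg, rng):
        expr, surv, _ = self._cohort(rng)
        from exprshape.classify import classify_matrix

        calls, _ = classify_matrix(expr, fast_cfg)
        shape = prognostic_scan(expr, calls, surv, fast_cfg, Assumption.SHAPE)
        sym = prognostic_scan(expr, None, surv, fast_cfg, Assumption.SYMMETRIC)
        normal_ids = [c.gene_id for c in calls if c.family is Family.NORMAL]
        for g in normal_ids:
            p_shape = shape.loc[shape.gene_id == g, "p"].iloc[0]
            p_sym = sym.loc[sym.gene_id == g, "p"].iloc[0]
            assert p_shape == pytest.approx(p_sym, rel=1e-12)


class TestRandomSplitNull:
    def test_determinism_and_label_symmetry(self, rng):
        n = 60
        ids = [f"S{i}" for i in range(n)]
        surv = SurvivalTable(ids, rng.exponential(5, n), np.ones(n, dtype=int))
        from exprshape.survival import PatientSplit

        splits = [
            PatientSplit(ids, rng.permutation(np.arange(n) < 30), SplitRule.TWO_TAIL, (0.0,))
            for _ in range(5)
        ]
        a = random_split_null(surv, splits, 20, seed=3)
        b = random_split_null(surv, splits, 20, seed=3)
        assert np.array_equal(a, b)
        # swapped labels on an equal split give the identical statistic
        res = logrank_from_arrays(surv.time, surv.event, splits[0].in_group1)
        res_swap = logrank_from_arrays(surv.time, surv.event, ~splits[0].in_group1)
        assert res.statistic == pytest.approx(res_swap.statistic, rel=1e-12)
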
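"""Deconvolution, correlation, group-comparison and survival statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from lifelines.statistics import logrank_test

from mpeco.ecosystem import (
    km_logrank,
    kruskal_dunn,
    nnls_deconvolve,
    optimal_cutpoint,
    spearman,
)


def _signature(rng, n_genes=100, states=("epi", "stroma", "immune")):
    sig = pd.DataFrame(rng.uniform(0.1, 5.0, size=(n_genes, len(states))),
                       index=[f"g{i}" for i in range(n_genes)], columns=list(states))
    return sig


class TestDeconvolution:
    def test_pure_state_bulk_recovers_unit_proportion(self, rng):
        sig = _signature(rng)
        bulk = pd.DataFrame([sig["stroma"].to_numpy()], columns=sig.index, index=["B1"])
        res = nnls_deconvolve(bulk, sig)
        assert res.proportions.loc["B1", "stroma"] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_mixture_recovered_exactly(self, rng):
        sig = _signature(rng)
        props = np.array([[0.3, 0.7, 0.0], [0.2, 0.3, 0.5]])
        bulk = pd.DataFrame(props @ sig.T.to_numpy(), columns=sig.index, index=["B1", "B2"])
        res = nnls_deconvolve(bulk, sig)
        np.testing.assert_allclose(res.proportions.to_numpy(), props, atol=1e-6)

    def test_noisy_mixtures_small_mean_error(self, rng):
        sig = _signature(rng, n_genes=150)
        props = rng.dirichlet([2, 2, 2], size=50)
        bulk = props @ sig.T.to_numpy() + rng.normal(0, 0.1, size=(50, 150))
        bulk = pd.DataFrame(np.maximum(bulk, 0), columns=sig.index)
        res = nnls_deconvolve(bulk, sig)
        mae = np.abs(res.proportions.to_numpy() - props).mean()
        assert mae <= 0.05

    def test_proportions_live_on_simplex(self, rng):
        sig = _signature(rng)
        bulk = pd.DataFrame(rng.uniform(0, 5, size=(10, 100)), columns=sig.index)
        res = nnls_deconvolve(bulk, sig)
        assert (res.proportions.to_numpy() >= 0).all()
        np.testing.assert_allclose(res.proportions.sum(axis=1), 1.0, atol=1e-8)

    def test_single_state_rejected(self, rng):
        sig = _signature(rng, states=("only",))
        bulk = pd.DataFrame(rng.uniform(0, 5, size=(2, 100)), columns=sig.index)
        with pytest.raises(ValueError):
            nnls_deconvolve(bulk, sig)


class TestSpearman:
    def test_perfect_monotone_extremes(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0, 9.0])
        assert spearman(x, x).R == pytest.approx(1.0)
        assert spearman(x, -x).R == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_at_n6(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = spearman(x, y)
        rx = scipy.stats.rankdata(x)
        ry = scipy.stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        rhos = [np.corrcoef(rx, np.array(p))[0, 1] for p in itertools.permutations(ry)]
        expected = np.mean(np.abs(rhos) >= abs(obs) - 1e-12)
        assert res.p == pytest.approx(expected, abs=1e-12)
        assert res.R == pytest.approx(obs)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        a = spearman(x, y)
        assert a.R == pytest.approx(spearman(y, x).R)
        assert a.R == pytest.approx(spearman(np.exp(x), y).R)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman(np.ones(10), np.arange(10.0))


class TestKruskalDunn:
    def test_hand_computed_h_on_ranks_one_to_six(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        groups = np.array(["a", "a", "b", "b", "c", "c"])
        omnibus, _ = kruskal_dunn(values, groups, alpha=0.05)
        # mean ranks 1.5 / 3.5 / 5.5 -> H = 12/(6*7) * 2*(4 + 0 + 4) = 32/7
        assert omnibus["H"] == pytest.approx(32 / 7)

    def test_gatekeeping_empty_posthoc_when_omnibus_ns(self, rng):
        values = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        omnibus, table = kruskal_dunn(values, groups, alpha=1e-6)
        assert omnibus["p"] >= 1e-6
        assert table.empty

    def test_posthoc_bh_adjusted_and_separated_groups_found(self, rng):
        values = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(8, 1, 15)])
        groups = np.repeat(["a", "b", "c"], 15)
        omnibus, table = kruskal_dunn(values, groups)
        assert omnibus["p"] < 0.05
        sig = table[table["p_adj"] < 0.05]
        pairs = {frozenset((r.group_a, r.group_b)) for r in sig.itertuples()}
        assert frozenset(("a", "c")) in pairs and frozenset(("b", "c")) in pairs

    def test_small_group_dropped_with_warning(self, rng):
        values = np.concatenate([rng.normal(size=10), rng.normal(size=10), rng.normal(size=10), [1.0]])
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10 + ["d"])
        with pytest.warns(UserWarning):
            omnibus, _ = kruskal_dunn(values, groups)
        assert set(omnibus["groups"]) == {"a", "b", "c"}


class TestLogrank:
    def test_six_subject_toy_matches_hand_tables(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.ones(6, dtype=bool)
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        res = km_logrank(times, events, groups)
        # hand computation: O_A = 3, E_A = 0.5 + 0.4 + 0.25 = 1.15,
        # V = 0.25 + 0.24 + 0.1875 = 0.6775
        assert res.logrank_chi2 == pytest.approx((3 - 1.15) ** 2 / 0.6775)
        oracle = logrank_test(times[:3], times[3:], events[:3], events[3:])
        assert res.logrank_chi2 == pytest.approx(oracle.test_statistic)
        assert res.p == pytest.approx(oracle.p_value)

    def test_matches_lifelines_with_censoring(self, rng):
        times = rng.exponential(10, size=40)
        events = rng.random(40) < 0.7
        groups = np.repeat(["A", "B"], 20)
        res = km_logrank(times, events, groups)
        oracle = logrank_test(times[:20], times[20:], events[:20], events[20:])
        assert res.logrank_chi2 == pytest.approx(oracle.test_statistic, rel=1e-10)

    def test_km_curve_product_limit_drop(self):
        times = np.array([2.0, 5.0, 9.0, 1.0, 4.0, 7.0])
        events = np.array([True, False, False, True, True, False])
        groups = np.array(["A", "A", "A", "B", "B", "B"])
        res = km_logrank(times, events, groups)
        curve = res.km_curves["A"].set_index("time")["survival"]
        # single death at t=2 among 3 at risk: survival drops to 2/3
        assert curve.loc[2.0] == pytest.approx(2 / 3)

    def test_zero_event_group_flagged(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, False, False])
        groups = np.array(["A", "A", "B", "B"])
        res = km_logrank(times, events, groups)
        assert res.flags.get("no_events_B")
        assert 0 <= res.p <= 1


class TestOptimalCutpoint:
    def test_perfect_separation_finds_the_gap(self, rng):
        score = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(3, 4, 20)])
        times = np.concatenate([rng.exponential(1, 20), 20 + rng.exponential(1, 20)])
        events = np.ones(40, dtype=bool)
        out = optimal_cutpoint(score, times, events)
        groups = out["optimal"].groups.to_numpy()
        true_high = score >= 3.0
        agreement = ((groups == "high") == true_high).mean()
        assert agreement >= 0.95
        assert out["optimal"].p < 1e-6

    def test_min_prop_half_degenerates_to_median(self, rng):
        score = rng.normal(size=30)
        times = rng.exponential(5, size=30)
        events = np.ones(30, dtype=bool)
        out = optimal_cutpoint(score, times, events, min_prop=0.5)
        med_groups = np.where(score > np.median(score), "high", "low")
        direct = km_logrank(times, events, med_groups)
        assert out["optimal"].p == pytest.approx(direct.p) or out["median"].p == pytest.approx(direct.p)

    def test_anticonservative_null_rejection_rate(self):
        """Without correction the maximally selected p rejects far too often."""
        rejections = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            score = rng.normal(size=40)
            times = rng.exponential(5, size=40)
            events = np.ones(40, dtype=bool)
            out = optimal_cutpoint(score, times, events)
            if out["optimal"].p < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.15
        assert out["anti_conservative_p"]

    def test_requires_minimum_subjects(self):
        with pytest.raises(ValueError):
            optimal_cutpoint(np.arange(5.0), np.arange(1.0, 6.0), np.ones(5, dtype=bool))
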
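"""Rank-based signature scoring, ssGSEA and the DE filter against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from mpeco.scoring import (
    ScoreMatrix,
    assign_state,
    de_genes,
    ssgsea_score,
    ucell_score,
    ucell_scores_matrix,
)


def brute_force_ucell(values: pd.Series, signature, rank_cap=1500):
    """Independent oracle: explicit rank-sum computation."""
    ranks = pd.Series(
        scipy.stats.rankdata(-values.to_numpy(), method="average"), index=values.index
    )
    n = len(signature)
    total = 0.0
    for g in signature:
        r = ranks.get(g, rank_cap + 1)
        total += min(r, rank_cap + 1)
    u = total - n * (n + 1) / 2
    return max(0.0, 1.0 - u / (n * rank_cap))


class TestUCell:
    def test_top_ranked_signature_scores_one(self):
        expr = pd.Series(np.arange(100, 0, -1, dtype=float), index=[f"g{i}" for i in range(100)])
        assert ucell_score(expr, [f"g{i}" for i in range(5)]) == pytest.approx(1.0)

    def test_fully_unexpressed_signature_closed_form(self):
        """10 missing genes at rank cap+1: U' = 10*1501 - 55, score = 0.0030."""
        expr = pd.Series(np.arange(50, 0, -1, dtype=float), index=[f"g{i}" for i in range(50)])
        score = ucell_score(expr, [f"absent{i}" for i in range(10)], rank_cap=1500)
        expected = max(0.0, 1.0 - (10 * 1501 - 55) / (10 * 1500))
        assert score == pytest.approx(expected)
        assert score == pytest.approx(0.003, abs=1e-12)

    def test_matches_brute_force_oracle_exactly(self, rng):
        genes = [f"g{i}" for i in range(200)]
        for trial in range(20):
            vals = pd.Series(rng.poisson(2.0, size=200).astype(float), index=genes)
            sig = list(rng.choice(genes, size=10, replace=False))
            assert ucell_score(vals, sig, rank_cap=150) == pytest.approx(
                brute_force_ucell(vals, sig, rank_cap=150), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        genes = [f"g{i}" for i in range(300)]
        vals = pd.Series(rng.gamma(2, 2, size=300), index=genes)
        sig = list(rng.choice(genes, size=12, replace=False))
        s1 = ucell_score(vals, sig)
        s2 = ucell_score(np.log1p(vals * 100), sig)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_matrix_scores_in_unit_interval_and_stable_to_extra_signature(self, rng):
        genes = [f"g{i}" for i in range(100)]
        expr = pd.DataFrame(rng.poisson(1.0, size=(30, 100)).astype(float),
                            columns=genes)
        sigs = {"a": genes[:10], "b": genes[50:60]}
        s1 = ucell_scores_matrix(expr, sigs, rank_cap=80)
        assert ((s1 >= 0) & (s1 <= 1)).all().all()
        s2 = ucell_scores_matrix(expr, {**sigs, "c": genes[20:25]}, rank_cap=80)
        pd.testing.assert_series_equal(s1["a"], s2["a"])
        pd.testing.assert_series_equal(s1["b"], s2["b"])

    def test_empty_signature_rejected(self):
        expr = pd.Series([1.0], index=["g0"])
        with pytest.raises(ValueError):
            ucell_score(expr, [])


class TestAssignState:
    @pytest.mark.parametrize(
        "scores,min_score,margin,expected",
        [
            ((0.9, 0.1), 0.2, 0.0, "A"),
            ((0.15, 0.1), 0.2, 0.0, "unassigned"),
            ((0.5, 0.5), 0.0, 0.0, "unassigned"),
            ((0.6, 0.55), 0.2, 0.1, "unassigned"),
            ((0.6, 0.4), 0.2, 0.1, "A"),
        ],
    )
    def test_rules(self, scores, min_score, margin, expected):
        sm = ScoreMatrix(scores=pd.DataFrame([list(scores)], columns=["A", "B"]))
        out = assign_state(sm, min_score=min_score, margin=margin)
        assert out.iloc[0] == expected


class TestSSGSEA:
    def test_all_genes_set_degenerates_to_zero(self):
        expr = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        assert ssgsea_score(expr, ["a", "b", "c"]) == 0.0

    def test_top_placement_beats_bottom_placement(self):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.Series(np.arange(30, 0, -1, dtype=float), index=genes)
        top = ssgsea_score(expr, genes[:4])
        bottom = ssgsea_score(expr, genes[-4:])
        assert top > bottom

    def test_twenty_gene_toy_matches_hand_running_sum(self):
        genes = [f"g{i:02d}" for i in range(20)]
        expr = pd.Series(np.arange(20, 0, -1, dtype=float), index=genes)
        gene_set = [genes[1], genes[4], genes[10], genes[15]]
        alpha = 0.25
        # independent running-sum computation
        in_set = np.isin(np.arange(20), [1, 4, 10, 15])
        w = np.where(in_set, (20 - np.arange(20)) ** alpha, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set) / 16
        expected = float(np.sum(p_in - p_out))
        assert ssgsea_score(expr, gene_set, alpha=alpha) == pytest.approx(expected, abs=1e-12)

    def test_empty_overlap_rejected(self):
        expr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ssgsea_score(expr, ["zz"])


class TestDEGenes:
    def test_identical_groups_have_no_survivors(self, rng):
        block = rng.poisson(2.0, size=(10, 30)).astype(float)
        expr = pd.DataFrame(np.vstack([block, block]), columns=[f"g{i}" for i in range(30)])
        labels = np.array([True] * 10 + [False] * 10)
        table = de_genes(expr, labels)
        assert table["significant"].sum() == 0

    def test_engineered_toy_passes_and_fails_the_right_filters(self, rng):
        """3 genes pass all filters; 3 fail exactly one filter each."""
        n = 40
        labels = np.array([True] * n + [False] * n)
        cols = {}
        for i in range(3):  # clear hits: strong fold change, detection shift
            v = np.concatenate([rng.uniform(4, 6, n), np.zeros(n)])
            cols[f"hit{i}"] = v
        # fails d: expressed everywhere (d = 0) but higher in-group
        cols["fail_d"] = np.concatenate([rng.uniform(40, 60, n), rng.uniform(1, 2, n)])
        # fails log2fc: modest 1.5-fold shift (log2 ~ 0.58 < 1.2) but well detected
        cols["fail_fc"] = np.concatenate([rng.uniform(2.9, 3.1, n), np.concatenate([rng.uniform(1.9, 2.1, n - 12), np.zeros(12)])])
        # fails p: one outlier cell only
        v = np.zeros(2 * n)
        v[0] = 100.0
        cols["fail_p"] = v
        expr = pd.DataFrame(cols)
        table = de_genes(expr, labels)
        assert set(table.index[table["significant"]]) == {"hit0", "hit1", "hit2"}
        assert table.loc["fail_d", "d"] <= 0.4
        assert table.loc["fail_fc", "log2fc"] <= 1.2
        assert table.loc["fail_fc", "d"] > 0.0
        assert table.loc["fail_p", "p_adj"] >= 0.05

    def test_wilcoxon_p_matches_full_enumeration(self, rng):
        """n = (4, 4): p equals the exact permutation distribution over C(8,4)."""
        x = np.array([1.2, 3.4, 0.5, 2.2])
        y = np.array([4.1, 5.0, 0.9, 6.3])
        expr = pd.DataFrame({"g": np.concatenate([x, y]), "pad": np.arange(8, dtype=float)})
        labels = np.array([True] * 4 + [False] * 4)
        table = de_genes(expr, labels)
        ranks = scipy.stats.rankdata(np.concatenate([x, y]))
        obs_u = ranks[:4].sum() - 10
        us = np.array([
            ranks[list(comb)].sum() - 10 for comb in itertools.combinations(range(8), 4)
        ])
        expected = min(1.0, 2 * min((us >= obs_u).mean(), (us <= obs_u).mean()))
        assert table.loc["g", "p"] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_gets_p_one(self):
        expr = pd.DataFrame({"flat": np.ones(20), "var": np.arange(20, dtype=float)})
        labels = np.array([True] * 10 + [False] * 10)
        table = de_genes(expr, labels)
        assert table.loc["flat", "p"] == 1.0

    def test_invariants_and_threshold_monotonicity(self, rng):
        expr = pd.DataFrame(rng.poisson(1.5, size=(60, 50)).astype(float),
                            columns=[f"g{i}" for i in range(50)])
        expr.iloc[:30, :5] *= 8
        labels = np.array([True] * 30 + [False] * 30)
        loose = de_genes(expr, labels, p_adj_max=0.2, log2fc_min=0.5, d_min=0.1)
        strict = de_genes(expr, labels, p_adj_max=0.05, log2fc_min=1.2, d_min=0.4)
        assert (loose["p_adj"] >= loose["p"] - 1e-15).all()
        assert loose["d"].between(-1, 1).all()
        strict_set = set(strict.index[strict["significant"]])
        loose_set = set(loose.index[loose["significant"]])
        assert strict_set <= loose_set

    def test_small_groups_rejected(self):
        expr = pd.DataFrame({"g": np.arange(4, dtype=float)})
        with pytest.raises(ValueError):
            de_genes(expr, np.array([True, True, False, False]))


class TestUCellProperties:
    """Property-based checks of the rank-sum score."""

    from hypothesis import given, settings, strategies as st

    @given(
        values=st.lists(
            st.one_of(st.just(0.0), st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)),
            min_size=20, max_size=60,
        ),
        sig_idx=st.sets(st.integers(min_value=0, max_value=19), min_size=1, max_size=8),
        shift=st.floats(min_value=0.1, max_value=100, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_unit_interval_and_affine_invariance(self, values, sig_idx, shift):
        genes = [f"g{i}" for i in range(len(values))]
        expr = pd.Series(values, index=genes)
        sig = [genes[i] for i in sig_idx]
        s1 = ucell_score(expr, sig, rank_cap=30)
        assert 0.0 <= s1 <= 1.0
        # strictly increasing affine transform preserves all ranks
        s2 = ucell_score(expr * shift + 1.0, sig, rank_cap=30)
        assert s1 == pytest.approx(s2, abs=1e-12)
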
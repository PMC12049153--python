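"""CNV smoothing, scores, correlation and malignancy-call behaviour."""

import numpy as np
import pandas as pd
import pytest

from mpeco.cnv import (
    CNVProfile,
    classify_malignant,
    cnv_correlation,
    cnv_score,
    malignancy_statistic,
    smooth_cnv_profile,
)
from mpeco.io_qc import normalize_log_median
from mpeco.synthetic import SimulationConfig, generate_dataset, make_gene_annotation


def _profile(smoothed, n_ref=0):
    n = smoothed.shape[0]
    ids = [f"c{i}" for i in range(n)]
    return CNVProfile(
        smoothed=np.asarray(smoothed, dtype=float),
        cell_ids=ids,
        gene_order=[f"g{j}" for j in range(smoothed.shape[1])],
        reference_cell_ids=ids[:n_ref],
    )


class TestSmoothing:
    def test_cell_equal_to_reference_mean_is_flat(self):
        annot = make_gene_annotation(110)
        rng = np.random.default_rng(1)
        ref = rng.normal(2, 1, size=(30, 110))
        query = ref.mean(axis=0, keepdims=True)
        expr = np.vstack([ref, query])
        ids = [f"r{i}" for i in range(30)] + ["q"]
        prof = smooth_cnv_profile(expr, annot, ids, ids[:30], window=3)
        # the query residual is exactly the deviation of ref-mean from itself... zero
        np.testing.assert_allclose(prof.smoothed[-1], 0.0, atol=1e-12)

    def test_planted_doubling_shows_log2_unit_gain(self):
        annot = make_gene_annotation(440)  # 20 genes per chromosome
        arms = (annot.table["chromosome"] + annot.table["arm"]).to_numpy()
        base = np.full(440, 5.0)
        ref = np.tile(base, (20, 1))
        query = base.copy()
        query[arms == "chr5q"] += 1.0  # +1 in log2 = 2x dosage
        expr = np.vstack([ref, query[None, :]])
        ids = [f"r{i}" for i in range(20)] + ["q"]
        prof = smooth_cnv_profile(expr, annot, ids, ids[:20], window=5)
        order_arms = arms[annot.genome_order_index()]
        inside = prof.smoothed[-1][order_arms == "chr5q"]
        outside = prof.smoothed[-1][~np.isin(order_arms, ["chr5q", "chr5p"])]
        # interior of the gained arm sits ~= +1 after median-centering
        assert inside[2:-2].mean() == pytest.approx(1.0, abs=0.05)
        assert abs(outside.mean()) < 0.05

    def test_window_one_returns_centered_residuals(self):
        annot = make_gene_annotation(66)
        rng = np.random.default_rng(3)
        expr = rng.normal(0, 0.5, size=(25, 66))
        ids = [f"c{i}" for i in range(25)]
        prof = smooth_cnv_profile(expr, annot, ids, ids[:10], window=1, clip=10.0)
        order = annot.genome_order_index()
        resid = expr[:, order] - expr[:10][:, order].mean(axis=0)
        resid -= np.median(resid, axis=1, keepdims=True)
        np.testing.assert_allclose(prof.smoothed, resid, atol=1e-12)

    def test_translation_equivariance_on_unclipped_input(self):
        annot = make_gene_annotation(66)
        rng = np.random.default_rng(4)
        expr = rng.normal(0, 0.2, size=(25, 66))
        ids = [f"c{i}" for i in range(25)]
        prof1 = smooth_cnv_profile(expr, annot, ids, ids[:10], window=3, clip=50.0)
        shifted = expr.copy()
        shifted[20] += 0.7  # constant shift of one query cell
        prof2 = smooth_cnv_profile(shifted, annot, ids, ids[:10], window=3, clip=50.0)
        # after per-cell median-centering the constant shift vanishes
        np.testing.assert_allclose(prof1.smoothed[20], prof2.smoothed[20], atol=1e-10)

    def test_rejects_even_window_and_empty_reference(self):
        annot = make_gene_annotation(66)
        expr = np.zeros((25, 66))
        ids = [f"c{i}" for i in range(25)]
        with pytest.raises(ValueError):
            smooth_cnv_profile(expr, annot, ids, ids[:5], window=4)
        with pytest.raises(ValueError):
            smooth_cnv_profile(expr, annot, ids, [], window=3)
        with pytest.raises(ValueError, match="fewer than window"):
            smooth_cnv_profile(expr, annot, ids, ids[:5], window=101)


class TestScoreAndCorrelation:
    def test_score_closed_forms_and_oracle(self, rng):
        assert cnv_score(_profile(np.zeros((3, 10))))[0] == 0.0
        half = np.zeros((1, 10))
        half[0, :5] = 1.0
        assert cnv_score(_profile(half))[0] == pytest.approx(0.5)
        random = rng.normal(size=(8, 30))
        np.testing.assert_allclose(cnv_score(_profile(random)), (random**2).mean(axis=1))

    def test_score_invariant_to_gene_permutation(self, rng):
        tracks = rng.normal(size=(6, 40))
        perm = rng.permutation(40)
        np.testing.assert_allclose(
            cnv_score(_profile(tracks)), cnv_score(_profile(tracks[:, perm]))
        )

    def test_correlation_extremes(self, rng):
        base = rng.normal(size=30)
        tracks = np.vstack([base * 3] + [base] * 18 + [-base])
        prof = _profile(tracks)
        corr = cnv_correlation(prof, top_fraction=0.05)
        # top-score cell IS the consensus (top 5% of 20 cells = 1 cell)
        assert corr[0] == pytest.approx(1.0)
        assert corr[-1] == pytest.approx(-1.0)

    def test_correlation_matches_brute_force(self, rng):
        tracks = rng.normal(size=(300, 50))
        prof = _profile(tracks)
        corr = cnv_correlation(prof, top_fraction=0.05)
        score = (tracks**2).mean(axis=1)
        top = np.argsort(-score)[:15]
        consensus = tracks[top].mean(axis=0)
        for i in range(0, 300, 37):
            assert corr[i] == pytest.approx(np.corrcoef(tracks[i], consensus)[0, 1])

    def test_constant_track_flagged_zero(self):
        tracks = np.vstack([np.zeros(30)] + [np.random.default_rng(0).normal(size=(24, 30))])
        prof = _profile(tracks)
        corr = cnv_correlation(prof)
        assert corr[0] == 0.0
        assert prof.flags.get("constant_tracks", 0) >= 1


class TestClassification:
    def test_all_zero_profiles_never_called(self):
        prof = _profile(np.zeros((40, 30)), n_ref=15)
        assert not classify_malignant(prof, method="mixture").any()
        prof2 = _profile(np.zeros((40, 30)), n_ref=15)
        assert not classify_malignant(prof2, method="threshold").any()

    def test_threshold_rule_literal(self, rng):
        tracks = rng.normal(0, 0.1, size=(50, 30))
        tracks[40:] += rng.normal(0, 1.0, size=(10, 30))  # noisy aberrant cells
        prof = _profile(tracks, n_ref=30)
        calls = classify_malignant(prof, score_k=2.0, corr_min=0.3, method="threshold")
        ref_scores = prof.cnv_score[:30]
        thr = ref_scores.mean() + 2.0 * ref_scores.std()
        expected = (prof.cnv_score > thr) & (prof.cnv_correlation > 0.3)
        np.testing.assert_array_equal(calls, expected)

    def test_reference_only_data_yields_no_calls(self):
        """Aberration-free cells evaluated against a reference: >= 95% non-malignant."""
        cfg = SimulationConfig(n_samples=3, cells_per_sample=200, n_genes=1000,
                               program_gene_size=60, malignant_fraction=0.0, seed=31)
        em, annot, _ = generate_dataset(cfg)
        x = normalize_log_median(em)
        comp = em.cell_meta["compartment"]
        ref_ids = list(em.cell_meta.index[comp.isin(["stromal", "immune"])])
        prof = smooth_cnv_profile(x, annot, em.cell_ids, ref_ids, window=31)
        calls = classify_malignant(prof, method="mixture")
        assert calls.mean() <= 0.05

    def test_gained_arm_mean_exceeds_neutral_arms(self):
        cfg = SimulationConfig(n_samples=2, cells_per_sample=250, n_genes=1000,
                               program_gene_size=60, malignant_fraction=0.5, seed=37)
        em, annot, truth = generate_dataset(cfg)
        x = normalize_log_median(em)
        comp = em.cell_meta["compartment"]
        ref_ids = list(em.cell_meta.index[comp.isin(["stromal", "immune"])])
        prof = smooth_cnv_profile(x, annot, em.cell_ids, ref_ids, window=31)
        arms = (annot.table["chromosome"] + annot.table["arm"]).to_numpy()[annot.genome_order_index()]
        gained = np.isin(arms, list(truth.arm_dosage.columns))
        mal = truth.malignant_labels.to_numpy()
        assert prof.smoothed[mal][:, gained].mean() > prof.smoothed[mal][:, ~gained].mean()

    def test_detection_z_separates_malignant(self):
        """At the study conditions the detection statistic puts malignant
        cells several reference-null SDs above normal epithelial cells."""
        cfg = SimulationConfig(malignant_fraction=0.3, seed=41)
        em, annot, truth = generate_dataset(cfg)
        x = normalize_log_median(em)
        comp = em.cell_meta["compartment"]
        ref_ids = list(em.cell_meta.index[comp.isin(["stromal", "immune"])])
        prof = smooth_cnv_profile(x, annot, em.cell_ids, ref_ids, window=51)
        z = malignancy_statistic(prof)
        mal = truth.malignant_labels.to_numpy()
        epi = (comp == "epithelial").to_numpy()
        assert z[mal].mean() > z[epi & ~mal].mean() + 2.0
        assert abs(z[~epi].mean()) < 0.2
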
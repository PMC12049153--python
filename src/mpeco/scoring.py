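"""Per-cell and per-sample signature scoring plus the differential-expression filter.

``ucell_score`` is a rank-based (Mann-Whitney U) signature activity score in
[0, 1]: robust to sequencing depth and invariant under monotone transforms of
a cell's expression.  ``ssgsea_score`` is the single-sample enrichment
running-sum for bulk profiles.  ``de_genes`` applies a Wilcoxon rank-sum test
with Benjamini-Hochberg correction and the three-way filter on adjusted
p-value, log2 fold change and detection-fraction difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ScoreMatrix:
    scores: pd.DataFrame          # cell x signature, in [0, 1]
    assignment: pd.Series | None = None
    rank_cap: int = 1500


# ---------------------------------------------------------------------------
# UCell-style rank-sum scoring
# ---------------------------------------------------------------------------

def ucell_score(expr_cell: pd.Series, signature: list[str], rank_cap: int = 1500) -> float:
    """UCell-style score of one cell for one signature.

    Genes are ranked by descending expression with average ties; ranks beyond
    ``rank_cap`` (including signature genes absent from the matrix) are set
    to ``rank_cap + 1``.  With U' = sum of signature ranks - n(n+1)/2 the
    score is max(0, 1 - U' / (n * rank_cap)).
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    scores = ucell_scores_matrix(expr_cell.to_frame().T, {"sig": list(signature)}, rank_cap=rank_cap)
    return float(scores.iloc[0, 0])


def ucell_scores_matrix(
    expr: pd.DataFrame,
    signatures: dict[str, list[str]],
    rank_cap: int = 1500,
) -> pd.DataFrame:
    """Vectorized UCell scores for a cell x gene frame and several signatures."""
    if not signatures:
        raise ValueError("no signatures given")
    for name, sig in signatures.items():
        if len(sig) == 0:
            raise ValueError(f"signature {name!r} is empty")
    X = expr.to_numpy(dtype=np.float64)
    ranks = scipy.stats.rankdata(-X, axis=1, method="average")
    ranks = np.minimum(ranks, rank_cap + 1)
    col = {g: j for j, g in enumerate(expr.columns)}
    out = {}
    for name, sig in signatures.items():
        idx = [col[g] for g in sig if g in col]
        n = len(sig)
        missing = n - len(idx)
        rank_sum = ranks[:, idx].sum(axis=1) + missing * (rank_cap + 1)
        u = rank_sum - n * (n + 1) / 2.0
        out[name] = np.maximum(0.0, 1.0 - u / (n * rank_cap))
    return pd.DataFrame(out, index=expr.index)


def assign_state(scores: ScoreMatrix, min_score: float = 0.2, margin: float = 0.0) -> pd.Series:
    """Argmax state assignment with a floor and an optional winning margin.

    A cell is labelled with its top-scoring signature when the top score is
    at least ``min_score`` and beats the runner-up by at least ``margin``;
    exact ties and sub-threshold cells are "unassigned".
    """
    df = scores.scores
    if df.shape[1] < 1:
        raise ValueError("need at least one signature")
    vals = df.to_numpy()
    order = np.argsort(-vals, axis=1, kind="stable")
    best = vals[np.arange(len(df)), order[:, 0]]
    second = vals[np.arange(len(df)), order[:, 1]] if df.shape[1] > 1 else np.full(len(df), -np.inf)
    labels = np.asarray(df.columns)[order[:, 0]].astype(object)
    unassigned = (best < min_score) | (best - second < margin) | (best == second)
    labels[unassigned] = "unassigned"
    assignment = pd.Series(labels, index=df.index, name="assignment")
    scores.assignment = assignment
    return assignment


# ---------------------------------------------------------------------------
# single-sample GSEA
# ---------------------------------------------------------------------------

def ssgsea_score(bulk_sample: pd.Series, gene_set: list[str], alpha: float = 0.25) -> float:
    """Single-sample enrichment: running-sum difference of in-set and out-set ECDFs.

    Genes are ordered by descending expression; the in-set ECDF weights the
    gene at position i (1-based) by its rank value (N - i + 1) ** alpha, the
    out-set ECDF is uniform over non-set genes, and the score is the sum of
    the ECDF differences over all positions.  The degenerate all-genes set
    returns 0.
    """
    present = [g for g in gene_set if g in bulk_sample.index]
    if len(present) == 0:
        raise ValueError("gene set has no overlap with the measured genes")
    n = len(bulk_sample)
    if len(set(present)) >= n:
        return 0.0
    # descending expression; ties broken by gene id for determinism
    order = sorted(bulk_sample.index, key=lambda g: (-bulk_sample[g], g))
    in_set = np.array([g in set(present) for g in order])
    pos = np.arange(1, n + 1)
    weights = np.where(in_set, (n - pos + 1.0) ** alpha, 0.0)
    w_total = weights.sum()
    p_in = np.cumsum(weights) / w_total
    p_out = np.cumsum(~in_set) / (n - in_set.sum())
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(bulk: pd.DataFrame, gene_sets: dict[str, list[str]], alpha: float = 0.25, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA over a sample x gene matrix; min-max normalized across samples."""
    out = pd.DataFrame(
        {name: [ssgsea_score(bulk.loc[s], gs, alpha=alpha) for s in bulk.index] for name, gs in gene_sets.items()},
        index=bulk.index,
    )
    if normalize and len(bulk) > 1:
        rng_all = out.to_numpy().max() - out.to_numpy().min()
        if rng_all > 0:
            out = (out - out.to_numpy().min()) / rng_all
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def de_genes(
    expr: pd.DataFrame,
    in_group: np.ndarray,
    p_adj_max: float = 0.05,
    log2fc_min: float = 1.2,
    d_min: float = 0.4,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Wilcoxon rank-sum marker test with the three-way survivor filter.

    Per gene: two-sided Wilcoxon rank-sum on normalized expression between
    the in-group and the rest (exact null for small tie-free groups,
    tie-corrected normal approximation otherwise), Benjamini-Hochberg
    adjustment, log2 fold change of group means, and the detection-fraction
    difference d = pct_in - pct_out.  Survivors satisfy p_adj < ``p_adj_max``
    AND log2fc > ``log2fc_min`` AND d > ``d_min``.
    """
    in_group = np.asarray(in_group, dtype=bool)
    if in_group.sum() < 3 or (~in_group).sum() < 3:
        raise ValueError("both groups need at least 3 cells")
    X = expr.to_numpy(dtype=np.float64)
    xin, xout = X[in_group], X[~in_group]

    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(xin, xout, axis=0, alternative="two-sided", method="auto")
    p = np.asarray(res.pvalue, dtype=float)
    constant = X.max(axis=0) == X.min(axis=0)
    p[constant | ~np.isfinite(p)] = 1.0

    p_adj = multipletests(p, method="fdr_bh")[1]
    mean_in, mean_out = xin.mean(axis=0), xout.mean(axis=0)
    log2fc = np.log2((mean_in + eps) / (mean_out + eps))
    pct_in = (xin > 0).mean(axis=0)
    pct_out = (xout > 0).mean(axis=0)
    d = pct_in - pct_out
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "d": d,
        },
        index=expr.columns,
    )
    table["significant"] = (table["p_adj"] < p_adj_max) & (table["log2fc"] > log2fc_min) & (table["d"] > d_min)
    return table
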
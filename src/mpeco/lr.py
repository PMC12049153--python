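"""Cluster-level ligand-receptor interaction scoring with a permutation null.

The statistic follows the CellPhoneDB convention: for a (pair, sender state,
receiver state) triple, the ligand summary is the minimum over ligand
subunits of the mean normalized expression in sender cells (a complex is as
strong as its limiting subunit), the receptor summary is the analogue in
receiver cells, and the interaction score is their average — zeroed when
either molecule is expressed in fewer than ``min_frac`` of its state's
cells.  Significance comes from shuffling the state labels: one shared
shuffle per permutation round across all pairs, add-one p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class LRDatabase:
    """Ligand-receptor pair table; subunit lists model multimeric complexes."""

    pairs: list[tuple[str, list[str], list[str]]]

    def __post_init__(self) -> None:
        ids = [p[0] for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pair_ids must be unique")
        for pid, lig, rec in self.pairs:
            if not lig or not rec:
                raise ValueError(f"pair {pid}: subunit lists must be non-empty")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LRDatabase":
        df = pd.read_csv(path, sep="\t")
        pairs = [
            (row["pair_id"], row["ligand_subunits"].split(","), row["receptor_subunits"].split(","))
            for _, row in df.iterrows()
        ]
        return cls(pairs)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "pair_id": [p[0] for p in self.pairs],
                "ligand_subunits": [",".join(p[1]) for p in self.pairs],
                "receptor_subunits": [",".join(p[2]) for p in self.pairs],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def bundled_toy(cls) -> "LRDatabase":
        """Small built-in database for tests and demos (20 pairs, 2 complexes)."""
        with resources.as_file(resources.files("mpeco").joinpath("data/toy_lr_pairs.tsv")) as p:
            return cls.from_tsv(p)

    def genes(self) -> list[str]:
        out: set[str] = set()
        for _, lig, rec in self.pairs:
            out.update(lig)
            out.update(rec)
        return sorted(out)


def _state_summaries(expr: np.ndarray, pos: np.ndarray, labels: np.ndarray, states: list[str]):
    """Per-state mean expression and expressed fraction, genes restricted upstream."""
    means = np.empty((len(states), expr.shape[1]))
    fracs = np.empty_like(means)
    for i, s in enumerate(states):
        mask = labels == s
        means[i] = expr[mask].mean(axis=0)
        fracs[i] = pos[mask].mean(axis=0)
    return means, fracs


def _pair_statistic(
    means: np.ndarray, fracs: np.ndarray,
    lig_idx: list[int], rec_idx: list[int],
    sender_i: int, receiver_i: int, min_frac: float,
) -> float:
    """CellPhoneDB-style score; missing subunits enter as zero summaries."""
    if not lig_idx or not rec_idx:
        return 0.0
    lig_mean = means[sender_i, lig_idx].min()
    rec_mean = means[receiver_i, rec_idx].min()
    lig_frac = fracs[sender_i, lig_idx].min()
    rec_frac = fracs[receiver_i, rec_idx].min()
    if lig_frac < min_frac or rec_frac < min_frac:
        return 0.0
    return 0.5 * (lig_mean + rec_mean)


def interaction_mean(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    pair: tuple[str, list[str], list[str]],
    sender: str,
    receiver: str,
    min_frac: float = 0.1,
    min_cells: int = 10,
) -> float:
    """Observed interaction score for a single (pair, sender, receiver) triple."""
    labels = np.asarray(labels)
    for state in (sender, receiver):
        if (labels == state).sum() < min_cells:
            raise ValueError(f"state {state!r} has fewer than {min_cells} cells")
    _, lig, rec = pair
    genes = [g for g in set(lig) | set(rec) if g in expr.columns]
    sub = expr[genes].to_numpy(dtype=np.float64)
    pos = (sub > 0).astype(np.float64)
    states = [sender, receiver] if sender != receiver else [sender]
    means, fracs = _state_summaries(sub, pos, labels, states)
    col = {g: j for j, g in enumerate(genes)}
    lig_idx = [col[g] for g in lig if g in col]
    rec_idx = [col[g] for g in rec if g in col]
    if len(lig_idx) < len(lig) or len(rec_idx) < len(rec):
        lig_idx = lig_idx if len(lig_idx) == len(lig) else []
        rec_idx = rec_idx if len(rec_idx) == len(rec) else []
    ri = states.index(receiver)
    return _pair_statistic(means, fracs, lig_idx, rec_idx, 0 if sender == states[0] else 1, ri, min_frac)


def permutation_test(
    expr: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    db: LRDatabase,
    n_perm: int = 1000,
    seed: int = 0,
    min_frac: float = 0.1,
    min_cells: int = 10,
    state_pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Label-permutation test for every (pair, sender, receiver) combination.

    One label shuffle per permutation round is shared across all pairs, which
    preserves the cross-pair correlation structure of the null.  p-values use
    the add-one convention p = (1 + #{permuted >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    states = sorted(pd.unique(labels))
    states = [s for s in states if (labels == s).sum() >= min_cells]
    if state_pairs is None:
        state_pairs = [(a, b) for a in states for b in states]
    else:
        state_pairs = [p for p in state_pairs if p[0] in states and p[1] in states]

    genes = [g for g in db.genes() if g in expr.columns]
    col = {g: j for j, g in enumerate(genes)}
    sub = np.ascontiguousarray(expr[genes].to_numpy(dtype=np.float64))
    pos = (sub > 0).astype(np.float64)

    triples = []
    for pid, lig, rec in db.pairs:
        lig_idx = [col[g] for g in lig if g in col]
        rec_idx = [col[g] for g in rec if g in col]
        flagged = len(lig_idx) < len(lig) or len(rec_idx) < len(rec)
        if len(lig_idx) < len(lig):
            lig_idx = []
        if len(rec_idx) < len(rec):
            rec_idx = []
        for sender, receiver in state_pairs:
            triples.append((pid, sender, receiver, lig_idx, rec_idx, flagged))

    state_index = {s: i for i, s in enumerate(states)}
    means, fracs = _state_summaries(sub, pos, labels, states)
    observed = np.array(
        [
            _pair_statistic(means, fracs, lig, rec, state_index[s], state_index[r], min_frac)
            for _, s, r, lig, rec, _ in triples
        ]
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(triples), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pm, pf = _state_summaries(sub, pos, perm, states)
        perm_stats = np.array(
            [
                _pair_statistic(pm, pf, lig, rec, state_index[s], state_index[r], min_frac)
                for _, s, r, lig, rec, _ in triples
            ]
        )
        exceed += perm_stats >= observed
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    return pd.DataFrame(
        {
            "pair_id": [t[0] for t in triples],
            "sender_state": [t[1] for t in triples],
            "receiver_state": [t[2] for t in triples],
            "mean_score": observed,
            "p": pvals,
            "n_permutations": n_perm,
            "missing_gene": [t[5] for t in triples],
        }
    )


def select_top_pairs(results: pd.DataFrame, n_top: int = 100, p_max: float = 0.01) -> pd.DataFrame:
    """Significant interactions ranked by mean score, truncated to ``n_top``.

    Filter p < ``p_max``, sort by mean_score descending with ties broken by
    pair_id (then sender/receiver), keep the first ``n_top`` rows.
    """
    if len(results) == 0:
        raise ValueError("results table is empty")
    sig = results[results["p"] < p_max].copy()
    sig = sig.sort_values(
        by=["mean_score", "pair_id", "sender_state", "receiver_state"],
        ascending=[False, True, True, True],
        kind="stable",
    )
    return sig.head(n_top).reset_index(drop=True)
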
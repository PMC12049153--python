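"""Per-sample consensus non-negative matrix factorization (cNMF).

The decomposition pipeline for one sample is: per-gene z-scores of log-CPM
with negatives clipped to zero, multiplicative-update NMF from many random
restarts, density filtering of pooled components, k-means grouping of the
survivors on a 1 - Pearson embedding, per-cluster median consensus spectra,
NNLS refit of per-cell usages, and a silhouette-based stability score that
drives rank (K) selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NMFConfig:
    k_range: tuple[int, int] = (4, 10)
    n_restarts: int = 20
    max_iter: int = 500
    tol: float = 1e-5                     # relative change of reconstruction error
    outlier_filter_quantile: float = 0.9
    seed: int = 0
    k_scan_restarts: int | None = None    # cheaper restart count for the K scan
    k_scan_tol: float | None = None       # looser convergence for the K scan

    def validate(self, n_cells: int, n_genes: int) -> None:
        lo, hi = self.k_range
        if lo < 2 or hi > min(n_cells, n_genes) or lo > hi:
            raise ValueError(f"k_range {self.k_range} outside [2, min(cells, genes)]")
        if self.n_restarts < 3:
            raise ValueError("n_restarts must be >= 3")


@dataclass
class ProgramSet:
    """One sample's consensus decomposition at a chosen rank.

    ``spectra`` lives in the preprocessed (z-scored, clipped) space the
    factorization ran in; ``gene_scores`` re-expresses each program on the
    normalized-expression scale as the covariance between a gene's log
    expression and the program's standardized usage — the scale top-gene
    signatures are extracted from.
    """

    sample_id: str
    k: int
    spectra: pd.DataFrame          # k x gene, rows unit-L1
    usages: pd.DataFrame           # cell x k, non-negative
    stability: float
    reconstruction_error: float
    gene_scores: pd.DataFrame | None = None
    diagnostics: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)


def preprocess_for_nmf(log_expr: np.ndarray) -> np.ndarray:
    """Per-gene z-score with negative values set to zero.

    Computed per sample; constant genes become all-zero columns which the
    factorization drops and re-inserts.
    """
    x = np.asarray(log_expr, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    np.clip(z, 0.0, None, out=z)
    return z


def nmf_factorize(
    X: np.ndarray,
    k: int,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF minimizing squared Frobenius error.

    Returns ``(W, H, errors)`` where H rows are unit-L1 (with compensating
    scaling folded into W) and ``errors`` is the per-iteration Frobenius
    error, guaranteed non-increasing.  All-zero rows or columns of X are
    dropped before the updates and re-inserted as zeros afterwards.
    """
    X = np.asarray(X, dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("X must be non-negative (preprocess first)")
    if k < 1:
        raise ValueError("k must be >= 1")
    row_ok = np.flatnonzero(X.sum(axis=1) > 0)
    col_ok = np.flatnonzero(X.sum(axis=0) > 0)
    dropped = (X.shape[0] - len(row_ok), X.shape[1] - len(col_ok))
    if any(dropped):
        logger.debug("nmf_factorize: dropping %d zero rows, %d zero columns", *dropped)
    Xs = X[np.ix_(row_ok, col_ok)]
    n, m = Xs.shape

    rng = np.random.default_rng(seed)
    scale = np.sqrt(Xs.mean() / k) if Xs.size else 1.0
    W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
    # spectra init by a clipped least-squares solve for the random usages:
    # depends on X only through X itself, so the whole algorithm is
    # equivariant under gene permutations
    H0, *_ = np.linalg.lstsq(W, Xs, rcond=None)
    floor = 0.01 * (Xs.mean() if Xs.size else 1.0)
    H = np.maximum(H0, floor)

    xsq = float((Xs**2).sum())
    errors = []
    prev = np.inf
    for _ in range(max_iter):
        WtW = W.T @ W
        H *= (W.T @ Xs) / (WtW @ H + _EPS)
        HHt = H @ H.T
        XHt = Xs @ H.T
        W *= XHt / (W @ HHt + _EPS)
        # ||X - WH||^2 expanded; XHt and HHt are current, W just updated
        err2 = xsq - 2.0 * float(np.sum(XHt * W)) + float(np.sum((W.T @ W) * HHt))
        err = np.sqrt(max(err2, 0.0))
        errors.append(err)
        if prev < np.inf and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err

    # unit-L1 spectra rows with compensating usage scaling
    norms = H.sum(axis=1)
    norms[norms == 0] = 1.0
    H /= norms[:, None]
    W *= norms[None, :]

    W_full = np.zeros((X.shape[0], k))
    H_full = np.zeros((k, X.shape[1]))
    W_full[row_ok] = W
    H_full[:, col_ok] = H
    return W_full, H_full, np.asarray(errors)


def _pearson_distance(rows: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; constant rows get distance 1."""
    centered = rows - rows.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    norm[norm == 0] = 1.0
    corr = (centered / norm[:, None]) @ (centered / norm[:, None]).T
    d = 1.0 - np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def refit_usages(X: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Non-negative least-squares usage refit, one cell at a time.

    Each cell's problem min ||spectra^T u - x||, u >= 0 is reduced to an
    equivalent k x k problem through the Cholesky factor of the spectra Gram
    matrix (||C^T u - C^{-1} S x||^2 differs only by a constant), which
    keeps the active-set solver cost independent of the gene count.
    """
    k = spectra.shape[0]
    G = spectra @ spectra.T
    C = np.linalg.cholesky(G + 1e-12 * np.trace(G) / max(k, 1) * np.eye(k))
    B = scipy.linalg.solve_triangular(C, spectra @ X.T, lower=True)
    A = np.ascontiguousarray(C.T)
    usages = np.empty((X.shape[0], k))
    for i in range(X.shape[0]):
        usages[i], _ = scipy.optimize.nnls(A, B[:, i])
    return usages


def consensus_factorize(
    X: np.ndarray,
    k: int,
    config: NMFConfig,
    n_restarts: int | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Consensus spectra, refit usages and a stability score at rank ``k``.

    Spectra from ``n_restarts`` seeded factorizations are pooled, components
    far from their (k-1) nearest neighbours (beyond the
    ``outlier_filter_quantile`` of those distances) are dropped, survivors
    are grouped into k clusters by k-means on the 1 - Pearson embedding, and
    each cluster's element-wise median becomes a consensus spectrum.
    Stability is the mean silhouette of the grouping; a cluster with fewer
    than two members marks the rank unstable (stability -1).
    """
    n_restarts = n_restarts or config.n_restarts
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_restarts)
    pooled = []
    for child in children:
        _, H, _ = nmf_factorize(X, k, seed=child, max_iter=config.max_iter, tol=config.tol)
        pooled.append(H)
    pooled = np.vstack(pooled)

    D = _pearson_distance(pooled)
    if k > 1:
        knn = np.sort(D, axis=1)[:, 1:k]       # distances to the (k-1) nearest others
        mean_knn = knn.mean(axis=1)
        cutoff = np.quantile(mean_knn, config.outlier_filter_quantile)
        keep = mean_knn <= cutoff
    else:
        keep = np.ones(pooled.shape[0], dtype=bool)
    survivors = pooled[keep]
    Ds = D[np.ix_(keep, keep)]

    km_seed = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2**31))
    labels = KMeans(n_clusters=k, n_init=10, random_state=km_seed).fit_predict(Ds)

    spectra = np.empty((k, X.shape[1]))
    unstable = False
    for c in range(k):
        members = survivors[labels == c]
        if len(members) < 2:
            unstable = True
        med = np.median(members, axis=0) if len(members) else np.zeros(X.shape[1])
        s = med.sum()
        spectra[c] = med / s if s > 0 else med
    if unstable or k < 2 or len(np.unique(labels)) < 2:
        stability = -1.0
    else:
        stability = float(silhouette_score(Ds, labels, metric="precomputed"))

    usages = refit_usages(X, spectra)
    return spectra, usages, stability


def reconstruction_error(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Relative Frobenius reconstruction error ||X - WH|| / ||X||."""
    denom = np.linalg.norm(X)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(X - W @ H) / denom)


def select_k(X: np.ndarray, config: NMFConfig) -> tuple[int, pd.DataFrame]:
    """Stability-driven rank selection with an error guard.

    For each k in ``k_range`` the consensus stability and relative
    reconstruction error are computed.  Among ranks whose error is within 5%
    of the best error over the range, the rank with the highest stability is
    chosen (ties towards the larger k).  When no rank shows positive
    stability (e.g. pure noise with no stability peak) the range minimum is
    returned.
    """
    lo, hi = config.k_range
    ks = list(range(lo, hi + 1))
    rows = []
    for k in ks:
        sub = replace(
            config,
            seed=int(np.random.SeedSequence([config.seed, 7, k]).generate_state(1)[0] % (2**31)),
            tol=config.k_scan_tol if config.k_scan_tol is not None else config.tol,
        )
        spectra, usages, stability = consensus_factorize(X, k, sub, n_restarts=config.k_scan_restarts)
        err = reconstruction_error(X, usages, spectra)
        rows.append({"k": k, "stability": stability, "error": err})
    diag = pd.DataFrame(rows)
    if len(ks) == 1:
        return ks[0], diag
    min_err = diag["error"].min()
    ok = diag["error"] <= 1.05 * min_err
    cand = diag[ok] if ok.any() else diag
    if (cand["stability"] <= 0).all():
        return lo, diag
    best = cand["stability"].max()
    chosen = int(cand.loc[cand["stability"] >= best - 1e-12, "k"].max())
    return chosen, diag


def usage_gene_scores(expr_log: np.ndarray, usages: np.ndarray) -> np.ndarray:
    """Per-program gene scores: cov(log expression, standardized usage).

    Re-expresses programs on the expression scale; the covariance with the
    standardized usage ranks genes by how strongly they track the program
    across cells, which is the ranking top-gene signatures are built from.
    """
    Lc = expr_log - expr_log.mean(axis=0)
    W = np.asarray(usages, dtype=np.float64)
    Wz = (W - W.mean(axis=0)) / (W.std(axis=0) + 1e-12)
    return (Wz.T @ Lc) / len(W)


def fit_sample(
    X: np.ndarray,
    sample_id: str,
    cell_ids: list[str],
    gene_ids: list[str],
    config: NMFConfig,
    k: int | None = None,
    expr_log: np.ndarray | None = None,
) -> ProgramSet:
    """Full cNMF for one sample: optional K selection then consensus at K.

    When ``expr_log`` (the normalized expression the preprocessing started
    from) is given, per-program gene scores on that scale are attached.
    """
    config.validate(*X.shape)
    diagnostics = None
    if k is None:
        k, diagnostics = select_k(X, config)
    spectra, usages, stability = consensus_factorize(X, k, config)
    err = reconstruction_error(X, usages, spectra)
    program_ids = [f"{sample_id}_p{i + 1}" for i in range(k)]
    gene_scores = None
    if expr_log is not None:
        gene_scores = pd.DataFrame(usage_gene_scores(expr_log, usages), index=program_ids, columns=gene_ids)
    return ProgramSet(
        sample_id=sample_id,
        k=k,
        spectra=pd.DataFrame(spectra, index=program_ids, columns=gene_ids),
        usages=pd.DataFrame(usages, index=cell_ids, columns=program_ids),
        stability=stability,
        reconstruction_error=err,
        gene_scores=gene_scores,
        diagnostics=diagnostics,
    )


def top_genes(spectra_row: pd.Series, n: int = 50) -> list[str]:
    """Genes with the ``n`` largest weights, ties broken by identifier."""
    if n > len(spectra_row):
        raise ValueError("n exceeds gene count")
    order = sorted(spectra_row.index, key=lambda g: (-spectra_row[g], g))
    return order[:n]
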
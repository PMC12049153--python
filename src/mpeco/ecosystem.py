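"""Bulk deconvolution and multi-compartment correlation / survival statistics.

Covers the ecosystem layer of the analysis: NNLS regression of bulk profiles
on a cell-state signature matrix, Spearman correlation among program scores
and inferred abundances, Kruskal-Wallis stage comparisons gated Dunn post-hoc
tests with FDR correction, Kaplan-Meier / log-rank survival stratification,
and the maximally selected rank-statistic ("optimal cutpoint") split.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from lifelines import KaplanMeierFitter
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------

@dataclass
class DeconvolutionResult:
    proportions: pd.DataFrame     # sample x state, simplex rows
    residual_norm: pd.Series
    signature_matrix: pd.DataFrame
    flags: dict = field(default_factory=dict)


def nnls_deconvolve(bulk: pd.DataFrame, signature_matrix: pd.DataFrame) -> DeconvolutionResult:
    """Estimate cell-state proportions per bulk sample by non-negative least squares.

    ``signature_matrix`` is gene x state; the fit runs over the signature
    genes present in the bulk matrix and the solution is renormalized onto
    the simplex (an all-zero solution falls back to uniform, flagged).
    """
    if signature_matrix.shape[1] < 2:
        raise ValueError("need at least 2 states")
    genes = [g for g in signature_matrix.index if g in bulk.columns]
    if not genes:
        raise ValueError("no signature genes present in the bulk matrix")
    S = signature_matrix.loc[genes].to_numpy(dtype=np.float64)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        warnings.warn("signature matrix is rank-deficient; proportions may not be unique", stacklevel=2)
    B = bulk[genes].to_numpy(dtype=np.float64)
    props = np.empty((len(bulk), S.shape[1]))
    resid = np.empty(len(bulk))
    fallback = 0
    for i in range(len(bulk)):
        x, r = scipy.optimize.nnls(S, B[i])
        total = x.sum()
        if total == 0:
            props[i] = 1.0 / S.shape[1]
            fallback += 1
        else:
            props[i] = x / total
        resid[i] = r
    flags = {"uniform_fallback": fallback} if fallback else {}
    return DeconvolutionResult(
        proportions=pd.DataFrame(props, index=bulk.index, columns=signature_matrix.columns),
        residual_norm=pd.Series(resid, index=bulk.index, name="residual_norm"),
        signature_matrix=signature_matrix.loc[genes],
        flags=flags,
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    R: float
    p: float
    n: int
    method: str = "spearman"


def spearman(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank correlation with an exact permutation p for tiny n.

    Rho is the Pearson correlation of average-tie ranks.  For n <= 9 the
    two-sided p enumerates all n! rank orderings; otherwise the usual
    t-approximation with n - 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 paired observations")
    if x.max() == x.min() or y.max() == y.min():
        raise ValueError("constant input: Spearman correlation undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rxc = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
        ryc = (ry - ry.mean()) / np.sqrt(((ry - ry.mean()) ** 2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ryc[perms] * rxc).sum(axis=1)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(R=rho, p=min(p, 1.0), n=n)


def correlation_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman R and p over the columns of ``df``."""
    cols = list(df.columns)
    R = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    P = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = spearman(df[a].to_numpy(), df[b].to_numpy())
            R.loc[a, b] = R.loc[b, a] = res.R
            P.loc[a, b] = P.loc[b, a] = res.p
    return R, P


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def kruskal_dunn(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> tuple[dict, pd.DataFrame]:
    """Kruskal-Wallis omnibus with gatekept Dunn post-hoc tests.

    Groups of size < 2 are dropped with a warning.  The pairwise Dunn table
    (tie-corrected pooled variance, BH-adjusted p per pair) is only computed
    when the omnibus p falls below ``alpha``; otherwise it is empty.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    small = set(pd.unique(groups)) - set(names)
    if small:
        warnings.warn(f"dropping groups with fewer than 2 values: {sorted(map(str, small))}", stacklevel=2)
    if len(names) < 3:
        raise ValueError("need at least 3 groups with >= 2 values")
    keep = np.isin(groups, names)
    values, groups = values[keep], groups[keep]
    samples = [values[groups == g] for g in names]
    H, p = scipy.stats.kruskal(*samples)
    omnibus = {"H": float(H), "p": float(p), "groups": list(map(str, names))}
    if p >= alpha:
        return omnibus, pd.DataFrame(columns=["group_a", "group_b", "z", "p", "p_adj"])

    N = len(values)
    ranks = scipy.stats.rankdata(values)
    mean_ranks = {g: ranks[groups == g].mean() for g in names}
    sizes = {g: (groups == g).sum() for g in names}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p": 2 * scipy.stats.norm.sf(abs(z))})
    table = pd.DataFrame(rows)
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return omnibus, table


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalStratification:
    cutpoint: float | None
    groups: pd.Series
    logrank_chi2: float
    p: float
    km_curves: dict[str, pd.DataFrame]
    flags: dict = field(default_factory=dict)


def _logrank_two_group(times: np.ndarray, events: np.ndarray, in_group: np.ndarray) -> tuple[float, float]:
    """Observed-minus-expected and hypergeometric variance for group 1."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order].astype(bool), in_group[order].astype(bool)
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    at_risk_total = n
    at_risk_g = int(g.sum())
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        d_g = int((e[i:j] & g[i:j]).sum())
        if d > 0 and at_risk_total > 1:
            exp_g = d * at_risk_g / at_risk_total
            o_minus_e += d_g - exp_g
            var += (
                d
                * (at_risk_g / at_risk_total)
                * (1 - at_risk_g / at_risk_total)
                * (at_risk_total - d)
                / (at_risk_total - 1)
            )
        at_risk_total -= j - i
        at_risk_g -= int(g[i:j].sum())
        i = j
    return o_minus_e, var


def km_logrank(
    times: np.ndarray,
    events: np.ndarray,
    groups: np.ndarray,
    cutpoint: float | None = None,
) -> SurvivalStratification:
    """Kaplan-Meier curves per group and the two-group log-rank test (1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError("km_logrank handles exactly 2 groups")
    flags = {}
    for g in names:
        if events[groups == g].sum() == 0:
            flags[f"no_events_{g}"] = True
    in_g = groups == names[0]
    o_minus_e, var = _logrank_two_group(times, events, in_g)
    chi2 = (o_minus_e**2) / var if var > 0 else 0.0
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    curves = {}
    for g in names:
        kmf = KaplanMeierFitter()
        kmf.fit(times[groups == g], events[groups == g])
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    return SurvivalStratification(
        cutpoint=cutpoint,
        groups=pd.Series(groups),
        logrank_chi2=float(chi2),
        p=p,
        km_curves=curves,
        flags=flags,
    )


def optimal_cutpoint(
    score: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    min_prop: float = 0.1,
) -> dict:
    """Maximally selected rank-statistic cutpoint for survival stratification.

    Scans every distinct score value between the ``min_prop`` and
    ``1 - min_prop`` quantiles as a high/low threshold and picks the one
    maximizing the absolute standardized log-rank statistic.  Both the
    optimal and the median split are reported.  The selected-cutpoint
    p-value is anti-conservative without a multiplicity correction and is
    flagged as such.
    """
    score = np.asarray(score, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(score) < 10:
        raise ValueError("need at least 10 subjects")
    lo, hi = np.quantile(score, [min_prop, 1.0 - min_prop])
    candidates = np.unique(score[(score >= lo) & (score < hi)])
    median = float(np.median(score))

    def strat(cut: float) -> SurvivalStratification:
        groups = np.where(score > cut, "high", "low")
        return km_logrank(times, events, groups, cutpoint=cut)

    median_strat = strat(median)
    if len(candidates) < 2:
        logger.info("optimal_cutpoint: fewer than 2 distinct candidates; falling back to median split")
        median_strat.flags["median_fallback"] = True
        return {"optimal": median_strat, "median": median_strat, "anti_conservative_p": True}

    best_z, best_cut = -np.inf, candidates[0]
    for cut in candidates:
        in_g = score > cut
        if in_g.sum() == 0 or (~in_g).sum() == 0:
            continue
        o_minus_e, var = _logrank_two_group(times, events, in_g)
        z = abs(o_minus_e) / np.sqrt(var) if var > 0 else 0.0
        if z > best_z:
            best_z, best_cut = z, float(cut)
    optimal = strat(best_cut)
    optimal.flags["max_selected_z"] = float(best_z)
    optimal.flags["anti_conservative_p"] = True
    return {"optimal": optimal, "median": median_strat, "anti_conservative_p": True}
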
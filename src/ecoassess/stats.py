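"""Group comparisons and rank correlations over behavioral-profile features.

Mann-Whitney U tests (midranks for ties, tie-corrected normal approximation
with optional continuity correction, exact enumeration-free p for small
untied samples) and Spearman correlations (midrank product-moment with the
t-approximation).  Two-sided p-values throughout; significance is thresholded
at p < 0.05 with an optional Holm correction, off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "GroupComparisonResult",
    "SpearmanResult",
    "mann_whitney",
    "spearman",
    "group_comparison_table",
    "spearman_table",
    "holm_adjust",
]

ALPHA = 0.05

#: Largest pooled sample size for which the exact U distribution is computed.
EXACT_MAX_POOLED_N = 60
EXACT_MAX_MIN_N = 8


@dataclass(frozen=True)
class GroupComparisonResult:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    Z: float
    p: float
    method: str  # "exact" | "normal"

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _exact_u_sf_table(m: int, n: int) -> np.ndarray:
    """Counts of the U statistic for sample sizes (m, n) without ties.

    Dynamic program over subset rank sums: ``counts[u]`` is the number of
    ways to choose the m ranks of the first sample so that its U equals u.
    """
    N = m + n
    max_w = m * N  # rank sum upper bound
    dp = np.zeros((m + 1, max_w + 1))
    dp[0, 0] = 1.0
    for rank in range(1, N + 1):
        for k in range(min(m, rank), 0, -1):
            dp[k, rank:] += dp[k - 1, :-rank or None]
    w_min = m * (m + 1) // 2
    return dp[m, w_min:w_min + m * n + 1]  # index u = W - min rank sum


def _exact_two_sided_p(u: float, m: int, n: int) -> float:
    counts = _exact_u_sf_table(m, n)
    total = counts.sum()
    u_int = int(round(u))
    lo = min(u_int, m * n - u_int)  # U distribution is symmetric about mn/2
    p = 2.0 * counts[: lo + 1].sum() / total
    return float(min(p, 1.0))


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
    continuity: bool = True,
    method: str = "auto",
) -> GroupComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``U`` is the statistic of sample ``a`` computed from midrank sums.  For
    untied data with ``min(n_a, n_b) <= 8`` (and pooled n within the exact
    limit) the p-value is exact from the full U distribution; otherwise the
    tie-corrected normal approximation with continuity correction is used.
    ``Z`` is always reported from the normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    n_a, n_b = len(a), len(b)
    N = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = ranks[:n_a].sum()
    U = float(r_a - n_a * (n_a + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())

    mu = n_a * n_b / 2.0
    var = (n_a * n_b / 12.0) * ((N + 1) - tie_term / (N * (N - 1))) if N > 1 else 0.0
    if var <= 0:
        Z = 0.0
        p_normal = 1.0
    else:
        shift = 0.5 * np.sign(U - mu) if continuity else 0.0
        Z = float((U - mu - shift) / np.sqrt(var)) if U != mu else 0.0
        p_normal = float(min(1.0, 2.0 * sps.norm.sf(abs(Z))))

    use_exact = method == "exact" or (
        method == "auto"
        and not has_ties
        and min(n_a, n_b) <= EXACT_MAX_MIN_N
        and N <= EXACT_MAX_POOLED_N
    )
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method {method!r}")
    if use_exact and has_ties:
        raise ValueError("exact method requires untied data")

    if use_exact:
        m, n = (n_a, n_b) if n_a <= n_b else (n_b, n_a)
        u_small = U if n_a <= n_b else n_a * n_b - U
        p = _exact_two_sided_p(u_small, m, n)
        used = "exact"
    else:
        p = p_normal
        used = "normal"
    return GroupComparisonResult(feature, group_a, group_b, n_a, n_b, U, Z, p, used)


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation (midranks) with two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), n)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-15:
        return SpearmanResult(float(np.sign(rho)), 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), n - 2)))
    return SpearmanResult(rho, p, n)


def holm_adjust(pvalues: Sequence[float]) -> list:
    """Holm step-down adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def _fmt_cell(z: float, p: float) -> str:
    return f"{z:.3f}/{p:.3f}"


def group_comparison_table(
    df: pd.DataFrame,
    group_col: str,
    features: Sequence[str],
    pairs: Optional[Iterable[tuple]] = None,
    continuity: bool = True,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons, one row per group pair.

    Cells hold ``"Z/p"``; with ``holm`` the p-values are Holm-adjusted across
    the whole table.
    """
    groups = list(dict.fromkeys(df[group_col]))
    if pairs is None:
        pairs = [(g1, g2) for i, g1 in enumerate(groups) for g2 in groups[i + 1:]]
    pairs = list(pairs)
    results = {}
    for g1, g2 in pairs:
        for feat in features:
            a = df.loc[df[group_col] == g1, feat]
            b = df.loc[df[group_col] == g2, feat]
            results[(g1, g2, feat)] = mann_whitney(
                a, b, feature=feat, group_a=str(g1), group_b=str(g2),
                continuity=continuity,
            )
    keys = list(results)
    pvals = [results[k].p for k in keys]
    if holm:
        pvals = holm_adjust(pvals)
    cells = {k: _fmt_cell(results[k].Z, pv) for k, pv in zip(keys, pvals)}
    table = pd.DataFrame(
        [[cells[(g1, g2, f)] for f in features] for g1, g2 in pairs],
        index=[f"{g1} vs. {g2}" for g1, g2 in pairs],
        columns=list(features),
    )
    table.index.name = "comparison"
    return table


def spearman_table(
    df: pd.DataFrame,
    row_features: Sequence[str],
    col_features: Sequence[str],
    holm: bool = False,
) -> pd.DataFrame:
    """Spearman rho/p for every (row feature, column feature) pair."""
    results = {}
    for rf in row_features:
        for cf in col_features:
            results[(rf, cf)] = spearman(df[rf], df[cf])
    keys = list(results)
    pvals = [results[k].p for k in keys]
    if holm:
        pvals = holm_adjust(pvals)
    cells = {k: f"{results[k].rho:.3f}/{pv:.3f}" for k, pv in zip(keys, pvals)}
    table = pd.DataFrame(
        [[cells[(rf, cf)] for cf in col_features] for rf in row_features],
        index=list(row_features),
        columns=list(col_features),
    )
    table.index.name = "feature"
    return table
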
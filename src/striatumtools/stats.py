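"""Shared nonparametric statistics.

Every downstream stage of the pipeline (topography, firing analysis,
peak-timing comparisons, apposition counts) funnels its inference through
the small set of rank and exact tests in this module: Mann-Whitney U,
Wilcoxon signed-rank against zero, Kruskal-Wallis with Dunn post-hoc,
Fisher's exact test, Benjamini-Hochberg FDR, and Spearman rank
correlation.  Results are returned as :class:`TestResult` objects that
serialize to flat JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (U, W, H, odds ratio context dependent).
    p_value : float
        Two-sided p-value in [0, 1].
    n_per_group : tuple of int
        Sample size of each group entering the test.
    method : str
        Name of the test performed.
    degenerate : bool
        True when the input admitted no real test (e.g. all-zero
        differences for the signed-rank test); p_value is then 1.
    extra : dict
        Method-specific extras (odds ratio, pairwise tables, ...).
    """

    statistic: float
    p_value: float
    n_per_group: tuple
    method: str
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        out = {
            "test": self.method,
            "statistic": float(self.statistic),
            "p": float(self.p_value),
            "n": list(self.n_per_group),
        }
        if self.degenerate:
            out["degenerate"] = True
        for k, v in self.extra.items():
            if isinstance(v, (pd.DataFrame, pd.Series)):
                out[k] = v.to_dict()
            elif isinstance(v, np.ndarray):
                out[k] = v.tolist()
            else:
                out[k] = v
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 count table, rows = populations, columns = outcome classes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("contingency counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def _as1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both samples have n <= 8 and the pooled
    data is tie-free; otherwise the normal approximation with tie and
    continuity correction.
    """
    xa, ya = _as1d(x, "x"), _as1d(y, "y")
    pooled = np.concatenate([xa, ya])
    exact = xa.size <= 8 and ya.size <= 8 and np.unique(pooled).size == pooled.size
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(xa.size, ya.size),
        method="mann_whitney_u",
        extra={"exact": exact},
    )


def wilcoxon_signed_vs_zero(values: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of median(values) == 0.

    Exact zeros are dropped before ranking (Wilcoxon's convention).  If
    every value is zero the result is flagged degenerate with p = 1.
    """
    v = _as1d(values, "values")
    nonzero = v[v != 0.0]
    if nonzero.size == 0:
        return TestResult(0.0, 1.0, (v.size,), "wilcoxon_signed_rank", degenerate=True)
    res = sps.wilcoxon(nonzero, alternative="two-sided", zero_method="wilcox")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(nonzero.size,),
        method="wilcoxon_signed_rank",
        extra={"n_zeros_dropped": int(v.size - nonzero.size)},
    )


def _dunn_pairwise(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's z test on pooled mean ranks, with tie correction."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term sum(t^3 - t) over tied groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(np.mean(ranks[start : start + g.size])))
        sizes.append(g.size)
        start += g.size
    rows = []
    raw_ps = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(
                (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1)))
                * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z, "p": p})
            raw_ps.append(p)
    table = pd.DataFrame(rows)
    table["p_adj_bh"] = fdr_adjust(raw_ps)[0] if raw_ps else []
    return table


def kruskal_wallis_dunn(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis omnibus test followed by Dunn's pairwise post-hoc.

    Pairwise p-values are reported both raw and BH-adjusted; the
    ``significant`` convention downstream uses the raw p-values.
    """
    arrs = [_as1d(g, f"group {i}") for i, g in enumerate(groups)]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    if all(np.array_equal(a, arrs[0]) for a in arrs[1:]):
        # identical groups: H = 0 up to tie handling; avoid scipy's
        # all-identical ValueError
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*arrs)
    dunn = _dunn_pairwise(arrs)
    return TestResult(
        statistic=float(h),
        p_value=float(p),
        n_per_group=tuple(g.size for g in arrs),
        method="kruskal_wallis",
        extra={"dunn": dunn},
    )


def fisher_exact(t: Contingency2x2) -> TestResult:
    """Two-sided Fisher exact test with odds ratio.

    The p-value uses the hypergeometric point-probability rule.  The
    sample odds ratio ad/bc is reported alongside the conditional MLE;
    with a zero cell the sample odds ratio is 0 or inf and flagged.
    """
    table = t.as_array()
    res = sps.fisher_exact(table, alternative="two-sided")
    a, b, c, d = t.a, t.b, t.c, t.d
    zero_cell = 0 in (a, b, c, d)
    if b * c == 0:
        sample_or = math.inf if a * d > 0 else math.nan if a * d == 0 else 0.0
    else:
        sample_or = (a * d) / (b * c)
    cond_or = float(sps.contingency.odds_ratio(table, kind="conditional").statistic)
    return TestResult(
        statistic=float(sample_or) if math.isfinite(sample_or) else float("nan"),
        p_value=float(res.pvalue),
        n_per_group=(a + b, c + d),
        method="fisher_exact",
        extra={
            "odds_ratio_sample": sample_or,
            "odds_ratio_conditional_mle": cond_or,
            "zero_cell": zero_cell,
        },
    )


def fdr_adjust(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)`` where ``adjusted`` are BH
    adjusted p-values and ``significant`` the boolean flags at ``alpha``.
    Flags are monotone with the raw p-values.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = sps.false_discovery_control(p, method="bh")
    return adjusted, adjusted <= alpha


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN when either input is constant (rho undefined).
    """
    xa, ya = _as1d(x, "x"), _as1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return float("nan")
    rho = sps.spearmanr(xa, ya).statistic
    return float(rho)
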
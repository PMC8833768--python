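"""Cohort statistics: Spearman rank correlation and Wilcoxon rank-sum.

Spearman's rho measures monotonic association between two continuous
variables, or between a continuous variable and an ordered categorical
one after ordinal encoding (e.g. clinical T stage T0 < Tis < Ta < T1 <
T2a < T3b < T4a encoded 0..6).  The Wilcoxon rank-sum (Mann-Whitney U)
test compares two groups without distributional assumptions; for
categoricals with more than two levels it is run over every unordered
pair of levels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .categories import RARE_CATEGORIES, TOTAL_COLUMNS
from .enumeration import CohortDataset

__all__ = [
    "OrdinalEncoding",
    "TestResult",
    "CLINICAL_T_STAGE",
    "PATHOLOGICAL_T_STAGE",
    "spearman",
    "wilcoxon_rank_sum",
    "pairwise_group_tests",
    "compare_cohorts",
]


@dataclass(frozen=True)
class OrdinalEncoding:
    """An ordered label list encoded 0..L-1."""

    name: str
    levels: tuple[str, ...]

    @property
    def codes(self) -> dict[str, int]:
        return {lev: i for i, lev in enumerate(self.levels)}

    def encode(self, values) -> np.ndarray:
        codes = self.codes
        try:
            return np.array([codes[v] for v in values], dtype=float)
        except KeyError as err:
            raise ValueError(f"unknown {self.name} level: {err}") from err


# Tumor-stage encodings in anatomical order of invasion.  The clinical
# list is the assay cohort's observed stages; the pathological list
# additionally holds T2b and T3a, seen only at pathology.
CLINICAL_T_STAGE = OrdinalEncoding(
    "clinical_T_stage", ("T0", "Tis", "Ta", "T1", "T2a", "T3b", "T4a")
)
PATHOLOGICAL_T_STAGE = OrdinalEncoding(
    "pathological_T_stage",
    ("T0", "Tis", "Ta", "T1", "T2a", "T2b", "T3a", "T3b", "T4a"),
)


@dataclass
class TestResult:
    """One statistical comparison."""

    analyte: str
    comparison: str
    statistic: float
    p_value: float
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError("p-value outside [0, 1]")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho.

    Enumerates all n! pairings of y's mid-ranks against x's; rho is a
    monotone function of the rank cross-product, so the tail count uses
    the Pearson correlation of ranks directly (ties handled).
    """
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    permuted = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    py_c = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (py_c**2).sum(axis=1))
    rhos = (py_c @ rx_c) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(
    x, y, analyte: str = "", comparison: str = "", exact_max_n: int = 9
) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Rho is computed on mid-ranks (ties allowed).  For n <=
    ``exact_max_n`` the p-value is the exact permutation probability
    over all pairings; larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "Spearman rho is undefined for a constant vector: ranks carry "
            "no information when every value is identical"
        )
    rho, p_t = sps.spearmanr(x, y)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    else:
        p = float(p_t)
    return TestResult(analyte, comparison, float(rho), min(p, 1.0), (n,))


def wilcoxon_rank_sum(
    a,
    b,
    analyte: str = "",
    comparison: str = "",
    exact_max_n: int = 12,
    continuity: bool = True,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test, two-sided.

    The statistic is the Mann-Whitney U of the first sample with
    mid-rank ties.  The p-value is exact (full enumeration of rank
    splits) for tie-free data with ``n_a + n_b <= exact_max_n``,
    otherwise the normal approximation with tie correction and,
    optionally, continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if not has_ties and a.size + b.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=continuity
    )
    return TestResult(
        analyte, comparison, float(res.statistic), float(res.pvalue),
        (a.size, b.size),
    )


def pairwise_group_tests(
    values, labels, analyte: str = ""
) -> list[TestResult]:
    """Rank-sum test between every unordered pair of category levels.

    Levels with a single member cannot be tested; their pairs are
    skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        raise ValueError("need at least two categories")
    results = []
    for lo, hi in combinations(levels, 2):
        va = values[labels == lo]
        vb = values[labels == hi]
        if len(va) < 2 or len(vb) < 2:
            warnings.warn(
                f"pair {lo} vs {hi} skipped: singleton category", stacklevel=2
            )
            continue
        results.append(
            wilcoxon_rank_sum(va, vb, analyte=analyte, comparison=f"{lo} vs {hi}")
        )
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def compare_cohorts(
    cohort: CohortDataset, adjust: bool = True
) -> pd.DataFrame:
    """BCa-vs-ND rank-sum test per events/mL category and total.

    Returns a table sorted by ascending p-value (most significant
    first), optionally with a Benjamini-Hochberg adjusted column; raw
    p-values are the primary readout.
    """
    bca, nd = cohort.group_frames()
    if len(bca) < 2 or len(nd) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for col in RARE_CATEGORIES + TOTAL_COLUMNS:
        res = wilcoxon_rank_sum(
            bca[col].to_numpy(), nd[col].to_numpy(),
            analyte=col, comparison="BCa vs ND",
        )
        rows.append(
            {
                "analyte": col,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_bca": len(bca),
                "n_nd": len(nd),
                "median_bca": float(bca[col].median()),
                "median_nd": float(nd[col].median()),
            }
        )
    table = pd.DataFrame(rows)
    if adjust:
        table["p_bh"] = _bh_adjust(table["p_value"].to_numpy())
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)
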
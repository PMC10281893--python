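"""Self-contained rank statistics.

Implements the two nonparametric procedures used for the cross-cohort
and score comparisons -- the two-sided Mann-Whitney U test for
independent samples and the Spearman rank correlation coefficient --
without delegating to a statistics library, so the exact small-sample
behaviour is fully specified:

* U counts pairs with x > y plus half the ties.
* For n_x + n_y <= 12 with no ties the two-sided p-value comes from
  full enumeration of all C(n, n_x) group labelings of the pooled
  sample; otherwise a normal approximation with tie-corrected variance
  and a 0.5 continuity correction is used.
* Spearman's rho is the Pearson correlation of mid-ranks (average
  ranks on ties); no p-value is attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .errors import SizeError, UndefinedCorrelationError, ValidationError

EXACT_MAX_N = 12  # largest pooled size for exact enumeration


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation"


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, average rank for ties)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #ties, via pooled mid-ranks."""
    n_x = len(x)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r_x = float(np.sum(ranks[:n_x]))
    return r_x - n_x * (n_x + 1) / 2.0


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x == 0 or n_y == 0:
        raise SizeError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    mu = n_x * n_y / 2.0

    if n_x + n_y <= EXACT_MAX_N and not has_ties:
        # enumerate every way of labeling n_x of the pooled values as x
        ranks = _midranks(pooled)  # distinct values -> integer ranks
        dev = abs(u - mu)
        count = 0
        total = 0
        for combo in combinations(range(n_x + n_y), n_x):
            u_star = float(sum(ranks[k] for k in combo)) - n_x * (n_x + 1) / 2.0
            if abs(u_star - mu) >= dev - 1e-12:
                count += 1
            total += 1
        return TestResult(statistic=u, p_value=count / total, method="exact")

    n = n_x + n_y
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:  # all observations identical
        return TestResult(statistic=u, p_value=1.0, method="normal-approximation")
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)  # continuity correction
    z = max(z, 0.0)
    p = min(1.0, math.erfc(z / math.sqrt(2.0)))
    return TestResult(statistic=u, p_value=p, method="normal-approximation")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise SizeError("paired samples must have equal length")
    if len(x) < 3:
        raise SizeError("spearman_rho needs at least 3 pairs")
    rx = _midranks(x)
    ry = _midranks(y)
    sx = np.std(rx)
    sy = np.std(ry)
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant input has undefined correlation")
    return float(np.mean((rx - np.mean(rx)) * (ry - np.mean(ry))) / (sx * sy))


def score_summary(scores: Sequence[int]) -> dict:
    """Summary of 1..5 image-quality scores.

    Reports the fraction scored >= 4 (artifact-free or minimal
    artifacts), the fraction scored <= 2 (relevant information loss),
    the mean score and the per-score relative incidence.
    """
    scores = list(scores)
    if not scores:
        raise SizeError("empty score list")
    for s in scores:
        if int(s) != s or not 1 <= s <= 5:
            raise ValidationError(f"score {s!r} outside 1..5")
    arr = np.asarray(scores, dtype=int)
    n = len(arr)
    return {
        "n": n,
        "fraction_ge_4": float(np.sum(arr >= 4) / n),
        "fraction_le_2": float(np.sum(arr <= 2) / n),
        "mean_score": float(np.mean(arr)),
        "incidence": {s: float(np.sum(arr == s) / n) for s in range(1, 6)},
    }
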
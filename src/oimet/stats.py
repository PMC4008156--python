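"""Shared enrichment statistics.

Small wrappers around :mod:`scipy.stats` that fix the exact conventions used
throughout the package: Pearson chi-square with Yates continuity correction on
2x2 tables, the central (doubled one-tail) variant of Fisher's exact test, a
two-proportion z-test with continuity correction, and a doubled-tail Poisson
test for counts checked against an independence expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class EnrichmentResult:
    """Observed vs background proportions with a fold and a p-value.

    ``fold`` is the ratio of proportions (observed over background/expected);
    ``method`` records which test produced ``p_value``. Count fields are
    ``None`` when the background is supplied as a bare proportion.
    """

    term: str
    k_set: int
    n_set: int
    k_bg: int | None
    n_bg: int | None
    prop_set: float
    prop_bg: float
    fold: float
    statistic: float = math.nan
    p_value: float = math.nan
    method: str = ""

    @classmethod
    def from_counts(cls, term: str, k_set: int, n_set: int, k_bg: int, n_bg: int,
                    method: str = "") -> "EnrichmentResult":
        if not (0 <= k_set <= n_set):
            raise ValueError(f"k_set={k_set} outside [0, n_set={n_set}]")
        if not (0 <= k_bg <= n_bg):
            raise ValueError(f"k_bg={k_bg} outside [0, n_bg={n_bg}]")
        prop_set = k_set / n_set if n_set else math.nan
        prop_bg = k_bg / n_bg if n_bg else math.nan
        if k_bg == 0:
            warnings.warn("background count is zero; fold reported as +inf")
            fold = math.inf
        else:
            fold = prop_set / prop_bg
        return cls(term, k_set, n_set, k_bg, n_bg, prop_set, prop_bg, fold, method=method)

    @classmethod
    def from_background_prop(cls, term: str, k_set: int, n_set: int, prop_bg: float,
                             method: str = "") -> "EnrichmentResult":
        if not (0 <= k_set <= n_set):
            raise ValueError(f"k_set={k_set} outside [0, n_set={n_set}]")
        prop_set = k_set / n_set if n_set else math.nan
        return cls(term, k_set, n_set, None, None, prop_set, prop_bg,
                   prop_set / prop_bg, method=method)


def chi2_2x2(table: np.ndarray | list, correction: bool = True) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table; Yates-corrected by default."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=correction)
    return float(chi2), float(p)


def fisher_exact_central(table: np.ndarray | list) -> float:
    """Central two-sided Fisher exact p: twice the smaller hypergeometric tail.

    Differs from scipy's default (minimum-likelihood) two-sided definition;
    the central variant tracks the Yates chi-square closely once every cell
    is moderately large, which is what the dual-route consistency checks rely
    on.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    n = a + b + c + d
    lower = sps.hypergeom.cdf(a, n, a + b, a + c)
    upper = sps.hypergeom.sf(a - 1, n, a + b, a + c)
    return float(min(1.0, 2.0 * min(lower, upper)))


def two_proportion_ztest(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Two-sided z-test for equality of two binomial proportions.

    Pooled standard error; the continuity correction subtracts
    ``(1/n1 + 1/n2)/2`` from the absolute difference (floored at zero).
    Returns ``(z, p)``.
    """
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    diff = abs(p1 - p2)
    if continuity:
        diff = max(0.0, diff - 0.5 * (1 / n1 + 1 / n2))
    z = diff / se
    return z, float(2 * sps.norm.sf(z))


def poisson_test(observed: int, expected: float) -> float:
    """Two-sided (doubled-tail) Poisson test of a count against its mean."""
    if expected < 0:
        raise ValueError("expected count must be non-negative")
    if expected == 0:
        return 1.0 if observed == 0 else 0.0
    upper = sps.poisson.sf(observed - 1, expected)
    lower = sps.poisson.cdf(observed, expected)
    return float(min(1.0, 2.0 * min(upper, lower)))
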
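"""Shared exact-test and multiple-testing primitives.

One engine serves all modules: feature enrichment, gene-class peak counts and
set-intersection independence all call the same two-tailed exact binomial;
motif enrichment calls the same one-tailed hypergeometric; every FDR column is
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["BinomialTestResult", "binomial_two_tailed", "hypergeom_sf", "bh_fdr"]


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float
    direction: str  # "over" | "under"


def binomial_two_tailed(k: int, n: int, p0: float) -> BinomialTestResult:
    """Exact two-tailed binomial test (minimum-likelihood summation).

    The two-sided p-value is the total probability of all outcomes whose
    probability under Binomial(n, p0) does not exceed that of the observed k —
    well defined for asymmetric nulls, unlike doubling one tail.
    """
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not (0 < p0 < 1):
        raise ValueError(f"p0={p0} must lie strictly between 0 and 1")
    p = sps.binomtest(k, n, p0, alternative="two-sided").pvalue
    direction = "over" if (n > 0 and k / n > p0) else "under"
    return BinomialTestResult(k, n, p0, float(min(p, 1.0)), direction)


def hypergeom_sf(a: int, universe: int, marked: int, drawn: int) -> float:
    """One-tailed (over-representation) hypergeometric p-value P(X >= a)."""
    if not (0 <= a <= min(marked, drawn)):
        raise ValueError("observed overlap exceeds marginals")
    return float(sps.hypergeom.sf(a - 1, universe, marked, drawn))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs are passed through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(adj, 1.0)
    out[mask] = q
    return out
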
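"""Peak-level gene set enrichment analysis (GSEA).

Gene sets are mapped to peak sets through the peak-to-gene annotation (a
"gene set" becomes all peaks annotated to any member gene), peaks are ranked
by the log2 fold change of a chosen contrast, and the classic weighted
Kolmogorov-Smirnov running sum gives the enrichment score (ES). Significance
comes from a permutation null built by shuffling membership labels over the
ranked list; the normalized enrichment score (NES) divides the observed ES by
the mean |ES| of same-sign permutations, and p-values carry the +1 finite-
permutation correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import PeakGeneMap
from .peaksets import GeneSet, PeakSet
from .stats import bh_fdr

__all__ = ["GseaResult", "peaks_for_gene_set", "enrichment_score", "run_gsea"]


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p_value: float
    fdr: float
    weight_exponent: float


def peaks_for_gene_set(gene_set: GeneSet, peak_gene_map: PeakGeneMap) -> PeakSet:
    """All peaks associated with any member gene (set semantics)."""
    members = peak_gene_map.peaks_for_genes(gene_set.members)
    return PeakSet(
        gene_set.name, members, [f"peaks annotated to gene set {gene_set.name!r}"]
    )


def _es_from_positions(
    positions: np.ndarray, absstats: np.ndarray, n: int, weight_exponent: float
) -> float:
    """ES from sorted member positions (0-based) in a ranked list of length n."""
    m = positions.size
    if m == 0:
        raise ValueError("member set must be non-empty")
    if m == n:  # increments only: the running sum ends at exactly 1
        return 1.0
    w = absstats[positions] ** weight_exponent
    total = w.sum()
    if total == 0:
        raise ValueError("all member weights are zero under the chosen exponent")
    cum = np.cumsum(w) / total
    miss = 1.0 / (n - m)
    j = np.arange(m)
    tops = cum - (positions - j) * miss
    bottoms = np.concatenate(([0.0], cum[:-1])) - (positions - j) * miss
    hi = tops.max()
    lo = min(bottoms.min(), 0.0)
    return float(hi if hi >= -lo else lo)


def enrichment_score(
    ranked_stats: pd.Series, members, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """Running-sum enrichment score over a descending-ranked statistic.

    Member steps add |stat|^w normalized by the member weight total;
    non-member steps subtract 1/(N-m). Returns the signed extremum and the
    full running sum.
    """
    stats = ranked_stats.to_numpy(dtype=float)
    if np.any(np.diff(stats) > 0):
        raise ValueError("ranked_stats must be sorted in descending order")
    ids = ranked_stats.index
    member_ids = members.members if hasattr(members, "members") else set(members)
    mask = ids.isin(member_ids)
    n, m = len(ids), int(mask.sum())
    if m == 0:
        raise ValueError("member set must be non-empty")
    absstats = np.abs(stats)
    w = np.where(mask, absstats**weight_exponent, 0.0)
    total = w.sum()
    if total == 0:
        raise ValueError("all member weights are zero under the chosen exponent")
    if m == n:  # increments only
        return 1.0, np.cumsum(w / total)
    steps = np.where(mask, w / total, -1.0 / (n - m))
    running = np.cumsum(steps)
    hi, lo = running.max(), min(running.min(), 0.0)
    es = float(hi if hi >= -lo else lo)
    return es, running


def run_gsea(
    ranked_stats: pd.Series,
    peak_sets: dict[str, PeakSet] | list[PeakSet],
    n_perm: int = 10_000,
    min_size: int = 5,
    max_size: float = np.inf,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation GSEA over peak sets on a ranked statistic.

    Sets smaller than ``min_size`` (default 5) or larger than ``max_size``
    are skipped. The null shuffles membership over the ranked list (peak
    permutation): each permutation draws ``m`` random positions. NES divides
    the ES by the mean |ES| of same-sign permutations; p-values use the +1
    correction and are BH-adjusted across sets.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")
    if isinstance(peak_sets, dict):
        peak_sets = list(peak_sets.values())
    ranked_stats = ranked_stats.sort_values(ascending=False, kind="stable")
    ids = ranked_stats.index
    absstats = np.abs(ranked_stats.to_numpy(dtype=float))
    n = len(ids)
    rng = np.random.default_rng(seed)

    rows = []
    for ps in peak_sets:
        mask = ids.isin(ps.members)
        m = int(mask.sum())
        if m < min_size or m > max_size or m >= n:
            continue
        positions = np.flatnonzero(mask)
        es = _es_from_positions(positions, absstats, n, weight_exponent)
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            pos = np.sort(rng.choice(n, size=m, replace=False))
            try:
                es_perm[b] = _es_from_positions(pos, absstats, n, weight_exponent)
            except ValueError:  # all-zero weights in a permutation draw
                es_perm[b] = 0.0
        same_sign = es_perm > 0 if es > 0 else es_perm < 0
        n_same = int(same_sign.sum())
        if n_same:
            nes = es / np.mean(np.abs(es_perm[same_sign]))
            p = (1 + int((np.abs(es_perm[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        else:
            nes, p = np.nan, 1.0 / (1 + n_perm)
        rows.append((ps.name, m, es, nes, p))

    out = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p_value"])
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["weight_exponent"] = weight_exponent
    return out
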
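"""Motif-accessibility deviations and deviation Z-scores.

The accessibility of a motif in a sample is the summed fragment count over
motif-bearing peaks. Its expectation redistributes the motif's grand total
across samples proportionally to library size, so the raw deviation
(obs - exp)/exp is zero whenever a sample behaves like the pooled average.
The Z-score standardizes the raw deviation against background peak sets
sampled (with replacement) from the same bin of (GC content, mean normalized
accessibility), which controls for sequence composition and coverage biases.
Differential deviations between sample groups use a Welch t-test (two groups)
or one-way ANOVA (more), BH-corrected, significant at FDR < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import Accessome
from .motifs import MotifHitMatrix
from .stats import bh_fdr

__all__ = [
    "resize_peaks",
    "motif_observed_expected",
    "sample_background_sets",
    "deviation_zscores",
    "differential_deviations",
    "DeviationMatrix",
]


def resize_peaks(accessome: Accessome, width: int = 200) -> pd.DataFrame:
    """Center each peak and fix its width, clipping at chromosome bounds.

    The center is floor((start+end)/2); the resized interval is
    [center - width/2, center + width/2) before clipping.
    """
    half = width // 2
    out = accessome.peaks.copy()
    centers = (out["start"] + out["end"]) // 2
    out["start"] = (centers - half).clip(lower=0)
    out["end"] = np.minimum(
        centers + half, out["chrom"].map(accessome.genome_sizes)
    )
    return out


def _occupancy(hits) -> pd.DataFrame:
    return hits.occupancy if isinstance(hits, MotifHitMatrix) else hits


def motif_observed_expected(
    counts: pd.DataFrame,
    hits,
    library_sizes: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Observed and expected motif x sample accessibility, and raw deviations.

    observed(motif, s) = sum of counts over motif-bearing peaks;
    expected(motif, s) = grand motif total * library_size(s) / total library;
    raw deviation = (obs - exp) / exp (NA where the expectation is zero).
    """
    occ = _occupancy(hits)
    if not occ.index.equals(counts.index):
        occ = occ.reindex(counts.index)
        if occ.isna().any().any():
            raise ValueError("hit matrix does not cover the count matrix peaks")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    H = occ.to_numpy(dtype=float).T  # motifs x peaks
    C = counts.to_numpy(dtype=float)  # peaks x samples
    lib = library_sizes.to_numpy(dtype=float)
    obs = H @ C
    if lib.sum() <= 0:
        raise ValueError("total library size is zero")
    exp = np.outer(obs.sum(axis=1) / lib.sum(), lib)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.where(exp > 0, (obs - exp) / exp, np.nan)
    idx = occ.columns
    cols = counts.columns
    return (
        pd.DataFrame(obs, index=idx, columns=cols),
        pd.DataFrame(exp, index=idx, columns=cols),
        pd.DataFrame(dev, index=idx, columns=cols),
    )


def _gc_content(sequences: dict[str, str], peak_ids) -> np.ndarray:
    out = np.empty(len(peak_ids))
    for i, pid in enumerate(peak_ids):
        seq = sequences[pid].upper()
        n = max(len(seq), 1)
        out[i] = (seq.count("G") + seq.count("C")) / n
    return out


def sample_background_sets(
    accessome_or_ids,
    counts: pd.DataFrame,
    sequences: dict[str, str],
    n_iterations: int = 50,
    n_bins: int = 10,
    seed: int = 0,
    matched: bool = True,
) -> np.ndarray:
    """Background peak indices matched on (GC, mean normalized accessibility).

    Peaks are ranked into ``n_bins`` equal-frequency bins along each of GC
    content and mean library-normalized accessibility; for each iteration
    every peak is replaced by one sampled with replacement from its own 2-D
    bin. ``matched=False`` switches to unmatched uniform sampling over all
    peaks. Returns an (n_iterations, n_peaks) integer index array; seeded
    and reproducible.
    """
    if n_iterations < 2:
        raise ValueError("at least 2 background iterations are required for a sd")
    peak_ids = (
        list(accessome_or_ids.peak_ids)
        if isinstance(accessome_or_ids, Accessome)
        else list(accessome_or_ids)
    )
    if list(counts.index) != peak_ids:
        counts = counts.reindex(peak_ids)
    rng = np.random.default_rng(seed)
    n = len(peak_ids)
    if not matched:
        return rng.integers(0, n, size=(n_iterations, n))
    gc = _gc_content(sequences, peak_ids)
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    access = (counts.to_numpy(dtype=float) / lib[None, :]).mean(axis=1)

    def bin_ids(x):
        ranks = sps.rankdata(x, method="average") - 1
        return np.minimum((ranks / len(x) * n_bins).astype(int), n_bins - 1)

    cell = bin_ids(gc) * n_bins + bin_ids(access)
    out = np.empty((n_iterations, n), dtype=np.int64)
    members: dict[int, np.ndarray] = {
        c: np.flatnonzero(cell == c) for c in np.unique(cell)
    }
    for it in range(n_iterations):
        for c, idx in members.items():
            out[it, idx] = rng.choice(idx, size=idx.size, replace=True)
    return out


@dataclass
class DeviationMatrix:
    raw_deviation: pd.DataFrame  # motif x sample
    zscore: pd.DataFrame  # motif x sample
    background_params: dict = field(default_factory=dict)
    flagged: pd.DataFrame | None = None  # motif x sample bool (sd == 0)


def deviation_zscores(
    counts: pd.DataFrame,
    hits,
    backgrounds: np.ndarray,
    library_sizes: pd.Series | None = None,
) -> DeviationMatrix:
    """Deviation Z-scores against sampled background peak sets.

    z = (raw - mean(background raw)) / sd(background raw), where each
    background deviation replaces every peak's count row by its matched
    sampled peak before recomputing observed/expected. Background
    expectations use the background matrix's own column totals as library
    sizes, so a motif covering every peak deviates exactly zero in every
    background iteration (degenerate: flagged NA). Motif/sample entries with
    zero background sd are NA and flagged.
    """
    backgrounds = np.asarray(backgrounds)
    if backgrounds.ndim != 2 or backgrounds.shape[0] < 2:
        raise ValueError("need at least 2 background iterations")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    _, _, raw = motif_observed_expected(counts, hits, library_sizes)
    bg_devs = np.empty((backgrounds.shape[0],) + raw.shape)
    mat = counts.to_numpy()
    for i, idx in enumerate(backgrounds):
        bg_counts = pd.DataFrame(mat[idx], index=counts.index, columns=counts.columns)
        _, _, bg_raw = motif_observed_expected(bg_counts, hits, None)
        bg_devs[i] = bg_raw.to_numpy()
    mean_bg = bg_devs.mean(axis=0)
    sd_bg = bg_devs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_bg > 0, (raw.to_numpy() - mean_bg) / sd_bg, np.nan)
    flagged = pd.DataFrame(
        ~(sd_bg > 0), index=raw.index, columns=raw.columns
    )
    return DeviationMatrix(
        raw,
        pd.DataFrame(z, index=raw.index, columns=raw.columns),
        {"n_iterations": int(backgrounds.shape[0])},
        flagged,
    )


def differential_deviations(
    deviations: DeviationMatrix | pd.DataFrame,
    groups: pd.Series,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-motif group test on deviation Z-scores.

    Two groups: Welch t-test; more: one-way ANOVA. BH FDR across motifs;
    ``significant`` marks FDR < 0.01 (the default reporting threshold).
    """
    z = deviations.zscore if isinstance(deviations, DeviationMatrix) else deviations
    groups = pd.Series(groups).reindex(z.columns)
    if groups.isna().any():
        raise ValueError("groups must cover every sample column")
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    cols_by_level = {lv: z.columns[groups == lv] for lv in levels}
    for lv, cols in cols_by_level.items():
        if len(cols) < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    rows = []
    for motif in z.index:
        vecs = [z.loc[motif, cols].dropna().to_numpy() for cols in cols_by_level.values()]
        if any(v.size < 2 for v in vecs):
            rows.append((motif, np.nan) + tuple(np.nan for _ in levels))
            continue
        if len(vecs) == 2:
            if np.allclose(vecs[0], vecs[1]) and np.ptp(np.concatenate(vecs)) == 0:
                p = 1.0
            else:
                p = sps.ttest_ind(vecs[0], vecs[1], equal_var=False).pvalue
        else:
            p = sps.f_oneway(*vecs).pvalue
        if np.isnan(p):  # zero variance in both groups
            p = 1.0
        rows.append((motif, float(p)) + tuple(float(v.mean()) for v in vecs))
    out = pd.DataFrame(
        rows, columns=["motif_id", "p_value"] + [f"mean_{lv}" for lv in levels]
    ).set_index("motif_id")
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < fdr_threshold
    return out
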
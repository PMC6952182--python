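"""PWM parsing and scanning, motif-to-TF assignment, and motif enrichment.

Motif matches use log-odds scores log2(P(base|PWM)/P(base|background)) with a
score threshold set so that the probability of a background sequence reaching
it is at most a p-value cutoff (default 5e-5). The background score
distribution is computed exactly by dynamic programming over a discretized
score grid; scanning uses the same integer grid so threshold comparisons are
exact. Enrichment of a motif in a peak set versus the accessome is a
one-tailed hypergeometric test on peak-level occupancy, with the odds ratio
comparing in-set odds to whole-accessome odds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import Accessome
from .stats import bh_fdr, hypergeom_sf

__all__ = [
    "PWM",
    "MotifHitMatrix",
    "MotifTFCatalog",
    "read_meme",
    "write_meme",
    "read_jaspar",
    "background_frequencies",
    "pwm_threshold",
    "scan_sequences",
    "motif_enrichment",
    "assign_motifs_to_tfs",
]

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4
DEFAULT_PSEUDOCOUNT = 0.8


@dataclass
class PWM:
    """A position probability matrix with its pseudocount provenance.

    ``matrix`` is (length x 4) over A, C, G, T; each row sums to 1 and all
    entries are positive after pseudocounting.
    """

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"PWM {self.motif_id}: matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.motif_id}: rows must sum to 1")
        if (self.matrix <= 0).any():
            raise ValueError(f"PWM {self.motif_id}: zero entries (pseudocount missing?)")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.pseudocount)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """Per-position log2(p/bg) score matrix."""
        bg = np.asarray(background, dtype=float)
        return np.log2(self.matrix / bg[None, :])


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Probability matrix from counts with a background-split pseudocount."""
    counts = np.asarray(counts, dtype=float)
    bg = (
        np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    )
    total = counts.sum(axis=1, keepdims=True)
    mat = (counts + pseudocount * bg[None, :]) / (total + pseudocount)
    return PWM(motif_id, mat, pseudocount)


def regularize_probabilities(
    motif_id: str,
    probs: np.ndarray,
    nsites: float = 20.0,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Pseudocount a probability matrix via its (possibly nominal) site count."""
    probs = np.asarray(probs, dtype=float)
    return pwm_from_counts(motif_id, probs * nsites, background, pseudocount)


# ---------------------------------------------------------------------------
# MEME minimal / JASPAR readers (Bio.motifs backend)


def read_meme(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    for mot in record:
        probs = np.array(
            [[mot.pwm[b][i] for b in BASES] for i in range(mot.length)], dtype=float
        )
        nsites = getattr(mot, "num_occurrences", 0) or 20.0
        name = mot.name or mot.consensus
        out.append(regularize_probabilities(str(name), probs, nsites, None, pseudocount))
    return out


def write_meme(
    path: str | Path, pwms: list[PWM], background=None, nsites: int = 100_000
) -> None:
    # a large nominal nsites keeps probabilities faithful through parsers
    # that reconstruct integer counts from the printed matrix
    bg = np.full(4, 0.25) if background is None else np.asarray(background)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg))
            + "\n\n"
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    from Bio import motifs as bio_motifs

    out = []
    with open(path) as fh:
        for mot in bio_motifs.parse(fh, "jaspar"):
            counts = np.array(
                [[mot.counts[b][i] for b in BASES] for i in range(mot.length)],
                dtype=float,
            )
            name = mot.matrix_id or mot.name
            out.append(pwm_from_counts(str(name), counts, None, pseudocount))
    return out


# ---------------------------------------------------------------------------
# exact score thresholds


def background_frequencies(sequences) -> np.ndarray:
    """A/C/G/T frequencies over a collection of sequences (N ignored)."""
    counts = np.ones(4)  # one pseudo-observation per base keeps freqs positive
    for seq in sequences.values() if hasattr(sequences, "values") else sequences:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        for i, base in enumerate(BASES):
            counts[i] += int((arr == ord(base)).sum())
    return counts / counts.sum()


def _int_score_matrix(
    pwm: PWM, background: np.ndarray, granularity: float
) -> np.ndarray:
    """(L x 5) integer score matrix on a `granularity`-bit grid; N scores 0."""
    lo = pwm.log_odds(background)
    ints = np.rint(lo / granularity).astype(np.int64)
    return np.concatenate([ints, np.zeros((len(pwm), 1), dtype=np.int64)], axis=1)


def _int_threshold(
    int_scores: np.ndarray, background: np.ndarray, p_cutoff: float
) -> int | None:
    """Smallest integer score s with P_bg(score >= s) <= p_cutoff, by exact DP."""
    scores = int_scores[:, :4]
    mins = scores.min(axis=1)
    maxs = scores.max(axis=1)
    lo_total, hi_total = int(mins.sum()), int(maxs.sum())
    width = hi_total - lo_total + 1
    dist = np.zeros(width)
    offset = -lo_total  # index of integer score 0 ... shifted by lo_total
    # dist[i] = P(partial sum == i + running_lo)
    dist[0] = 1.0
    running_lo = 0
    cur_len = 1
    for pos in range(scores.shape[0]):
        new_lo = running_lo + int(mins[pos])
        new_len = cur_len + int(maxs[pos] - mins[pos])
        new = np.zeros(new_len)
        for b in range(4):
            shift = int(scores[pos, b] - mins[pos])
            new[shift : shift + cur_len] += background[b] * dist[:cur_len]
        dist = new
        cur_len = new_len
        running_lo = new_lo
    tail = np.cumsum(dist[::-1])[::-1]
    ok = np.flatnonzero(tail <= p_cutoff)
    if ok.size == 0:
        return None
    return int(ok[0]) + running_lo


def pwm_threshold(
    pwm: PWM,
    background_frequencies: np.ndarray,
    p_cutoff: float = 5e-5,
    granularity: float = 1e-3,
) -> float:
    """Log-odds score threshold (bits) at an exact background p-value cutoff.

    Returns +inf (with a warning) when no score is rare enough under the
    background — e.g. a fully uninformative matrix.
    """
    if not (0 < p_cutoff < 1):
        raise ValueError(f"p_cutoff={p_cutoff} outside (0, 1)")
    bg = np.asarray(background_frequencies, dtype=float)
    if (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background frequencies must be positive and sum to 1")
    ints = _int_score_matrix(pwm, bg, granularity)
    thr = _int_threshold(ints, bg, p_cutoff)
    if thr is None:
        warnings.warn(
            f"motif {pwm.motif_id}: no score reaches p <= {p_cutoff}; "
            "no positions can match"
        )
        return float("inf")
    return thr * granularity


# ---------------------------------------------------------------------------
# scanning


@dataclass
class MotifHitMatrix:
    """Peak x motif occupancy plus per-hit positions, strands and scores."""

    occupancy: pd.DataFrame  # bool, peaks x motifs
    hits: pd.DataFrame  # peak_id, motif_id, position, strand, score
    thresholds: dict[str, float] = field(default_factory=dict)

    def motif_peak_counts(self) -> pd.Series:
        return self.occupancy.sum(axis=0)


def _encode(seq: str, peak_id: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, -1, dtype=np.int64)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        bad = chr(arr[int(np.flatnonzero(codes < 0)[0])])
        raise ValueError(f"invalid character {bad!r} in sequence for peak {peak_id}")
    return codes


def scan_sequences(
    sequences: dict[str, str],
    pwms: list[PWM],
    background: np.ndarray | None = None,
    p_cutoff: float = 5e-5,
    granularity: float = 1e-3,
) -> MotifHitMatrix:
    """Scan both strands of each sequence for PWM matches above threshold.

    ``background`` defaults to the nucleotide frequencies of the scanned
    sequence set (the documented contract: the full accessome sequences).
    Positions are 0-based window starts in the forward coordinate system; a
    minus-strand hit at position i means the reverse complement of the site
    starts at i. Ambiguous bases (N) score zero and cannot create a match.
    """
    bg = (
        background_frequencies(sequences)
        if background is None
        else np.asarray(background, dtype=float)
    )
    encoded = {pid: _encode(seq, pid) for pid, seq in sequences.items()}
    peak_ids = list(sequences)
    occupancy = pd.DataFrame(
        False, index=pd.Index(peak_ids, name="peak_id"),
        columns=[p.motif_id for p in pwms],
    )
    hit_rows = []
    thresholds: dict[str, float] = {}
    for pwm in pwms:
        ints_fwd = _int_score_matrix(pwm, bg, granularity)
        thr = _int_threshold(ints_fwd[:, :4], bg, p_cutoff)
        thresholds[pwm.motif_id] = (
            float("inf") if thr is None else thr * granularity
        )
        if thr is None:
            continue
        ints_rev = _int_score_matrix(pwm.reverse_complement(), bg, granularity)
        L = len(pwm)
        for pid in peak_ids:
            codes = encoded[pid]
            if codes.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, L)
            for strand, ints in (("+", ints_fwd), ("-", ints_rev)):
                scores = ints[np.arange(L)[None, :], windows].sum(axis=1)
                for pos in np.flatnonzero(scores >= thr):
                    hit_rows.append(
                        (
                            pid, pwm.motif_id, int(pos), strand,
                            float(scores[pos] * granularity),
                        )
                    )
                    occupancy.loc[pid, pwm.motif_id] = True
    hits = pd.DataFrame(
        hit_rows, columns=["peak_id", "motif_id", "position", "strand", "score"]
    )
    return MotifHitMatrix(occupancy, hits, thresholds)


# ---------------------------------------------------------------------------
# enrichment


def motif_enrichment(
    hits: MotifHitMatrix | pd.DataFrame,
    peak_set,
    accessome: Accessome | set[str],
    effect: str = "odds_ratio",
) -> pd.DataFrame:
    """One-tailed hypergeometric motif enrichment of a peak set vs accessome.

    For each motif: a = set peaks with the motif, m = accessome peaks with the
    motif, N = accessome size, n = set size; p = P(X >= a). The default
    effect size is the odds ratio [a/(n-a)] / [m/(N-m)] (set odds vs
    accessome odds); ``effect="relative_risk"`` reports (a/n) / (m/N)
    instead. Either uses a Haldane 0.5 continuity correction (flagged) when a
    zero makes the raw ratio undefined; the choice is recorded in the output.
    FDR is BH across motifs.
    """
    if effect not in ("odds_ratio", "relative_risk"):
        raise ValueError(f"unknown effect measure {effect!r}")
    occupancy = hits.occupancy if isinstance(hits, MotifHitMatrix) else hits
    universe = (
        list(accessome.peak_ids) if isinstance(accessome, Accessome) else list(accessome)
    )
    occ = occupancy.reindex(universe).fillna(False)
    members = peak_set.members if hasattr(peak_set, "members") else set(peak_set)
    if not members <= set(universe):
        raise ValueError("peak set not contained in the accessome")
    in_set = occ.index.isin(members)
    N = len(universe)
    n_set = int(in_set.sum())
    rows = []
    for motif in occ.columns:
        col = occ[motif].to_numpy()
        m = int(col.sum())
        a = int(col[in_set].sum())
        if m == 0:
            rows.append((motif, a, n_set, m, N, 1.0, np.nan, np.nan, True))
            continue
        p = hypergeom_sf(a, N, m, n_set)
        corrected = False
        if effect == "odds_ratio":
            num_a, num_b = a, n_set - a
            den_a, den_b = m, N - m
        else:  # relative risk: in-set rate over accessome rate
            num_a, num_b = a, n_set
            den_a, den_b = m, N
        if min(num_a, num_b, den_a, den_b) == 0:
            corrected = True
            num_a, num_b = num_a + 0.5, num_b + 0.5
            den_a, den_b = den_a + 0.5, den_b + 0.5
        odds = (num_a / num_b) / (den_a / den_b)
        rows.append((motif, a, n_set, m, N, p, odds, np.log2(odds), corrected))
    out = pd.DataFrame(
        rows,
        columns=[
            "motif_id", "a", "set_size", "m", "universe_size",
            "p_value", "odds_ratio", "log2_or", "continuity_corrected",
        ],
    )
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["effect_measure"] = effect
    return out


# ---------------------------------------------------------------------------
# motif -> TF assignment


@dataclass
class MotifTFCatalog:
    """Candidate motif<->TF associations and the resolved assignment."""

    candidates: dict[str, set[str]]
    assignment: dict[str, list[str]] = field(default_factory=dict)  # tf -> motifs
    motif_to_tf: dict[str, str] = field(default_factory=dict)
    unassigned_tfs: list[str] = field(default_factory=list)


def assign_motifs_to_tfs(candidates: dict[str, set[str]]) -> MotifTFCatalog:
    """Iteratively resolve many-to-many motif/TF associations to one TF each.

    Round structure (stage k = 1, 2, 3, ...): every motif with exactly one
    remaining candidate TF is assigned to it; associations pointing at TFs
    that now own a motif are dropped (a motif left with no candidates stays
    unassigned); this propagates to a fixed point. If candidates remain, the
    motif with the fewest remaining TFs (ties broken by motif id, then TF id)
    is assigned to its first TF, and propagation restarts. Terminates for any
    finite catalog; TFs that never receive a motif are reported unassigned.
    """
    cand = {m: set(tfs) for m, tfs in candidates.items() if tfs}
    all_tfs = sorted({tf for tfs in cand.values() for tf in tfs})
    motif_to_tf: dict[str, str] = {}
    owned: set[str] = set()

    def propagate() -> None:
        changed = True
        while changed:
            changed = False
            singles = sorted(m for m in cand if len(cand[m]) == 1)
            for m in singles:
                tf = next(iter(cand[m]))
                motif_to_tf[m] = tf
                owned.add(tf)
                del cand[m]
                changed = True
            for m in sorted(cand):
                remaining = cand[m] - owned
                if remaining != cand[m]:
                    changed = True
                    if remaining:
                        cand[m] = remaining
                    else:
                        del cand[m]

    propagate()
    while cand:
        count, m = min((len(cand[m]), m) for m in cand)
        tf = min(cand[m])
        motif_to_tf[m] = tf
        owned.add(tf)
        del cand[m]
        propagate()

    assignment: dict[str, list[str]] = {}
    for m in sorted(motif_to_tf):
        assignment.setdefault(motif_to_tf[m], []).append(m)
    unassigned = [tf for tf in all_tfs if tf not in assignment]
    return MotifTFCatalog(
        {m: set(tfs) for m, tfs in candidates.items()},
        assignment,
        motif_to_tf,
        unassigned,
    )
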
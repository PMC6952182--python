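"""Genomic interval model, BED/chrom-sizes I/O, and accessome construction.

All coordinates are 0-based half-open (BED convention). GFF3 input (see
:mod:`accessome.gene_models`) is converted to this convention at parse time so
that a single convention is used everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Accessome",
    "merge_intervals",
    "merge_to_accessome",
    "genome_coverage_fraction",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval with 0-based half-open coordinates.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded, the default for
    ATAC-seq peaks).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _peak_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


@dataclass
class Accessome:
    """An ordered atlas of non-overlapping accessible regions.

    The accessome is the universe for every enrichment statistic downstream:
    feature enrichment, motif enrichment, set-intersection tests and deviation
    backgrounds all count over its peaks.

    Attributes
    ----------
    peaks : pandas.DataFrame
        Columns ``chrom``, ``start``, ``end``, ``peak_id``; sorted by
        (chrom, start); pairwise non-overlapping within a chromosome.
    genome_sizes : dict
        Chromosome name -> length in bp.
    """

    peaks: pd.DataFrame
    genome_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "peak_id"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise ValueError(f"accessome table missing columns {sorted(missing)}")
        self.validate()

    def validate(self) -> None:
        df = self.peaks
        if df["peak_id"].duplicated().any():
            dup = df.loc[df["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise ValueError(f"duplicate peak id {dup}")
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in self.genome_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            size = self.genome_sizes[chrom]
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts < 0).any() or (ends > size).any():
                bad = sub[(starts < 0) | (ends > size)].iloc[0]
                raise ValueError(
                    f"peak out of bounds: {chrom}:{bad.start}-{bad.end} "
                    f"(chromosome length {size})"
                )
            if (ends <= starts).any():
                raise ValueError(f"empty interval on {chrom}")
            order = np.argsort(starts, kind="stable")
            if (ends[order][:-1] > starts[order][1:]).any():
                raise ValueError(f"overlapping peaks on {chrom}")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def peak_ids(self) -> pd.Index:
        return pd.Index(self.peaks["peak_id"])

    def lengths(self) -> pd.Series:
        out = self.peaks["end"] - self.peaks["start"]
        out.index = self.peaks["peak_id"]
        return out

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in self.peaks.itertuples()
        ]

    def sequences(self, fasta) -> dict[str, str]:
        """Extract peak sequences from a pyfaidx.Fasta (or mapping of strings)."""
        out: dict[str, str] = {}
        for r in self.peaks.itertuples():
            seq = fasta[r.chrom][int(r.start) : int(r.end)]
            out[r.peak_id] = str(seq).upper()
        return out


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    """Sort-and-sweep merge; book-ended intervals (end == next start) merge."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def merge_to_accessome(
    peak_sets: Sequence[Iterable[GenomicInterval | tuple[str, int, int]]],
    genome_sizes: Mapping[str, int],
    min_length: int = 51,
) -> Accessome:
    """Concatenate per-sample peak lists into a reference accessome.

    All input intervals are pooled, merged (book-ended intervals sharing a
    boundary are merged), and merged intervals shorter than ``min_length``
    (default 51 bp, i.e. keeping length > 50 bp) are removed. Stable peak IDs
    ``chrom:start-end`` are assigned in (chrom, start) order.
    """
    genome_sizes = dict(genome_sizes)
    pooled: list[tuple[str, int, int]] = []
    for peak_set in peak_sets:
        for iv in peak_set:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            if chrom not in genome_sizes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if start < 0 or end > genome_sizes[chrom] or end <= start:
                raise ValueError(
                    f"interval out of chromosome bounds: {chrom}:{start}-{end} "
                    f"(chromosome length {genome_sizes[chrom]})"
                )
            pooled.append((chrom, start, end))

    if not pooled:
        peaks = pd.DataFrame(columns=["chrom", "start", "end", "peak_id"])
        return Accessome(peaks, genome_sizes)

    merged = [
        (c, s, e) for c, s, e in merge_intervals(pooled) if e - s >= min_length
    ]
    peaks = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    peaks["peak_id"] = [
        _peak_id(c, s, e) for c, s, e in zip(peaks.chrom, peaks.start, peaks.end)
    ]
    return Accessome(peaks.reset_index(drop=True), genome_sizes)


def genome_coverage_fraction(accessome: Accessome) -> float:
    """Fraction of the genome covered by accessome peaks."""
    total = sum(accessome.genome_sizes.values())
    if total <= 0:
        raise ValueError("zero-length genome")
    covered = int((accessome.peaks["end"] - accessome.peaks["start"]).sum())
    return covered / total


# ---------------------------------------------------------------------------
# I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, 0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand)
            )
    return out


def write_bed(path: str | Path, intervals_or_accessome) -> None:
    """Write BED; accessome peaks carry their IDs in column 4."""
    with open(path, "w") as fh:
        if isinstance(intervals_or_accessome, Accessome):
            for r in intervals_or_accessome.peaks.itertuples():
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.peak_id}\n")
        else:
            for iv in intervals_or_accessome:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(path: str | Path, sizes: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
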
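"""Peak-level genomic feature annotation and peak-to-gene association.

Windows follow the atlas conventions: the TSS is a +/-107 bp window around the
start of the annotated 5'UTR (a TSS-cluster-derived core-promoter width), the
promoter is the 1 kb upstream of the TSS split into proximal and distal 500 bp
windows, and the TTS is a +/-200 bp window around the 3'UTR end. A peak
carries every feature label it overlaps by at least one bp; peaks touching no
feature are intergenic. Genes are associated with every peak within 10 kb of
the gene span, and feature over/under-representation in the accessome is
tested with a two-tailed binomial whose null probability is the fraction of
the genome the feature covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .gene_models import GeneModel
from .intervals import Accessome, merge_intervals
from .stats import BinomialTestResult, binomial_two_tailed

__all__ = [
    "FeatureMap",
    "PeakGeneMap",
    "build_feature_map",
    "classify_peaks",
    "associate_peaks_to_genes",
    "peak_gene_summary",
    "binomial_enrichment",
    "feature_enrichment_table",
    "FEATURE_PRECEDENCE",
]

FEATURE_PRECEDENCE = [
    "TSS",
    "promoter_proximal_500",
    "promoter_distal_500",
    "5UTR",
    "exon",
    "3UTR",
    "TTS",
    "intron",
]


@dataclass
class FeatureMap:
    """Per-label merged interval sets plus each label's genome fraction."""

    labels: dict[str, list[tuple[str, int, int]]]
    genome_sizes: dict[str, int]
    fractions: dict[str, float] = field(default_factory=dict)
    _trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.genome_sizes.values())
        for label, ivs in self.labels.items():
            covered = sum(e - s for _, s, e in ivs)
            self.fractions[label] = covered / total if total else 0.0
            trees: dict[str, IntervalTree] = {}
            for chrom, s, e in ivs:
                trees.setdefault(chrom, IntervalTree()).addi(s, e)
            self._trees[label] = trees

    def overlapping_labels(self, chrom: str, start: int, end: int) -> set[str]:
        out = set()
        for label, trees in self._trees.items():
            tree = trees.get(chrom)
            if tree is not None and tree.overlap(start, end):
                out.add(label)
        return out


def _clip(ivs, chrom, genome_sizes):
    size = genome_sizes[chrom]
    out = []
    for s, e in ivs:
        s, e = max(0, s), min(size, e)
        if e > s:
            out.append((chrom, s, e))
    return out


def build_feature_map(
    gene_models: list[GeneModel],
    genome_sizes: dict[str, int],
    tss_halfwidth: int = 107,
    promoter_length: int = 1000,
    tts_halfwidth: int = 200,
) -> FeatureMap:
    """Build strand-aware feature windows from gene models.

    For a plus-strand transcript with TSS anchor ``p``: TSS window
    ``[p-107, p+107)``; promoter ``[p-1000, p)`` split into distal
    ``[p-1000, p-500)`` and proximal ``[p-500, p)``. Minus-strand windows are
    mirrored (promoter at coordinates greater than the TSS). The TTS window is
    ``[q-200, q+200)`` around the 3'UTR end boundary ``q``. All windows are
    clipped to chromosome bounds; introns are the transcript span minus exons.
    """
    half_prom = promoter_length // 2
    raw: dict[str, list[tuple[str, int, int]]] = {
        label: [] for label in FEATURE_PRECEDENCE
    }
    for gene in gene_models:
        for tx in gene.transcripts:
            if not tx.exons:
                raise ValueError(f"transcript {tx.transcript_id} has no exons")
            chrom = tx.chrom
            p = tx.tss_position()
            raw["TSS"] += _clip([(p - tss_halfwidth, p + tss_halfwidth)], chrom, genome_sizes)
            if tx.strand == "-":
                prox = (p + 1, p + 1 + half_prom)
                dist = (p + 1 + half_prom, p + 1 + promoter_length)
            else:
                prox = (p - half_prom, p)
                dist = (p - promoter_length, p - half_prom)
            raw["promoter_proximal_500"] += _clip([prox], chrom, genome_sizes)
            raw["promoter_distal_500"] += _clip([dist], chrom, genome_sizes)
            q = tx.tes_boundary()
            raw["TTS"] += _clip([(q - tts_halfwidth, q + tts_halfwidth)], chrom, genome_sizes)
            raw["exon"] += _clip(tx.exons, chrom, genome_sizes)
            raw["5UTR"] += _clip(tx.utr5, chrom, genome_sizes)
            raw["3UTR"] += _clip(tx.utr3, chrom, genome_sizes)
            raw["intron"] += _clip(tx.introns(), chrom, genome_sizes)
    labels = {
        label: merge_intervals(ivs) if ivs else []
        for label, ivs in raw.items()
    }
    return FeatureMap(labels, dict(genome_sizes))


def classify_peaks(accessome: Accessome, feature_map: FeatureMap) -> pd.DataFrame:
    """Multi-label classification of peaks; unlabeled peaks are intergenic.

    Returns a DataFrame indexed by peak_id with boolean columns per label, an
    ``intergenic`` column, and a ``primary_label`` column resolved by the
    precedence order TSS > promoter > 5UTR > exon > 3UTR > TTS > intron.
    """
    unknown = set(accessome.peaks["chrom"]) - set(feature_map.genome_sizes)
    if unknown:
        raise ValueError(f"accessome chromosomes absent from feature map: {sorted(unknown)}")
    rows = []
    for r in accessome.peaks.itertuples():
        labels = feature_map.overlapping_labels(r.chrom, int(r.start), int(r.end))
        rows.append(labels)
    out = pd.DataFrame(
        [[lab in labels for lab in FEATURE_PRECEDENCE] for labels in rows],
        columns=FEATURE_PRECEDENCE,
        index=accessome.peak_ids,
    )
    out["intergenic"] = ~out[FEATURE_PRECEDENCE].any(axis=1)
    primary = []
    for labels in rows:
        primary.append(
            next((lab for lab in FEATURE_PRECEDENCE if lab in labels), "intergenic")
        )
    out["primary_label"] = primary
    return out


@dataclass
class PeakGeneMap:
    """Many-to-many peak<->gene associations with signed genomic distances.

    ``associations`` has columns ``peak_id``, ``gene_id``, ``distance`` where
    distance is 0 for peaks overlapping the gene span, negative for peaks
    upstream of the span in genome coordinates and positive downstream.
    """

    associations: pd.DataFrame
    window: int

    def genes_for_peak(self, peak_id: str) -> list[str]:
        df = self.associations
        return df.loc[df["peak_id"] == peak_id, "gene_id"].tolist()

    def peaks_for_genes(self, gene_ids) -> set[str]:
        gene_ids = set(gene_ids)
        df = self.associations
        return set(df.loc[df["gene_id"].isin(gene_ids), "peak_id"])

    def peak_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.associations.itertuples():
            out.setdefault(r.peak_id, set()).add(r.gene_id)
        return out


def associate_peaks_to_genes(
    accessome: Accessome,
    gene_models: list[GeneModel],
    window: int = 10_000,
) -> PeakGeneMap:
    """Associate each peak with every gene whose span +/- window overlaps it."""
    trees: dict[str, IntervalTree] = {}
    spans: dict[str, tuple[str, int, int]] = {}
    for gene in gene_models:
        s, e = gene.span
        spans[gene.gene_id] = (gene.chrom, s, e)
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            max(0, s - window), e + window, gene.gene_id
        )
    rows = []
    for r in accessome.peaks.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(int(r.start), int(r.end)):
            gid = hit.data
            _, gs, ge = spans[gid]
            if r.end <= gs:
                dist = int(r.end) - gs  # upstream in genome coords: negative
            elif r.start >= ge:
                dist = int(r.start) - ge + 1
            else:
                dist = 0
            rows.append((r.peak_id, gid, dist))
    df = pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance"])
    return PeakGeneMap(df.sort_values(["peak_id", "gene_id"]).reset_index(drop=True), window)


def peak_gene_summary(pg_map: PeakGeneMap) -> dict[str, float]:
    """Median peaks per gene and genes per peak, over non-empty rows."""
    df = pg_map.associations
    if df.empty:
        raise ValueError("empty peak-gene map")
    peaks_per_gene = df.groupby("gene_id")["peak_id"].nunique()
    genes_per_peak = df.groupby("peak_id")["gene_id"].nunique()
    return {
        "median_peaks_per_gene": float(np.median(peaks_per_gene)),
        "median_genes_per_peak": float(np.median(genes_per_peak)),
    }


def binomial_enrichment(k: int, n: int, p0: float) -> BinomialTestResult:
    """Two-tailed binomial enrichment (shared engine; see :mod:`accessome.stats`)."""
    return binomial_two_tailed(k, n, p0)


def gene_class_peak_enrichment(
    pg_map: PeakGeneMap, class_genes, all_genes
) -> dict:
    """Test whether a gene class attracts more peak associations than expected.

    k = associations to class genes, n = all associations, p0 = the class's
    share of genes. The p0 construction is a documented convention (the
    natural null when every gene is equally likely to receive an
    association), flagged in the returned metadata.
    """
    class_genes, all_genes = set(class_genes), set(all_genes)
    if not class_genes <= all_genes:
        raise ValueError("class genes must be a subset of all genes")
    if not all_genes:
        raise ValueError("empty gene universe")
    df = pg_map.associations
    n = len(df)
    k = int(df["gene_id"].isin(class_genes).sum())
    p0 = len(class_genes) / len(all_genes)
    result = binomial_two_tailed(k, n, p0)
    return {
        "k": k,
        "n": n,
        "p0": p0,
        "p_value": result.p_value,
        "direction": result.direction,
        "null": "class share of genes (convention)",
    }


def feature_enrichment_table(
    classification: pd.DataFrame, feature_map: FeatureMap
) -> pd.DataFrame:
    """Per-feature two-tailed binomial enrichment of peaks vs genome fraction.

    k = peaks overlapping the feature, n = total peaks, p0 = the feature's
    genome fraction.
    """
    n = len(classification)
    rows = []
    for label in FEATURE_PRECEDENCE:
        p0 = feature_map.fractions.get(label, 0.0)
        k = int(classification[label].sum())
        if 0 < p0 < 1 and n > 0:
            res = binomial_two_tailed(k, n, p0)
            rows.append((label, k, n, p0, res.p_value, res.direction))
        else:
            rows.append((label, k, n, p0, np.nan, "n/a"))
    return pd.DataFrame(
        rows, columns=["feature", "k", "n", "p0", "p_value", "direction"]
    )
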
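"""Synthetic fixtures with the statistical structure the pipeline assumes.

The generator emulates a lineage-resolved ATAC-seq design: a small
multi-chromosome genome with non-overlapping gene models, a non-overlapping
peak atlas, NB-distributed fragment counts with library-size variation and
planted condition/timepoint/lineage effects of stated size, and informative
motifs planted into chosen peak sets. Every planted membership is recorded in
a truth bundle so recovery can be scored. All randomness flows from a single
seed through integer-stream NumPy generators, so outputs are byte-identical
across runs and platforms.

Default condition scale (chosen once as a desk-scale emulation of the study
design; see docs/methods.md): 4 x 400 kb chromosomes at GC 0.36, 160 genes,
800 peaks of ~185 bp mean (≈9-10% genome coverage), NB dispersion 0.1,
planted |log2FC| = 2, three replicates per design cell, base means log-uniform
on [400, 2000] fragments so that library totals clear the 500,000-read
filter, library factors log-uniform on [1.0, 2.5], and one deliberately
shallow replicate that the filter removes. Planted closing:opening set sizes at the
6->10 hpf transition (200:109) mirror the roughly two-thirds closing
proportion of the study design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gene_models import GeneModel, Transcript, write_gff3
from .intervals import Accessome, merge_to_accessome, write_bed, write_chrom_sizes
from .motifs import PWM, write_meme

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "default_motif_catalog",
    "simulate_genome_and_genes",
    "place_peaks",
    "simulate_counts",
    "plant_motifs",
    "simulate_de_tables",
    "make_fixture_bundle",
]

BASES = "ACGT"

#: design cells (lineage, condition, timepoint, n_replicates) mirroring the
#: sampled stages: naive mesoderm (6 hpf), multipotent progenitors (10 hpf,
#: with FGF-MAPK perturbations), fate-restricted precursors (18 hpf), plus
#: the mesenchyme outgroup lineage.
DEFAULT_DESIGN = [
    ("B7.5", "control", 6, 3),
    ("B7.5", "control", 10, 3),
    ("B7.5", "fgfr_dn", 10, 3),
    ("B7.5", "mek_act", 10, 3),
    ("B7.5", "control", 18, 3),
    ("B7.5", "fgfr_dn", 18, 3),
    ("B7.5", "mras_ca", 18, 3),
    ("mesenchyme", "control", 10, 3),
    ("mesenchyme", "control", 18, 3),
]

DEFAULT_SET_SIZES = {
    "opened_by_fgf_mapk_10hpf": 109,
    "closing_6_to_10": 200,
    "closed_by_fgf_mapk_10hpf": 60,
    "opened_by_fgf_mapk_18hpf": 40,
    "closed_by_fgf_mapk_18hpf": 40,
    "denovo_cardiac": 20,
    "denovo_asm": 20,
    "b75_specific": 60,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chrom_length: int = 400_000
    gc_content: float = 0.36
    n_genes: int = 160
    n_peaks: int = 800
    peak_length_range: tuple[int, int] = (120, 260)
    design: list[tuple] = field(default_factory=lambda: list(DEFAULT_DESIGN))
    set_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SET_SIZES))
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    base_mean_range: tuple[float, float] = (400.0, 2000.0)
    library_factor_range: tuple[float, float] = (1.0, 2.5)
    n_shallow_libraries: int = 1  # replicates planted below the read filter
    motif_insertion_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class TruthBundle:
    peak_sets: dict[str, list[str]]
    gene_sets: dict[str, list[str]]
    motif_registry: pd.DataFrame  # motif_id, peak_id, position, strand

    def to_json(self, path: str | Path) -> None:
        payload = {
            "peak_sets": self.peak_sets,
            "gene_sets": self.gene_sets,
            "motif_registry": self.motif_registry.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            payload["peak_sets"],
            payload["gene_sets"],
            pd.DataFrame(
                payload["motif_registry"],
                columns=["motif_id", "peak_id", "position", "strand"],
            ),
        )


def _sharp_pwm(motif_id: str, consensus: str, p_major: float = 0.997) -> PWM:
    minor = (1.0 - p_major) / 3.0
    mat = np.full((len(consensus), 4), minor)
    for i, base in enumerate(consensus):
        mat[i, BASES.index(base)] = p_major
    return PWM(motif_id, mat)


def default_motif_catalog() -> dict[str, PWM]:
    """Five sharp 8-bp motifs: three planted lineage motifs plus two decoys."""
    return {
        "FOXF_LIKE": _sharp_pwm("FOXF_LIKE", "GTAAACAA"),
        "TBX_LIKE": _sharp_pwm("TBX_LIKE", "AGGTGTGA"),
        "EBF_LIKE": _sharp_pwm("EBF_LIKE", "TCCCTGGG"),
        "ZIC_DECOY": _sharp_pwm("ZIC_DECOY", "CCCCGCTG"),
        "POU_DECOY": _sharp_pwm("POU_DECOY", "ATGCAAAT"),
    }


# ---------------------------------------------------------------------------
# genome, genes, peaks


def simulate_genome_and_genes(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], dict[str, int]]:
    """I.i.d. background genome plus non-overlapping gene models."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    genome = {
        chrom: "".join(
            np.array(list(BASES))[rng.choice(4, size=size, p=probs)]
        )
        for chrom, size in sizes.items()
    }
    genes: list[GeneModel] = []
    if config.n_genes:
        per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
        for ci, (chrom, idxs) in enumerate(zip(sizes, per_chrom)):
            if len(idxs) == 0:
                continue
            slot = config.chrom_length // len(idxs)
            for j, gi in enumerate(idxs):
                span = int(rng.integers(1500, 3001))
                if span + 200 > slot:
                    raise ValueError("genes do not fit: increase chrom_length")
                start = j * slot + int(rng.integers(100, slot - span - 100))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    _make_gene(f"gene{gi:04d}", chrom, start, span, strand, rng)
                )
    return genome, genes, sizes


def _make_gene(gene_id, chrom, start, span, strand, rng) -> GeneModel:
    utr5_len, utr3_len = int(rng.integers(80, 180)), int(rng.integers(80, 180))
    n_exons = int(rng.integers(2, 5))
    end = start + span
    cuts = np.sort(rng.choice(np.arange(start + utr5_len + 50, end - utr3_len - 50),
                              size=2 * (n_exons - 1), replace=False))
    bounds = [start] + list(map(int, cuts)) + [end]
    exons = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
    tx = Transcript(f"{gene_id}.t1", chrom, strand, exons=exons)
    if strand == "+":
        tx.utr5 = [(start, start + utr5_len)]
        tx.utr3 = [(end - utr3_len, end)]
    else:
        tx.utr5 = [(end - utr5_len, end)]
        tx.utr3 = [(start, start + utr3_len)]
    first_exon_end = exons[0][1]
    last_exon_start = exons[-1][0]
    cds_start = min(start + utr5_len, first_exon_end - 1)
    cds_end = max(end - utr3_len, last_exon_start + 1)
    tx.cds = [
        (max(s, cds_start), min(e, cds_end))
        for s, e in exons
        if min(e, cds_end) > max(s, cds_start)
    ]
    tx.finalize()
    return GeneModel(gene_id, chrom, [tx])


def place_peaks(config: SimulationConfig, sizes: dict[str, int]) -> Accessome:
    """Non-overlapping peaks spread uniformly along each chromosome."""
    rng = np.random.default_rng(config.seed + 1)
    per_chrom = np.array_split(np.arange(config.n_peaks), len(sizes))
    intervals = []
    lo, hi = config.peak_length_range
    for chrom, idxs in zip(sizes, per_chrom):
        n = len(idxs)
        if n == 0:
            continue
        slot = sizes[chrom] // n
        if slot <= hi + 2:
            raise ValueError("peaks do not fit: decrease n_peaks or peak length")
        for j in range(n):
            length = int(rng.integers(lo, hi + 1))
            start = j * slot + int(rng.integers(0, slot - length))
            intervals.append((chrom, start, start + length))
    return merge_to_accessome([intervals], sizes)


# ---------------------------------------------------------------------------
# planted effects and counts


def _assign_peak_sets(
    accessome: Accessome, set_sizes: dict[str, int], rng
) -> dict[str, list[str]]:
    ids = list(accessome.peak_ids)
    total = sum(set_sizes.values())
    if total > len(ids):
        raise ValueError(f"planted sets ({total}) exceed peak count ({len(ids)})")
    chosen = rng.choice(len(ids), size=total, replace=False)
    out: dict[str, list[str]] = {}
    offset = 0
    for name, size in set_sizes.items():
        out[name] = sorted(ids[i] for i in chosen[offset : offset + size])
        offset += size
    return out


def _effect_matrix(
    accessome: Accessome, peak_sets: dict[str, list[str]], cells: list[tuple],
    lfc: float,
) -> pd.DataFrame:
    """Per-peak log2 effects per design cell, encoding the planted biology."""
    ids = accessome.peak_ids
    cols = pd.MultiIndex.from_tuples(
        [(c[0], c[1], c[2]) for c in cells], names=["lineage", "condition", "timepoint"]
    )
    E = pd.DataFrame(0.0, index=ids, columns=cols)

    def setcell(names, lineage, condition, timepoint, value):
        key = (lineage, condition, timepoint)
        if key in E.columns:
            E.loc[names, key] += value

    sets = {k: v for k, v in peak_sets.items()}
    # FGF-MAPK opens these at 10 hpf: closed at 6 hpf and under receptor block;
    # they stay open at 18 hpf (primed behaviour).
    op10 = sets.get("opened_by_fgf_mapk_10hpf", [])
    setcell(op10, "B7.5", "control", 6, -lfc)
    setcell(op10, "B7.5", "fgfr_dn", 10, -lfc)
    setcell(op10, "B7.5", "fgfr_dn", 18, -lfc)
    # naive-mesoderm peaks closing between 6 and 10 hpf
    setcell(sets.get("closing_6_to_10", []), "B7.5", "control", 6, +lfc)
    # closed by ectopic MAPK activation at 10 hpf
    setcell(sets.get("closed_by_fgf_mapk_10hpf", []), "B7.5", "mek_act", 10, -lfc)
    # 18 hpf perturbation-responsive elements
    setcell(sets.get("opened_by_fgf_mapk_18hpf", []), "B7.5", "fgfr_dn", 18, -lfc)
    setcell(sets.get("closed_by_fgf_mapk_18hpf", []), "B7.5", "mras_ca", 18, -lfc)
    # de novo elements: closed before 18 hpf, opening in fate-restricted cells
    for name, cond in (("denovo_cardiac", "mras_ca"), ("denovo_asm", "fgfr_dn")):
        members = sets.get(name, [])
        for lineage, condition, timepoint in E.columns:
            if timepoint < 18:
                setcell(members, lineage, condition, timepoint, -lfc)
        setcell(members, "B7.5", cond, 18, -lfc)
    # lineage-specific elements absent from mesenchyme
    b75 = sets.get("b75_specific", [])
    for lineage, condition, timepoint in E.columns:
        if lineage == "mesenchyme":
            setcell(b75, lineage, condition, timepoint, -lfc)
    return E


def simulate_counts(
    config: SimulationConfig, accessome: Accessome
) -> tuple[pd.DataFrame, pd.DataFrame, TruthBundle]:
    """NB counts with planted effects; returns (counts, meta, truth).

    counts ~ NB(mean = base * libfactor * 2^effect, dispersion); effects are
    applied only in the affected design cells; truth records the planted peak
    sets. Shallow libraries (factor 0.05) emulate failed replicates for the
    library filter.
    """
    rng = np.random.default_rng(config.seed + 2)
    peak_sets = _assign_peak_sets(accessome, config.set_sizes, rng)
    E = _effect_matrix(accessome, peak_sets, config.design, config.effect_log2fc)

    lo_b, hi_b = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo_b), np.log(hi_b), size=len(accessome)))

    samples, cells = [], []
    for lineage, condition, timepoint, n_rep in config.design:
        for rep in range(1, n_rep + 1):
            samples.append(
                {
                    "sample": f"{lineage}_{condition}_{timepoint}hpf_rep{rep}",
                    "lineage": lineage,
                    "condition": condition,
                    "timepoint": timepoint,
                    "replicate": rep,
                }
            )
            cells.append((lineage, condition, timepoint))
    meta = pd.DataFrame(samples).set_index("sample")

    lo_f, hi_f = config.library_factor_range
    factors = np.exp(rng.uniform(np.log(lo_f), np.log(hi_f), size=len(meta)))
    for i in range(min(config.n_shallow_libraries, len(meta))):
        factors[len(meta) - 1 - i] = 0.05  # shallow replicate, dropped by the filter

    alpha = config.dispersion
    counts = np.empty((len(accessome), len(meta)), dtype=np.int64)
    for j, cell in enumerate(cells):
        mu = base * np.power(2.0, E[cell].to_numpy()) * factors[j]
        r = 1.0 / alpha
        p = r / (r + mu)
        counts[:, j] = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=accessome.peak_ids, columns=meta.index)
    truth = TruthBundle(peak_sets, {}, pd.DataFrame(
        columns=["motif_id", "peak_id", "position", "strand"]
    ))
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# motif planting


def plant_motifs(
    sequences: dict[str, str],
    pwm: PWM,
    target_peaks,
    insertion_rate: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert a PWM-sampled site into each selected target peak sequence.

    Each selected peak receives one site sampled base-by-base from the PWM at
    a random offset and strand (reverse-complemented when minus). Peaks
    shorter than the motif are skipped with a warning. Returns the mutated
    sequence dict and a registry of (motif_id, peak_id, position, strand).
    """
    import warnings as _warnings

    rng = np.random.default_rng(seed)
    L = len(pwm)
    comp = str.maketrans("ACGT", "TGCA")
    out = dict(sequences)
    rows = []
    for pid in target_peaks:
        if rng.random() > insertion_rate:
            continue
        seq = out[pid]
        if len(seq) < L:
            _warnings.warn(f"peak {pid} shorter than motif {pwm.motif_id}; skipped")
            continue
        site = "".join(
            BASES[rng.choice(4, p=pwm.matrix[i])] for i in range(L)
        )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = site if strand == "+" else site.translate(comp)[::-1]
        pos = int(rng.integers(0, len(seq) - L + 1))
        out[pid] = seq[:pos] + inserted + seq[pos + L :]
        rows.append((pwm.motif_id, pid, pos, strand))
    registry = pd.DataFrame(rows, columns=["motif_id", "peak_id", "position", "strand"])
    return out, registry


# ---------------------------------------------------------------------------
# DE tables


def _de_table(genes, planted: dict[str, float], rng, sig: str = "fdr") -> pd.DataFrame:
    """A DE table with planted log2FCs; other genes are null."""
    lfc = rng.normal(0.0, 0.25, size=len(genes))
    p = rng.uniform(0.0, 1.0, size=len(genes))
    df = pd.DataFrame({"log2fc": lfc, "p_value": p}, index=pd.Index(genes, name="gene_id"))
    for gene, effect in planted.items():
        if gene in df.index:
            df.loc[gene, "log2fc"] = effect + rng.normal(0.0, 0.15)
            df.loc[gene, "p_value"] = rng.uniform(1e-8, 1e-4)
    from .stats import bh_fdr

    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df


def simulate_de_tables(
    config: SimulationConfig,
    gene_ids: list[str],
    gene_sets: dict[str, list[str]],
) -> dict[str, pd.DataFrame]:
    """Differential-expression tables consistent with the planted gene sets."""
    rng = np.random.default_rng(config.seed + 3)
    lfc = config.effect_log2fc

    def planted(*specs):
        out: dict[str, float] = {}
        for set_name, effect in specs:
            for g in gene_sets.get(set_name, []):
                out[g] = effect
        return out

    return {
        "foxf_crispr_vs_control": _de_table(
            gene_ids, planted(("foxf_targets", -lfc)), rng
        ),
        "mras_ca_vs_control_18": _de_table(
            gene_ids,
            planted(("mapk_inhibited_18", -lfc), ("denovo_asm", lfc),
                    ("denovo_cardiac", -lfc)),
            rng,
        ),
        "fgfr_dn_vs_control_18": _de_table(
            gene_ids,
            planted(("mapk_activated_18", -lfc), ("denovo_asm", -lfc),
                    ("denovo_cardiac", lfc)),
            rng,
        ),
        "mras_ca_vs_fgfr_dn_18": _de_table(
            gene_ids,
            planted(("mapk_inhibited_18", -lfc), ("mapk_activated_18", lfc)),
            rng,
        ),
        "fgfr_dn_vs_control_10": _de_table(
            gene_ids,
            planted(("mapk_activated_10", -lfc), ("mapk_inhibited_10", lfc)),
            rng,
        ),
    }


def _assign_gene_sets(
    accessome: Accessome, genes: list[GeneModel], peak_sets: dict[str, list[str]], rng
) -> dict[str, list[str]]:
    """Gene-set truth derived from planted peak sets via 10 kb proximity.

    A gene joins the program of the first planted peak class found near it
    (priority order below), keeping the truth sets disjoint.
    """
    from .annotation import associate_peaks_to_genes

    pg = associate_peaks_to_genes(accessome, genes, window=10_000)
    g2p = pg.associations.groupby("gene_id")["peak_id"].apply(set)
    priority = [
        ("denovo_cardiac", "denovo_cardiac"),
        ("denovo_asm", "denovo_asm"),
        ("opened_by_fgf_mapk_10hpf", "mapk_activated_10"),
        ("closing_6_to_10", "mapk_inhibited_10"),
        ("opened_by_fgf_mapk_18hpf", "mapk_activated_18"),
        ("closed_by_fgf_mapk_18hpf", "mapk_inhibited_18"),
    ]
    assigned: dict[str, list[str]] = {name: [] for _, name in priority}
    taken: set[str] = set()
    for peak_class, set_name in priority:
        members = set(peak_sets.get(peak_class, []))
        for gene_id, peaks in g2p.items():
            if gene_id not in taken and peaks & members:
                assigned[set_name].append(gene_id)
                taken.add(gene_id)
    # Foxf targets: a planted subset of the 10 hpf MAPK-activated program
    activated = assigned["mapk_activated_10"]
    n_half = max(len(activated) // 2, 1) if activated else 0
    if n_half:
        pick = rng.choice(len(activated), size=n_half, replace=False)
        assigned["foxf_targets"] = sorted(activated[i] for i in pick)
    else:
        assigned["foxf_targets"] = []
    return {k: sorted(v) for k, v in assigned.items()}


# ---------------------------------------------------------------------------
# full bundle


def make_fixture_bundle(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate and write a complete fixture directory.

    Writes genome.fa, genes.gff3, chrom.sizes, peaks.bed, counts.tsv,
    samples.tsv, de_tables/*.tsv, gene_sets.tsv, motifs.meme and truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, sizes = simulate_genome_and_genes(config)
    accessome = place_peaks(config, sizes)
    counts, meta, truth = simulate_counts(config, accessome)

    rng = np.random.default_rng(config.seed + 4)
    gene_sets = _assign_gene_sets(accessome, genes, truth.peak_sets, rng)
    truth.gene_sets = gene_sets
    de_tables = simulate_de_tables(config, [g.gene_id for g in genes], gene_sets)

    # plant motifs into the genome through the peak sequences
    catalog = default_motif_catalog()
    seqs = accessome.sequences(genome)
    registries = []
    for offset, (motif_id, target_class) in enumerate(
        (
            ("FOXF_LIKE", "opened_by_fgf_mapk_10hpf"),
            ("TBX_LIKE", "closing_6_to_10"),
            ("EBF_LIKE", "denovo_asm"),
        )
    ):
        targets = truth.peak_sets.get(target_class, [])
        seqs, registry = plant_motifs(
            seqs, catalog[motif_id], targets, config.motif_insertion_rate,
            seed=config.seed + 5 + offset,
        )
        registries.append(registry)
    truth.motif_registry = (
        pd.concat(registries, ignore_index=True)
        if registries
        else truth.motif_registry
    )
    # write the planted sites back into the genome
    genome_mut = {c: list(s) for c, s in genome.items()}
    for r in accessome.peaks.itertuples():
        genome_mut[r.chrom][int(r.start) : int(r.end)] = list(seqs[r.peak_id])
    genome = {c: "".join(s) for c, s in genome_mut.items()}

    # --- writes
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff3(outdir / "genes.gff3", genes)
    write_chrom_sizes(outdir / "chrom.sizes", sizes)
    write_bed(outdir / "peaks.bed", accessome)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    meta.to_csv(outdir / "samples.tsv", sep="\t")
    de_dir = outdir / "de_tables"
    de_dir.mkdir(exist_ok=True)
    for name, table in de_tables.items():
        table.to_csv(de_dir / f"{name}.tsv", sep="\t")
    with open(outdir / "gene_sets.tsv", "w") as fh:
        for name, members in gene_sets.items():
            for gene in members:
                fh.write(f"{name}\t{gene}\n")
    write_meme(outdir / "motifs.meme", list(catalog.values()))
    truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=list)
    return outdir
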
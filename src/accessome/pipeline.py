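"""End-to-end pipeline orchestration: accessome -> annotation -> DA -> sets ->
GSEA / motifs / deviations, with a YAML config, stage toggles and a JSON
provenance manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import (
    associate_peaks_to_genes,
    build_feature_map,
    classify_peaks,
    feature_enrichment_table,
    peak_gene_summary,
)
from .da import filter_libraries, rpkm_and_correlation, run_design_models
from .deviations import (
    deviation_zscores,
    differential_deviations,
    resize_peaks,
    sample_background_sets,
)
from .gene_models import read_gff3
from .gsea import peaks_for_gene_set, run_gsea
from .intervals import (
    genome_coverage_fraction,
    merge_to_accessome,
    read_bed,
    read_chrom_sizes,
    write_bed,
)
from .motifs import motif_enrichment, read_meme, scan_sequences
from .peaksets import (
    GeneSet,
    define_accessibility_sets,
    define_expression_gene_sets,
    classify_primed_denovo_elements,
    intersection_independence_test,
)

log = logging.getLogger("accessome")

STAGES = ["accessome", "annotate", "da", "sets", "gsea", "motifs", "deviations"]


@dataclass
class PipelineConfig:
    peaks: list[str]
    chrom_sizes: str
    genome_fasta: str
    gff3: str
    counts: str
    samples: str
    de_tables_dir: str
    gene_sets: str
    motifs_meme: str
    outdir: str = "pipeline_out"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    min_peak_length: int = 51
    min_reads: int = 500_000
    lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    motif_p_cutoff: float = 5e-5
    gsea_n_perm: int = 10_000
    gsea_min_size: int = 5
    gsea_weight_exponent: float = 1.0
    deviations_n_iterations: int = 50
    deviations_n_bins: int = 10
    deviations_fdr: float = 0.01
    gsea_rank_contrast: str = "fgfr_dn_vs_control"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold outside (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_de_tables(de_dir: str | Path) -> dict[str, pd.DataFrame]:
    out = {}
    for path in sorted(Path(de_dir).glob("*.tsv")):
        out[path.stem] = pd.read_csv(path, sep="\t", index_col=0)
    return out


def _read_gene_sets(path: str | Path) -> dict[str, GeneSet]:
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "member"])
    return {
        name: GeneSet(name, set(sub["member"]), [f"loaded from {path}"])
        for name, sub in df.groupby("set_name")
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the enabled stages in order; returns the output directory.

    Each stage writes its reports under ``outdir/<stage>/`` (write-once); a
    ``manifest.json`` records the package version, thresholds, seed, input
    checksums and per-stage outputs. Disabling a stage that a later enabled
    stage needs raises a dependency error naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    deps = {
        "annotate": ["accessome"],
        "da": ["accessome"],
        "sets": ["da", "annotate"],
        "gsea": ["da", "annotate", "sets"],
        "motifs": ["accessome", "sets"],
        "deviations": ["accessome", "da", "motifs"],
    }
    for stage in enabled:
        missing = [d for d in deps.get(stage, []) if d not in enabled]
        if missing:
            raise ValueError(
                f"stage {stage!r} requires disabled stage(s) {missing}"
            )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v
            for k, v in asdict(config).items()
            if isinstance(v, (int, float)) and k != "seed"
        },
        "inputs": {},
        "stages": {},
    }
    for key in ("chrom_sizes", "genome_fasta", "gff3", "counts", "samples",
                "gene_sets", "motifs_meme"):
        p = Path(getattr(config, key))
        if p.exists():
            manifest["inputs"][key] = _sha256(p)
    for p in config.peaks:
        manifest["inputs"][f"peaks:{p}"] = _sha256(Path(p))

    state: dict = {}

    def report(stage: str, name: str, obj) -> None:
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        path = stage_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t")
        else:
            path.write_text(json.dumps(obj, indent=1, default=float))
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)
        log.info("wrote %s", path)

    # ---- accessome
    if "accessome" in enabled:
        sizes = read_chrom_sizes(config.chrom_sizes)
        peak_sets = [read_bed(p) for p in config.peaks]
        acc = merge_to_accessome(peak_sets, sizes, config.min_peak_length)
        state["accessome"] = acc
        stage_dir = outdir / "accessome"
        stage_dir.mkdir(exist_ok=True)
        write_bed(stage_dir / "accessome.bed", acc)
        manifest["stages"].setdefault("accessome", {})["accessome.bed"] = _sha256(
            stage_dir / "accessome.bed"
        )
        report(
            "accessome",
            "stats.json",
            {
                "n_peaks": len(acc),
                "genome_coverage_fraction": genome_coverage_fraction(acc),
            },
        )

    # ---- annotate
    if "annotate" in enabled:
        acc = state["accessome"]
        genes = read_gff3(config.gff3)
        fmap = build_feature_map(genes, acc.genome_sizes)
        classification = classify_peaks(acc, fmap)
        report("annotate", "classification.tsv", classification)
        report("annotate", "feature_enrichment.tsv",
               feature_enrichment_table(classification, fmap).set_index("feature"))
        pg = associate_peaks_to_genes(acc, genes)
        state["peak_gene_map"] = pg
        report("annotate", "peak_gene_map.tsv", pg.associations.set_index("peak_id"))
        report("annotate", "peak_gene_summary.json", peak_gene_summary(pg))

    # ---- da
    if "da" in enabled:
        acc = state["accessome"]
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        meta = pd.read_csv(config.samples, sep="\t", index_col=0)
        counts, meta = filter_libraries(counts, meta, config.min_reads)
        state["counts"], state["meta"] = counts, meta
        da_tables: dict[str, pd.DataFrame] = {}
        for model in ("m10hpf", "m15_20hpf", "time", "lineage"):
            try:
                results = run_design_models(counts, meta, model)
            except ValueError as err:
                log.warning("model %s skipped: %s", model, err)
                continue
            for contrast, table in results.items():
                da_tables[contrast] = table
                report("da", f"{contrast}.tsv", table)
        state["da_tables"] = da_tables
        changing = set()
        for table in da_tables.values():
            changing |= set(table.index[table["fdr"] < config.fdr_threshold])
        if len(changing) >= 10:
            corr = rpkm_and_correlation(counts, acc, sorted(changing))
            report("da", "qc_spearman_correlation.tsv", corr)

    # ---- sets
    if "sets" in enabled:
        da_tables = state["da_tables"]
        peak_sets = define_accessibility_sets(
            da_tables, config.lfc_threshold, config.fdr_threshold
        )
        state["peak_sets"] = peak_sets
        rows = [(name, pid) for name, ps in peak_sets.items() for pid in sorted(ps.members)]
        report("sets", "accessibility_sets.tsv",
               pd.DataFrame(rows, columns=["set_name", "peak_id"]).set_index("set_name"))
        de_tables = _read_de_tables(config.de_tables_dir)
        expr_sets = define_expression_gene_sets(de_tables)
        marker_sets = _read_gene_sets(config.gene_sets)
        gene_sets = {**marker_sets, **expr_sets}
        state["gene_sets"] = gene_sets
        rows = [(name, g) for name, gs in gene_sets.items() for g in sorted(gs.members)]
        report("sets", "gene_sets.tsv",
               pd.DataFrame(rows, columns=["set_name", "gene_id"]).set_index("set_name"))
        if {"denovo_cardiac", "denovo_asm"} <= set(gene_sets):
            labeled = classify_primed_denovo_elements(
                state["peak_gene_map"], da_tables, gene_sets, peak_sets
            )
            rows = [(n, p) for n, ps in labeled.items() for p in sorted(ps.members)]
            report("sets", "primed_denovo_elements.tsv",
                   pd.DataFrame(rows, columns=["set_name", "peak_id"]).set_index("set_name"))
        inter = intersection_independence_test(
            list(peak_sets.values()), state["accessome"], min_sets=2
        )
        report("sets", "intersection_independence.tsv", inter.set_index("intersection"))

    # ---- gsea
    if "gsea" in enabled:
        da_tables = state["da_tables"]
        contrast = config.gsea_rank_contrast
        if contrast not in da_tables:
            raise ValueError(f"GSEA rank contrast {contrast!r} has no DA table")
        ranked = da_tables[contrast]["log2fc"].dropna()
        mapped = {
            name: peaks_for_gene_set(gs, state["peak_gene_map"])
            for name, gs in state["gene_sets"].items()
        }
        mapped = {k: v for k, v in mapped.items() if len(v)}
        results = run_gsea(
            ranked,
            mapped,
            n_perm=config.gsea_n_perm,
            min_size=config.gsea_min_size,
            weight_exponent=config.gsea_weight_exponent,
            seed=config.seed,
        )
        report("gsea", "gsea.tsv", results.set_index("set"))

    # ---- motifs
    if "motifs" in enabled:
        from pyfaidx import Fasta

        acc = state["accessome"]
        fasta = Fasta(config.genome_fasta)
        seqs = acc.sequences(fasta)
        pwms = read_meme(config.motifs_meme)
        hits = scan_sequences(seqs, pwms, p_cutoff=config.motif_p_cutoff)
        state["hits"] = hits
        report("motifs", "hits.tsv", hits.hits.set_index("peak_id"))
        report("motifs", "occupancy.tsv", hits.occupancy)
        tables = []
        for name, ps in state["peak_sets"].items():
            if not len(ps):
                continue
            table = motif_enrichment(hits, ps, acc)
            table.insert(0, "set_name", name)
            tables.append(table)
        if tables:
            report("motifs", "motif_enrichment.tsv",
                   pd.concat(tables, ignore_index=True).set_index("set_name"))

    # ---- deviations
    if "deviations" in enabled:
        acc = state["accessome"]
        counts, meta = state["counts"], state["meta"]
        da_tables = state["da_tables"]
        pre = set()
        for name in ("fgfr_dn_vs_control", "mek_act_vs_control", "mek_act_vs_fgfr_dn"):
            if name in da_tables:
                t = da_tables[name]
                pre |= set(t.index[t["fdr"] < config.fdr_threshold])
        sel_samples = meta.index[
            (meta["lineage"] == "B7.5") & (meta["timepoint"].astype(int).isin([6, 10]))
        ]
        peak_ids = sorted(pre & set(acc.peak_ids)) or list(acc.peak_ids)
        sub_counts = counts.loc[peak_ids, sel_samples]
        resized = resize_peaks(acc)
        from pyfaidx import Fasta

        fasta = Fasta(config.genome_fasta)
        resized = resized.set_index("peak_id")
        seqs = {
            pid: str(fasta[resized.loc[pid, "chrom"]][
                int(resized.loc[pid, "start"]) : int(resized.loc[pid, "end"])
            ]).upper()
            for pid in peak_ids
        }
        occ = state["hits"].occupancy.loc[peak_ids]
        backgrounds = sample_background_sets(
            peak_ids, sub_counts, seqs,
            n_iterations=config.deviations_n_iterations,
            n_bins=config.deviations_n_bins,
            seed=config.seed,
        )
        dev = deviation_zscores(sub_counts, occ, backgrounds)
        report("deviations", "deviation_zscores.tsv", dev.zscore)
        groups = (
            meta.loc[sel_samples, "condition"].astype(str)
            + "_"
            + meta.loc[sel_samples, "timepoint"].astype(str)
        )
        diff = differential_deviations(dev, groups, config.deviations_fdr)
        report("deviations", "differential_deviations.tsv", diff)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
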
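"""Gene models and a GFF3 reader restricted to gene/transcript structure.

Only ``gene``, ``mRNA``, ``exon``, ``CDS``, ``five_prime_UTR`` and
``three_prime_UTR`` features are consumed. GFF3 coordinates (1-based,
inclusive) are converted to 0-based half-open on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Transcript", "GeneModel", "read_gff3", "write_gff3"]


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def finalize(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons.sort()
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] < a[1]:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )
        self.cds.sort()
        self.utr5.sort()
        self.utr3.sort()

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def tss_position(self) -> int:
        """0-based position of the transcription start.

        Anchored at the start of the 5'UTR when one is annotated (in *Ciona*,
        SL trans-splicing makes the mRNA 5' end differ from the TSS, so the
        annotated 5'UTR is the best TSS proxy); transcripts without a 5'UTR
        fall back to the transcript span boundary.
        """
        if self.utr5:
            return self.utr5[0][0] if self.strand != "-" else self.utr5[-1][1] - 1
        return self.start if self.strand != "-" else self.end - 1

    def tes_boundary(self) -> int:
        """Coordinate of the transcription end (3'UTR end boundary)."""
        if self.utr3:
            return self.utr3[-1][1] if self.strand != "-" else self.utr3[0][0]
        return self.end if self.strand != "-" else self.start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


_FEATURES = {"gene", "mRNA", "exon", "CDS", "five_prime_UTR", "three_prime_UTR"}


def _attrs(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 (restricted feature vocabulary)."""
    genes: dict[str, GeneModel] = {}
    transcripts: dict[str, Transcript] = {}
    tx_gene: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in _FEATURES:
                continue
            chrom, ftype, start, end, strand = f[0], f[2], int(f[3]), int(f[4]), f[6]
            iv = (start - 1, end)  # GFF3 1-based inclusive -> half-open
            attrs = _attrs(f[8])
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid:
                    genes.setdefault(gid, GeneModel(gid, chrom))
            elif ftype == "mRNA":
                tid = attrs.get("ID")
                parent = attrs.get("Parent", "")
                if tid:
                    transcripts[tid] = Transcript(tid, chrom, strand)
                    tx_gene[tid] = parent or tid
            else:
                for parent in attrs.get("Parent", "").split(","):
                    tx = transcripts.get(parent)
                    if tx is None:
                        continue
                    if ftype == "exon":
                        tx.exons.append(iv)
                    elif ftype == "CDS":
                        tx.cds.append(iv)
                    elif ftype == "five_prime_UTR":
                        tx.utr5.append(iv)
                    elif ftype == "three_prime_UTR":
                        tx.utr3.append(iv)
    for tid, tx in transcripts.items():
        tx.finalize()
        gid = tx_gene[tid]
        gene = genes.setdefault(gid, GeneModel(gid, tx.chrom))
        gene.transcripts.append(tx)
    return [g for g in genes.values() if g.transcripts]


def write_gff3(path: str | Path, genes: list[GeneModel]) -> None:
    def row(chrom, ftype, s, e, strand, attrs):
        return f"{chrom}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}\n"

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            strand = g.transcripts[0].strand
            fh.write(row(g.chrom, "gene", s, e, strand, f"ID={g.gene_id}"))
            for tx in g.transcripts:
                fh.write(
                    row(
                        tx.chrom, "mRNA", tx.start, tx.end, tx.strand,
                        f"ID={tx.transcript_id};Parent={g.gene_id}",
                    )
                )
                for ftype, ivs in (
                    ("exon", tx.exons),
                    ("CDS", tx.cds),
                    ("five_prime_UTR", tx.utr5),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for a, b in ivs:
                        fh.write(
                            row(
                                tx.chrom, ftype, a, b, tx.strand,
                                f"Parent={tx.transcript_id}",
                            )
                        )
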
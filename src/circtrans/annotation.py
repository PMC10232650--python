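"""Exon-resolved gene models and annotation I/O.

Coordinates are 0-based half-open everywhere in memory. GTF is converted on
read (1-based closed -> half-open) and on write (half-open -> 1-based closed).
Exon ordinals follow transcription order: for a minus-strand gene, exon 0 is
the genomically rightmost interval and extracted sequences are
reverse-complemented, so everything downstream of extraction is
strand-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from Bio.Seq import reverse_complement


@dataclass(frozen=True)
class ExonInterval:
    """A single exon on the genome.

    ``index`` is the ordinal of the exon within its transcript counted
    5'->3' in transcription order (0-based).
    """

    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    index: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single-transcript gene: an ordered run of exons on one contig."""

    gene_id: str
    contig: str
    strand: str
    exons: list[ExonInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, ex in enumerate(self.exons):
            if ex.index != i:
                raise ValueError(
                    f"{self.gene_id}: exon ordinals must be consecutive from 0"
                )
            if ex.contig != self.contig or ex.strand != self.strand:
                raise ValueError(f"{self.gene_id}: exon contig/strand mismatch")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all exons, half-open."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def exon_sequence(self, genome: dict[str, str], index: int) -> str:
        """Sequence of one exon, reverse-complemented on the minus strand."""
        ex = self.exons[index]
        seq = genome[self.contig][ex.start : ex.end]
        return reverse_complement(seq) if self.strand == "-" else seq

    def transcript_sequence(self, genome: dict[str, str]) -> str:
        """Spliced transcript sequence in transcription order."""
        return "".join(self.exon_sequence(genome, i) for i in range(self.n_exons))

    @property
    def transcript_length(self) -> int:
        return sum(e.length for e in self.exons)


# ---------------------------------------------------------------------------
# GTF round-trip. Only `exon` features with gene_id/transcript_id attributes
# are produced by the simulator and consumed by the index.
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models as GTF exon features (1-based closed intervals)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in genes:
            for ex in gene.exons:
                attrs = (
                    f'gene_id "{gene.gene_id}"; '
                    f'transcript_id "{gene.gene_id}.t1"; '
                    f'exon_number "{ex.index + 1}";'
                )
                fh.write(
                    "\t".join(
                        [
                            gene.contig,
                            "circtrans_sim",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            gene.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_gtf(path: str) -> list[GeneModel]:
    """Read gene models from a GTF file.

    Exon ordinals are assigned in transcription order (ascending genomic
    start on '+', descending on '-'); any exon_number attribute present is
    ignored in favour of coordinate order.
    """
    raw: dict[str, list[tuple[str, int, int, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(parts[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"exon feature without gene_id: {line!r}")
            raw.setdefault(gene_id, []).append(
                (parts[0], int(parts[3]) - 1, int(parts[4]), parts[6])
            )
    genes = []
    for gene_id in sorted(raw):
        rows = raw[gene_id]
        strand = rows[0][3]
        rows.sort(key=lambda r: r[1], reverse=(strand == "-"))
        exons = [
            ExonInterval(contig=c, start=s, end=e, strand=st, index=i)
            for i, (c, s, e, st) in enumerate(rows)
        ]
        genes.append(
            GeneModel(gene_id=gene_id, contig=exons[0].contig, strand=strand, exons=exons)
        )
    return genes


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    """Write a name->sequence mapping as FASTA with fixed line wrapping."""
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
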
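"""Backsplice candidate enumeration and junction pseudo-sequence library.

A circRNA formed by backsplicing exons [i..j] of a gene is only directly
observable through reads that span its head-to-tail junction: the point where
the 3' end of exon j is covalently joined back to the 5' start of exon i.
This module enumerates candidate circles as contiguous exon runs, builds the
junction pseudo-sequence every read is matched against (the last L nt of the
circularized sequence followed by its first L nt), and annotates candidates
against a known-circle database by exact genomic span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .annotation import GeneModel, write_fasta

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 50  # nt on each side of the junction in the pseudo-sequence


@dataclass(frozen=True)
class CircleCandidate:
    """A candidate circle over contiguous exons [first_exon..last_exon]."""

    circ_id: str
    gene_id: str
    first_exon: int  # inclusive, transcription-order ordinal
    last_exon: int  # inclusive
    circle_len: int  # nt, sum of member exon lengths
    contig: str
    start: int  # genomic span, 0-based half-open
    end: int
    strand: str
    known_db: bool | None = None  # None until annotated


@dataclass(frozen=True)
class JunctionLibraryEntry:
    """The backsplice pseudo-sequence for one candidate circle.

    ``pseudo_seq`` = last ``left_flank_len`` nt of the circle sequence
    followed by its first ``right_flank_len`` nt; the backsplice point sits
    exactly between the two flanks, at offset ``left_flank_len``.
    """

    circ_id: str
    pseudo_seq: str
    left_flank_len: int
    right_flank_len: int
    ambiguous: bool = False

    @property
    def junction_offset(self) -> int:
        return self.left_flank_len


def enumerate_candidate_circles(
    gene: GeneModel, max_span_exons: int | None = None
) -> list[CircleCandidate]:
    """All contiguous exon runs [i..j] of ``gene`` as circle candidates.

    Candidates are emitted in deterministic order (by first exon, then last).
    ``max_span_exons`` caps the run length j-i+1; ``None`` means no cap.
    """
    if gene.n_exons < 1:
        raise ValueError(f"{gene.gene_id}: gene has no exons")
    cap = gene.n_exons if max_span_exons is None else max_span_exons
    out = []
    for i in range(gene.n_exons):
        for j in range(i, min(i + cap, gene.n_exons)):
            exons = gene.exons[i : j + 1]
            out.append(
                CircleCandidate(
                    circ_id=f"{gene.gene_id}:c{i}-{j}",
                    gene_id=gene.gene_id,
                    first_exon=i,
                    last_exon=j,
                    circle_len=sum(e.length for e in exons),
                    contig=gene.contig,
                    start=min(e.start for e in exons),
                    end=max(e.end for e in exons),
                    strand=gene.strand,
                )
            )
    return out


def circle_rna_sequence(
    gene: GeneModel, first_exon: int, last_exon: int, genome: dict[str, str]
) -> str:
    """Circularized RNA sequence: member exons spliced in transcription order.

    Position 0 is the first base of the circle's first exon; the backsplice
    point lies between the last and the first base.
    """
    return "".join(
        gene.exon_sequence(genome, k) for k in range(first_exon, last_exon + 1)
    )


def build_junction_library(
    candidates: Sequence[CircleCandidate],
    genes: Iterable[GeneModel],
    genome: dict[str, str],
    flank: int = DEFAULT_FLANK,
) -> list[JunctionLibraryEntry]:
    """One junction pseudo-sequence per candidate.

    Flanks are taken from the circularized RNA sequence (so they cross
    internal splice boundaries, as a real junction read would) and truncated
    to the circle length when the circle is shorter than ``flank``. Entries
    whose pseudo-sequences collide are flagged ambiguous.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1 nt")
    gene_by_id = {g.gene_id: g for g in genes}
    entries = []
    for cand in candidates:
        gene = gene_by_id[cand.gene_id]
        seq = circle_rna_sequence(gene, cand.first_exon, cand.last_exon, genome)
        f = min(flank, len(seq))
        entries.append(
            JunctionLibraryEntry(
                circ_id=cand.circ_id,
                pseudo_seq=seq[-f:] + seq[:f],
                left_flank_len=f,
                right_flank_len=f,
            )
        )
    seen: dict[str, list[int]] = {}
    for idx, e in enumerate(entries):
        seen.setdefault(e.pseudo_seq, []).append(idx)
    for idxs in seen.values():
        if len(idxs) > 1:
            for idx in idxs:
                entries[idx] = replace(entries[idx], ambiguous=True)
    return entries


def annotate_against_db(
    candidates: Sequence[CircleCandidate],
    db_rows: Iterable[Sequence[str]],
) -> tuple[list[CircleCandidate], dict[str, int]]:
    """Set ``known_db`` by exact (contig, start, end, strand) span match.

    ``db_rows`` are (circ_id, chrom, start, end, strand) records with 0-based
    half-open coordinates, e.g. from :func:`read_known_db`. Malformed rows
    are skipped with a logged warning and counted in the summary.
    """
    known: set[tuple[str, int, int, str]] = set()
    n_bad = 0
    for row in db_rows:
        try:
            _, chrom, start, end, strand = row[:5]
            start_i, end_i = int(start), int(end)
            if strand not in "+-" or start_i >= end_i:
                raise ValueError
            known.add((chrom, start_i, end_i, strand))
        except (ValueError, IndexError):
            n_bad += 1
            logger.warning("skipping malformed known-circle DB row: %r", row)
    annotated = [
        replace(c, known_db=(c.contig, c.start, c.end, c.strand) in known)
        for c in candidates
    ]
    n_known = sum(c.known_db for c in annotated)
    summary = {
        "n_candidates": len(annotated),
        "n_annotated": n_known,
        "n_novel": len(annotated) - n_known,
        "n_malformed_db_rows": n_bad,
    }
    return annotated, summary


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------


def read_known_db(path: str) -> list[list[str]]:
    """Known-circle DB TSV: circ_id, chrom, start, end, strand (half-open)."""
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("circ_id"):
            raise ValueError(f"{path}: expected a circ_id header line")
        for line in fh:
            if line.strip():
                rows.append(line.rstrip("\n").split("\t"))
    return rows


def write_known_db(rows: Iterable[Sequence], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tchrom\tstart\tend\tstrand\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_junction_fasta(entries: Iterable[JunctionLibraryEntry], path: str) -> None:
    write_fasta({e.circ_id: e.pseudo_seq for e in entries}, path)


def write_library_tsv(
    candidates: Sequence[CircleCandidate],
    entries: Sequence[JunctionLibraryEntry],
    path: str,
) -> None:
    by_id = {e.circ_id: e for e in entries}
    with open(path, "w") as fh:
        fh.write(
            "circ_id\tgene_id\tfirst_exon\tlast_exon\tcircle_len\t"
            "contig\tstart\tend\tstrand\t"
            "left_flank_len\tright_flank_len\tambiguous\tknown_db\n"
        )
        for c in candidates:
            e = by_id[c.circ_id]
            fh.write(
                f"{c.circ_id}\t{c.gene_id}\t{c.first_exon}\t{c.last_exon}\t"
                f"{c.circle_len}\t{c.contig}\t{c.start}\t{c.end}\t{c.strand}\t"
                f"{e.left_flank_len}\t{e.right_flank_len}\t"
                f"{int(e.ambiguous)}\t"
                f"{'NA' if c.known_db is None else int(c.known_db)}\n"
            )


def load_library(
    fasta_path: str, tsv_path: str
) -> tuple[list[CircleCandidate], list[JunctionLibraryEntry]]:
    """Round-trip of :func:`write_junction_fasta` + :func:`write_library_tsv`."""
    from .annotation import read_fasta

    seqs = read_fasta(fasta_path)
    candidates, entries = [], []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            candidates.append(
                CircleCandidate(
                    circ_id=row["circ_id"],
                    gene_id=row["gene_id"],
                    first_exon=int(row["first_exon"]),
                    last_exon=int(row["last_exon"]),
                    circle_len=int(row["circle_len"]),
                    contig=row["contig"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    known_db=None if row["known_db"] == "NA" else bool(int(row["known_db"])),
                )
            )
            entries.append(
                JunctionLibraryEntry(
                    circ_id=row["circ_id"],
                    pseudo_seq=seqs[row["circ_id"]],
                    left_flank_len=int(row["left_flank_len"]),
                    right_flank_len=int(row["right_flank_len"]),
                    ambiguous=bool(int(row["ambiguous"])),
                )
            )
    return candidates, entries


def write_catalog_bed(candidates: Iterable[CircleCandidate], path: str) -> None:
    """Circle catalog as BED6; score column carries the circle length."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end}\t{c.circ_id}\t"
                f"{c.circle_len}\t{c.strand}\n"
            )
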
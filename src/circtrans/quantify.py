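"""Match reads against the backsplice junction library and count per sample.

A read supports a circle only if it aligns across the backsplice point with
at least ``min_overlap`` nt on *each* side of the junction (default 8) and at
most ``max_mismatch`` substitutions (Ribo-seq mode: 0 — footprints with any
mismatch are excluded; RNA-seq mode default: 2). Matching is ungapped
Hamming comparison of the read against every pseudo-sequence at every
junction-straddling offset; a read whose best alignment is tied across
distinct circles is discarded as ambiguous, so counted reads are uniquely
assigned.

Two equivalent matchers are provided: a literal all-offsets scan
(:func:`match_read_brute`) and a pigeonhole seed index (:class:`JunctionIndex`)
that returns identical results whenever reads are long enough to seed
(read_len >= (max_mismatch+1) * k); otherwise the index falls back to the
scan. The pigeonhole argument: split the read into max_mismatch+1 contiguous
segments — any alignment within the mismatch budget leaves at least one
segment error-free, and the k-mer at that segment's start locates it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

DEFAULT_MIN_OVERLAP = 8  # nt on either side of the junction
RNASEQ_MAX_MISMATCH = 2
RIBOSEQ_MAX_MISMATCH = 0
_SEED_K = 16  # seed k-mer length (shrunk automatically for short reads)


@dataclass(frozen=True)
class JunctionAlignment:
    read_id: str
    circ_id: str
    offset: int  # read start within the pseudo-sequence
    mismatches: int
    left_overlap: int  # nt left of the junction point
    right_overlap: int


@dataclass
class CountMatrix:
    """Circle x sample junction-read counts for one modality."""

    modality: str  # 'rnaseq' or 'riboseq'
    counts: pd.DataFrame  # rows circ_id, columns sample ids, integer cells
    library_sizes: dict[str, int]  # total reads per sample
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def to_tsv(self, path: str) -> None:
        self.counts.rename_axis("circ_id").to_csv(path, sep="\t")

    def sidecar(self) -> dict:
        return {
            "modality": self.modality,
            "library_sizes": self.library_sizes,
            "params": self.params,
            "deduplication": "none",  # PCR/UMI deduplication is not performed
        }

    def write(self, tsv_path: str, sidecar_path: str) -> None:
        import json

        self.to_tsv(tsv_path)
        with open(sidecar_path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, tsv_path: str, sidecar_path: str) -> "CountMatrix":
        import json

        counts = pd.read_csv(tsv_path, sep="\t", index_col="circ_id")
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        return cls(
            modality=meta["modality"],
            counts=counts,
            library_sizes={k: int(v) for k, v in meta["library_sizes"].items()},
            params=meta.get("params", {}),
        )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _valid_offsets(read_len: int, entry, min_overlap: int) -> range:
    """Offsets where the read straddles the junction with min_overlap/side."""
    j = entry.left_flank_len
    lo = max(0, j - (read_len - min_overlap))
    hi = min(j - min_overlap, len(entry.pseudo_seq) - read_len)
    return range(lo, hi + 1)


def _pick_best(
    hits: list[tuple[int, int, int]],
    entries: Sequence,
    read_id: str,
    read_len: int,
    max_mismatch: int,
) -> JunctionAlignment | None:
    """Select the unique best hit; ties across distinct circles discard."""
    if not hits:
        return None
    best_mm = min(h[0] for h in hits)
    if best_mm > max_mismatch:
        return None
    best = sorted(h for h in hits if h[0] == best_mm)
    circ_ids = {entries[h[1]].circ_id for h in best}
    if len(circ_ids) > 1:
        return None
    entry = entries[best[0][1]]
    if entry.ambiguous:
        return None  # identical pseudo-sequence exists under another circ_id
    _, eidx, offset = best[0]
    left = entry.left_flank_len - offset
    return JunctionAlignment(
        read_id=read_id,
        circ_id=entry.circ_id,
        offset=offset,
        mismatches=best_mm,
        left_overlap=left,
        right_overlap=read_len - left,
    )


def match_read_brute(
    read_seq: str,
    entries: Sequence,
    max_mismatch: int,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    read_id: str = "read",
) -> JunctionAlignment | None:
    """Literal contract: scan every entry at every junction-straddling offset."""
    if not read_seq:
        raise ValueError("empty read")
    r = len(read_seq)
    hits = []
    for eidx, entry in enumerate(entries):
        for o in _valid_offsets(r, entry, min_overlap):
            mm = _hamming(read_seq, entry.pseudo_seq[o : o + r])
            hits.append((mm, eidx, o))
    return _pick_best(hits, entries, read_id, r, max_mismatch)


class JunctionIndex:
    """Seeded matcher over a junction library, equivalent to the brute scan."""

    def __init__(self, entries: Sequence):
        self.entries = list(entries)
        self._kmer_index: dict[int, dict[str, list[tuple[int, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[int, int]]]:
        idx = self._kmer_index.get(k)
        if idx is None:
            idx = {}
            for eidx, entry in enumerate(self.entries):
                seq = entry.pseudo_seq
                for pos in range(len(seq) - k + 1):
                    idx.setdefault(seq[pos : pos + k], []).append((eidx, pos))
            self._kmer_index[k] = idx
        return idx

    def match(
        self,
        read_seq: str,
        max_mismatch: int,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        read_id: str = "read",
    ) -> JunctionAlignment | None:
        if not read_seq:
            raise ValueError("empty read")
        r = len(read_seq)
        if r < 2 * min_overlap:
            return None
        n_seg = max_mismatch + 1
        k = min(_SEED_K, r // n_seg)
        if k < 6:  # too short to seed reliably; honor the contract directly
            return match_read_brute(
                read_seq, self.entries, max_mismatch, min_overlap, read_id
            )
        idx = self._index_for(k)
        entries = self.entries
        seen: set[tuple[int, int]] = set()
        hits: list[tuple[int, int, int]] = []
        for t in range(n_seg):
            q = t * r // n_seg
            for eidx, pos in idx.get(read_seq[q : q + k], ()):
                o = pos - q
                key = (eidx, o)
                if key in seen:
                    continue
                seen.add(key)
                entry = entries[eidx]
                p = len(entry.pseudo_seq)
                if o < 0 or o + r > p:
                    continue
                left = entry.left_flank_len - o
                if left < min_overlap or r - left < min_overlap:
                    continue
                mm = _hamming(read_seq, entry.pseudo_seq[o : o + r])
                if mm <= max_mismatch:
                    hits.append((mm, eidx, o))
        return _pick_best(hits, entries, read_id, r, max_mismatch)


def match_read(
    read_seq: str,
    entries: Sequence,
    max_mismatch: int,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    read_id: str = "read",
) -> JunctionAlignment | None:
    """One-off match of a single read (see :class:`JunctionIndex` for bulk)."""
    return match_read_brute(read_seq, entries, max_mismatch, min_overlap, read_id)


ASSIGNMENT_COLUMNS = [
    "read_id",
    "sample",
    "circ_id",
    "offset",
    "mismatches",
    "left_overlap",
    "right_overlap",
]


def quantify(
    reads_by_sample: dict[str, Iterable[tuple[str, str]]],
    entries: Sequence,
    modality: str,
    max_mismatch: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count uniquely assigned junction reads per circle and sample.

    ``reads_by_sample`` maps sample id to an iterable of (read_id, sequence).
    Identical sequences are counted per occurrence (no deduplication).
    Returns the count matrix and the per-read assignment table.
    """
    if max_mismatch is None:
        max_mismatch = (
            RIBOSEQ_MAX_MISMATCH if modality == "riboseq" else RNASEQ_MAX_MISMATCH
        )
    index = JunctionIndex(entries)
    circ_ids = [e.circ_id for e in entries]
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=circ_ids, columns=samples, dtype=int)
    lib_sizes: dict[str, int] = {}
    rows: list[list] = []
    for sample in samples:
        n_total = 0
        for read_id, seq in reads_by_sample[sample]:
            n_total += 1
            aln = index.match(seq, max_mismatch, min_overlap, read_id=read_id)
            if aln is not None:
                counts.loc[aln.circ_id, sample] += 1
                rows.append(
                    [
                        aln.read_id,
                        sample,
                        aln.circ_id,
                        aln.offset,
                        aln.mismatches,
                        aln.left_overlap,
                        aln.right_overlap,
                    ]
                )
        lib_sizes[sample] = n_total
    assignments = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    matrix = CountMatrix(
        modality=modality,
        counts=counts,
        library_sizes=lib_sizes,
        params={"max_mismatch": max_mismatch, "min_overlap": min_overlap},
    )
    return matrix, assignments


def iter_fastq(path: str) -> Iterable[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file (gzip allowed)."""
    import gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


def quantify_fastq(
    fastq_by_sample: dict[str, str],
    entries: Sequence,
    modality: str,
    max_mismatch: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[CountMatrix, pd.DataFrame]:
    """As :func:`quantify`, reading each sample's reads from a FASTQ file."""
    reads = {s: iter_fastq(p) for s, p in fastq_by_sample.items()}
    return quantify(reads, entries, modality, max_mismatch, min_overlap)
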
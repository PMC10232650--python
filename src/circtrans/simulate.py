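"""Synthetic paired tumor/normal circRNA-seq + Ribo-seq data with ground truth.

The simulator emulates the study design every downstream stage consumes:
paired tumor/normal samples; circles formed by backsplicing contiguous exon
runs (most under 1000 nt); planted tumor-vs-normal fold changes on a subset
of circles; a subset of "coding" circles that receive ribosome footprints
(26-34 nt) across the backsplice junction; junction-spanning RNA-seq reads;
iid substitution errors; RNase R depletion of linear species; and
nuclear/cytoplasmic partitioning. Every read's true origin is recorded so
parameter recovery can be audited exactly.

Randomness: one root seed. Each stage draws from a child generator seeded
with ``(seed, stage_offset)`` where the offsets are the module constants
``_STAGE_GENOME`` (0), ``_STAGE_CIRCLES`` (1), ``_STAGE_READS`` (2),
``_STAGE_COUNTS`` (3) and ``_STAGE_ASSAY`` (4). Identical (config, seed)
therefore reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ExonInterval, GeneModel
from .quantify import CountMatrix

_STAGE_GENOME = 0
_STAGE_CIRCLES = 1
_STAGE_READS = 2
_STAGE_COUNTS = 3
_STAGE_ASSAY = 4

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

TRUTH_COLUMNS = [
    "read_id",
    "sample",
    "modality",
    "source_type",
    "source_id",
    "start",
    "read_len",
    "spans_junction",
    "left_overlap",
    "right_overlap",
    "n_errors",
]


class ConfigurationError(ValueError):
    """Raised when a SimConfig fails validation."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults mirror the paired 4-vs-4 design with a handful of planted
    circles: 20 genes, 10 circles (90% under 1000 nt), 4 of them with an
    8-fold tumor fold change, 3 of them translated, 50,000 reads per sample
    and modality.
    """

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (4, 12)
    exon_len: tuple[int, int] = (100, 300)  # nt
    intron_len: tuple[int, int] = (50, 200)  # nt
    n_circles: int = 10
    circle_max_exons: int = 6  # planted circles span at most this many exons
    circle_len_max_frac_under_1000: float = 0.9
    n_pairs: int = 4
    n_de: int = 4
    n_coding: int = 3
    base_abundance: tuple[float, float] = (0.0, 0.5)  # lognormal (mean-log, sd-log)
    linear_abundance: tuple[float, float] = (1.0, 0.5)
    planted_fc: float = 8.0
    rna_read_len: int = 75
    ribo_len: tuple[int, int] = (26, 34)
    n_rna_reads: int = 50_000
    n_ribo_reads: int = 50_000
    error_rate: float = 0.001
    rnase_r_survival_circ: float = 0.9
    rnase_r_survival_linear: float = 0.05
    cyto_fraction_circ: float = 0.75
    known_db_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len", "ribo_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigurationError(f"degenerate range {name}={lo}..{hi}")
        for name in (
            "circle_len_max_frac_under_1000",
            "error_rate",
            "rnase_r_survival_circ",
            "rnase_r_survival_linear",
            "cyto_fraction_circ",
            "known_db_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.planted_fc <= 0:
            raise ConfigurationError("planted_fc must be > 0")
        for name in ("n_genes", "n_pairs", "n_circles", "circle_max_exons"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_de > self.n_circles or self.n_coding > self.n_circles:
            raise ConfigurationError("n_de and n_coding must not exceed n_circles")

    @property
    def samples(self) -> list[str]:
        """Tumor samples first, then their paired normals (T1..Tn, N1..Nn)."""
        return [f"T{i + 1}" for i in range(self.n_pairs)] + [
            f"N{i + 1}" for i in range(self.n_pairs)
        ]

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stage])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class CircleTruth:
    circ_id: str
    gene_id: str
    first_exon: int
    last_exon: int
    circle_len: int
    known_db: bool


@dataclass
class SimTruth:
    """Planted ground truth: circles, per-sample abundances, DE/coding sets."""

    circles: list[CircleTruth]
    abundance: pd.DataFrame  # circles x samples, expected relative abundance
    linear_abundance: pd.Series  # per gene, shared across samples
    de_set: set[str]
    coding_set: set[str]

    def __post_init__(self) -> None:
        ids = {c.circ_id for c in self.circles}
        if not self.de_set <= ids or not self.coding_set <= ids:
            raise ValueError("de_set and coding_set must be subsets of circles")

    @property
    def circ_ids(self) -> list[str]:
        return [c.circ_id for c in self.circles]


# ---------------------------------------------------------------------------
# Genome and circle planting
# ---------------------------------------------------------------------------


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], list[GeneModel]]:
    """Random toy genome: one contig, genes laid out left to right.

    Each gene gets an exon count and per-exon lengths uniform in the
    configured ranges, a random strand, and random intron/intergenic spacers.
    """
    rng = config.rng(_STAGE_GENOME)
    chunks: list[np.ndarray] = []
    genes: list[GeneModel] = []
    pos = 0
    contig = "chrS"
    for g in range(config.n_genes):
        gap = int(rng.integers(100, 301))
        chunks.append(_BASES[rng.integers(0, 4, size=gap)])
        pos += gap
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genomic_exons = []
        for k in range(n_exons):
            if k > 0:
                intron = int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
                chunks.append(_BASES[rng.integers(0, 4, size=intron)])
                pos += intron
            elen = int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))
            chunks.append(_BASES[rng.integers(0, 4, size=elen)])
            genomic_exons.append((pos, pos + elen))
            pos += elen
        # transcription order: left->right on '+', right->left on '-'
        ordered = genomic_exons if strand == "+" else genomic_exons[::-1]
        exons = [
            ExonInterval(contig=contig, start=s, end=e, strand=strand, index=i)
            for i, (s, e) in enumerate(ordered)
        ]
        genes.append(
            GeneModel(gene_id=f"g{g + 1:03d}", contig=contig, strand=strand, exons=exons)
        )
    genome = {contig: np.concatenate(chunks).tobytes().decode("ascii")}
    return genome, genes


def plant_circles(genes: list[GeneModel], config: SimConfig) -> SimTruth:
    """Plant circles as contiguous exon runs and draw their abundances.

    Circles are placed in distinct genes while genes remain (keeps junction
    flanks non-overlapping between circles); a configured fraction must be
    shorter than 1000 nt. Planted runs are at least as long as the longest
    read so no simulated read wraps the circle more than once.
    """
    rng = config.rng(_STAGE_CIRCLES)
    min_len = max(config.rna_read_len, config.ribo_len[1])
    runs_by_gene: dict[str, list[tuple[int, int, int]]] = {}
    for gene in genes:
        lens = [e.length for e in gene.exons]
        runs = []
        for i in range(len(lens)):
            total = 0
            for j in range(i, min(i + config.circle_max_exons, len(lens))):
                total += lens[j]
                if total >= min_len:
                    runs.append((i, j, total))
        if runs:
            runs_by_gene[gene.gene_id] = runs
    n_small = int(round(config.circle_len_max_frac_under_1000 * config.n_circles))
    total_runs = sum(len(v) for v in runs_by_gene.values())
    if config.n_circles > total_runs:
        raise ConfigurationError(
            f"requested {config.n_circles} circles but only {total_runs} exon runs exist"
        )

    gene_by_id = {g.gene_id: g for g in genes}
    order = list(runs_by_gene)
    rng.shuffle(order)
    circles: list[CircleTruth] = []
    used: set[tuple[str, int, int]] = set()
    gene_cycle = 0
    while len(circles) < config.n_circles:
        want_small = len(circles) < n_small
        placed = False
        for _ in range(len(order)):
            gid = order[gene_cycle % len(order)]
            gene_cycle += 1
            pool = [r for r in runs_by_gene[gid] if (gid, r[0], r[1]) not in used]
            pool_pref = [r for r in pool if (r[2] < 1000) == want_small]
            pick_from = pool_pref or pool
            if not pick_from:
                continue
            i, j, total = pick_from[int(rng.integers(len(pick_from)))]
            used.add((gid, i, j))
            circles.append(
                CircleTruth(
                    circ_id=f"{gid}:c{i}-{j}",
                    gene_id=gid,
                    first_exon=i,
                    last_exon=j,
                    circle_len=total,
                    known_db=bool(rng.random() < config.known_db_fraction),
                )
            )
            placed = True
            break
        if not placed:
            raise ConfigurationError("could not place all requested circles")

    circ_ids = [c.circ_id for c in circles]
    de_ids = set(rng.choice(circ_ids, size=config.n_de, replace=False).tolist())
    coding_ids = set(rng.choice(circ_ids, size=config.n_coding, replace=False).tolist())

    mu, sigma = config.base_abundance
    base = np.exp(rng.normal(mu, sigma, size=len(circles)))
    abundance = pd.DataFrame(
        {s: base.copy() for s in config.samples}, index=circ_ids, dtype=float
    )
    for cid in de_ids:
        for s in config.samples[: config.n_pairs]:  # tumor columns
            abundance.loc[cid, s] *= config.planted_fc
    lmu, lsigma = config.linear_abundance
    linear = pd.Series(
        np.exp(rng.normal(lmu, lsigma, size=len(genes))),
        index=[g.gene_id for g in genes],
        dtype=float,
    )
    # sanity: circle length truth equals the sum of member exon lengths
    for c in circles:
        gene = gene_by_id[c.gene_id]
        assert c.circle_len == sum(
            gene.exons[k].length for k in range(c.first_exon, c.last_exon + 1)
        )
    return SimTruth(
        circles=circles,
        abundance=abundance,
        linear_abundance=linear,
        de_set=de_ids,
        coding_set=coding_ids,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(
    seqs: list[str], rng: np.random.Generator, error_rate: float
) -> tuple[list[str], np.ndarray]:
    """iid per-base substitutions; returns mutated reads and error counts."""
    if error_rate == 0.0 or not seqs:
        return seqs, np.zeros(len(seqs), dtype=int)
    lens = np.fromiter((len(s) for s in seqs), dtype=int, count=len(seqs))
    n_err = rng.binomial(lens, error_rate)
    out = list(seqs)
    for idx in np.nonzero(n_err)[0]:
        s = bytearray(out[idx], "ascii")
        pos = rng.choice(len(s), size=n_err[idx], replace=False)
        for p in pos:
            # substitute with one of the three other bases
            choices = [b for b in b"ACGT" if b != s[p]]
            s[p] = choices[int(rng.integers(3))]
        out[idx] = s.decode("ascii")
    return out, n_err


@dataclass
class ReadSet:
    """In-memory simulated reads plus the per-read truth table."""

    reads: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, seq)]
    truth: pd.DataFrame  # TRUTH_COLUMNS

    def library_sizes(self) -> dict[str, int]:
        return {s: len(r) for s, r in self.reads.items()}


def simulate_reads(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[ReadSet, ReadSet]:
    """Draw RNA-seq reads and Ribo-seq footprints for every sample.

    RNA-seq reads come from linear transcripts and from circle sequences
    (fragment start uniform on the circle, so the junction-spanning fraction
    of a circle's reads is (read_len-1)/circle_len). Ribo-seq footprints are
    drawn only from coding-set circles and from linear transcripts acting as
    translated decoys. Returns (rnaseq, riboseq) read sets.
    """
    from .backsplice import circle_rna_sequence

    rng = config.rng(_STAGE_READS)
    gene_by_id = {g.gene_id: g for g in genes}
    circ_seq = {
        c.circ_id: circle_rna_sequence(
            gene_by_id[c.gene_id], c.first_exon, c.last_exon, genome
        )
        for c in truth.circles
    }
    circ_doubled = {cid: s + s for cid, s in circ_seq.items()}
    tx_seq = {g.gene_id: g.transcript_sequence(genome) for g in genes}

    def sample_from_sources(
        sample: str,
        modality: str,
        n_reads: int,
        circ_weights: pd.Series,
        lin_weights: pd.Series,
        read_len_fn,
    ) -> tuple[list[tuple[str, str]], list[list]]:
        sources = [("circle", cid, w) for cid, w in circ_weights.items()] + [
            ("linear", gid, w) for gid, w in lin_weights.items()
        ]
        weights = np.array([w for *_, w in sources], dtype=float)
        if weights.sum() == 0 or n_reads == 0:
            counts = np.zeros(len(sources), dtype=int)
        else:
            counts = rng.multinomial(n_reads, weights / weights.sum())
        reads: list[tuple[str, str]] = []
        rows: list[list] = []
        serial = 0
        for (stype, sid, _), cnt in zip(sources, counts):
            if cnt == 0:
                continue
            if stype == "circle":
                L = len(circ_seq[sid])
                doubled = circ_doubled[sid]
                starts = rng.integers(0, L, size=cnt)
                lens = read_len_fn(cnt)
                seqs = [
                    doubled[s : s + r] for s, r in zip(starts.tolist(), lens.tolist())
                ]
            else:
                tx = tx_seq[sid]
                lens = read_len_fn(cnt)
                starts = np.array(
                    [int(rng.integers(0, len(tx) - r + 1)) for r in lens.tolist()]
                )
                seqs = [tx[s : s + r] for s, r in zip(starts.tolist(), lens.tolist())]
            seqs, n_err = _apply_errors(seqs, rng, config.error_rate)
            for s, r, seq, ne in zip(
                starts.tolist(), lens.tolist(), seqs, n_err.tolist()
            ):
                rid = f"{sample}.{modality}.{serial:07d}"
                serial += 1
                if stype == "circle":
                    L = len(circ_seq[sid])
                    spans = s + r > L
                    left = L - s if spans else 0
                    right = s + r - L if spans else 0
                else:
                    spans, left, right = False, 0, 0
                reads.append((rid, seq))
                rows.append(
                    [rid, sample, modality, stype, sid, s, r, int(spans), left, right, ne]
                )
        return reads, rows

    rna_reads: dict[str, list[tuple[str, str]]] = {}
    ribo_reads: dict[str, list[tuple[str, str]]] = {}
    rna_rows: list[list] = []
    ribo_rows: list[list] = []
    rlen = config.rna_read_len
    ribo_lo, ribo_hi = config.ribo_len
    coding_ids = [c.circ_id for c in truth.circles if c.circ_id in truth.coding_set]
    for sample in config.samples:
        reads, rows = sample_from_sources(
            sample,
            "rnaseq",
            config.n_rna_reads,
            truth.abundance[sample],
            truth.linear_abundance,
            lambda n: np.full(n, rlen, dtype=int),
        )
        rna_reads[sample] = reads
        rna_rows.extend(rows)
        reads, rows = sample_from_sources(
            sample,
            "riboseq",
            config.n_ribo_reads,
            truth.abundance.loc[coding_ids, sample],
            truth.linear_abundance,
            lambda n: rng.integers(ribo_lo, ribo_hi + 1, size=n),
        )
        ribo_reads[sample] = reads
        ribo_rows.extend(rows)

    def frame(rows: list[list]) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    return (
        ReadSet(reads=rna_reads, truth=frame(rna_rows)),
        ReadSet(reads=ribo_reads, truth=frame(ribo_rows)),
    )


def truth_junction_counts(
    readset: ReadSet, circ_ids: list[str], samples: list[str], min_overlap: int
) -> pd.DataFrame:
    """Oracle count matrix: junction-spanning reads with >=min_overlap on
    both sides of the backsplice point, straight from the truth table."""
    t = readset.truth
    hits = t[
        (t.source_type == "circle")
        & (t.spans_junction == 1)
        & (t.left_overlap >= min_overlap)
        & (t.right_overlap >= min_overlap)
    ]
    mat = (
        hits.groupby(["source_id", "sample"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=circ_ids, columns=samples, fill_value=0)
    )
    return mat.astype(int)


# ---------------------------------------------------------------------------
# Direct count simulation (for DE recovery at many seeds) and assay models
# ---------------------------------------------------------------------------


def simulate_junction_counts(
    truth: SimTruth, config: SimConfig, mean_depth: float = 50.0
) -> CountMatrix:
    """Poisson junction counts from expected abundances, bypassing reads.

    Per-sample library sizes vary log-normally around 1e6 and scale the
    Poisson means, so CPM normalization is exercised honestly.
    """
    rng = config.rng(_STAGE_COUNTS)
    samples = config.samples
    lib = np.exp(rng.normal(np.log(1e6), 0.15, size=len(samples)))
    lib_sizes = {s: int(round(v)) for s, v in zip(samples, lib)}
    lam = truth.abundance[samples].to_numpy() * mean_depth
    lam = lam * (lib / 1e6)[None, :]
    counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=truth.abundance.index, columns=samples)
    return CountMatrix(modality="riboseq_or_rnaseq", counts=df, library_sizes=lib_sizes)


def apply_rnase_r(
    circ_abundance, linear_abundance, survival_circ: float, survival_linear: float
):
    """Deterministic RNase R depletion: circles and linear species are scaled
    by their survival fractions (order-preserving within each class)."""
    for name, v in (("survival_circ", survival_circ), ("survival_linear", survival_linear)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name}={v} outside [0, 1]")
    circ = np.asarray(circ_abundance, dtype=float)
    linear = np.asarray(linear_abundance, dtype=float)
    if (circ < 0).any() or (linear < 0).any():
        raise ValueError("abundances must be non-negative")
    return circ * survival_circ, linear * survival_linear


def simulate_rnase_r_counts(
    config: SimConfig, depth: int = 10_000
) -> dict[str, int]:
    """Binomial survival of molecules through an RNase R digestion.

    ``depth`` molecules of a circle and of its cognate linear mRNA are
    treated; each independently survives with its class survival fraction.
    """
    rng = config.rng(_STAGE_ASSAY)
    return {
        "circ_untreated": depth,
        "linear_untreated": depth,
        "circ_treated": int(rng.binomial(depth, config.rnase_r_survival_circ)),
        "linear_treated": int(rng.binomial(depth, config.rnase_r_survival_linear)),
    }


def simulate_fractionation_counts(
    config: SimConfig, depth: int = 10_000
) -> dict[str, int]:
    """Nuclear/cytoplasmic partitioning of circle molecules (binomial)."""
    rng = config.rng(_STAGE_ASSAY)
    rng.bit_generator.advance(4)  # decouple from the RNase R draw
    cyto = int(rng.binomial(depth, config.cyto_fraction_circ))
    return {"cytoplasmic": cyto, "nuclear": depth - cyto}


# ---------------------------------------------------------------------------
# On-disk dataset
# ---------------------------------------------------------------------------


def write_fastq(reads: list[tuple[str, str]], path: str) -> None:
    """4-line FASTQ with constant quality ('I' per base)."""
    with open(path, "w") as fh:
        fh.write(
            "".join(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n" for rid, seq in reads)
        )


def write_truth_tables(truth: SimTruth, rna: ReadSet, ribo: ReadSet, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    rows = [
        [
            c.circ_id,
            c.gene_id,
            c.first_exon,
            c.last_exon,
            c.circle_len,
            int(c.known_db),
            int(c.circ_id in truth.de_set),
            int(c.circ_id in truth.coding_set),
        ]
        for c in truth.circles
    ]
    pd.DataFrame(
        rows,
        columns=[
            "circ_id",
            "gene_id",
            "first_exon",
            "last_exon",
            "circle_len",
            "known_db",
            "is_de",
            "is_coding",
        ],
    ).to_csv(outdir / "truth_circles.tsv", sep="\t", index=False)
    truth.abundance.rename_axis("circ_id").to_csv(
        outdir / "truth_abundance.tsv", sep="\t"
    )
    rna.truth.to_csv(outdir / "truth_reads_rnaseq.tsv", sep="\t", index=False)
    ribo.truth.to_csv(outdir / "truth_reads_riboseq.tsv", sep="\t", index=False)
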
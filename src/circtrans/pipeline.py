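"""End-to-end orchestration: simulate -> index -> quantify -> DE ->
translatome filter -> ORF prediction, with a JSON run report.

Every stage writes its outputs under one directory; the run report records
gate counts (candidate library -> quantified -> DE up -> coding -> final
candidates), the full parameter set, the seed and SHA-256 checksums of all
outputs, so a rerun with the same inputs and seed is byte-identical and can
be verified by checksum comparison. Output directories holding results from
a different configuration hash are refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import backsplice, diffexp, orf, quantify, translatome
from .annotation import read_fasta, read_gtf, write_fasta, write_gtf
from .simulate import (
    ReadSet,
    SimConfig,
    plant_circles,
    simulate_fractionation_counts,
    simulate_genome,
    simulate_reads,
    simulate_rnase_r_counts,
    write_fastq,
    write_truth_tables,
)

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All stage parameters plus the simulation design."""

    sim: SimConfig = field(default_factory=SimConfig)
    flank: int = backsplice.DEFAULT_FLANK
    max_span_exons: int | None = None  # None = all contiguous exon runs
    rna_max_mismatch: int = quantify.RNASEQ_MAX_MISMATCH
    ribo_max_mismatch: int = quantify.RIBOSEQ_MAX_MISMATCH
    min_overlap: int = quantify.DEFAULT_MIN_OVERLAP
    fc_threshold: float = diffexp.FC_THRESHOLD
    coding: translatome.CodingThresholds = field(
        default_factory=translatome.CodingThresholds
    )
    orf_max_passes: int = 4
    orf_min_aa: int = 20
    direction_filter: tuple[str, ...] = ("up",)
    version: str = VERSION

    @property
    def seed(self) -> int:
        return self.sim.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["direction_filter"] = list(self.direction_filter)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("exons_per_gene", "exon_len", "intron_len", "ribo_len",
                        "base_abundance", "linear_abundance"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimConfig(**sim)
        coding = d.pop("coding", {})
        if isinstance(coding, dict):
            coding = translatome.CodingThresholds(**coding)
        if "direction_filter" in d:
            d["direction_filter"] = tuple(d["direction_filter"])
        return cls(sim=sim, coding=coding, **d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, sim=dataclasses.replace(self.sim, seed=seed))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_hash(outdir: Path, config_hash: str) -> None:
    marker = outdir / "config_hash.txt"
    if marker.exists():
        prev = marker.read_text().strip()
        if prev != config_hash:
            raise RuntimeError(
                f"{outdir} holds outputs for config {prev}, refusing to mix "
                f"with {config_hash}"
            )
    else:
        marker.write_text(config_hash + "\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def simulate_command(config: PipelineConfig, outdir) -> dict:
    """Write the full synthetic dataset plus truth tables and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_hash(outdir, config.config_hash())
    sim = config.sim
    genome, genes = simulate_genome(sim)
    truth = plant_circles(genes, sim)
    rna, ribo = simulate_reads(genome, genes, truth, sim)

    write_fasta(genome, outdir / "genome.fa")
    write_gtf(genes, outdir / "annotation.gtf")
    gene_by_id = {g.gene_id: g for g in genes}
    db_rows = []
    for c in truth.circles:
        if not c.known_db:
            continue
        gene = gene_by_id[c.gene_id]
        exons = gene.exons[c.first_exon : c.last_exon + 1]
        db_rows.append(
            (
                f"known_{c.circ_id}",
                gene.contig,
                min(e.start for e in exons),
                max(e.end for e in exons),
                gene.strand,
            )
        )
    backsplice.write_known_db(db_rows, outdir / "known_circles.tsv")
    for readset, modality in ((rna, "rnaseq"), (ribo, "riboseq")):
        for sample, reads in readset.reads.items():
            write_fastq(reads, outdir / f"{sample}.{modality}.fastq")
    write_truth_tables(truth, rna, ribo, outdir)
    pairs = [(f"T{i+1}", f"N{i+1}") for i in range(sim.n_pairs)]
    diffexp.write_sample_sheet(pairs, outdir / "sample_sheet.tsv")

    files = sorted(p.name for p in outdir.iterdir() if p.is_file())
    manifest = {
        "config_hash": config.config_hash(),
        "seed": sim.seed,
        "n_samples": 2 * sim.n_pairs,
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, data_dir, outdir) -> dict:
    """Execute index -> quantify (both modalities) -> DE -> translatome ->
    ORF prediction on a dataset directory; returns the run report."""
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_hash(outdir, config.config_hash())

    genome = read_fasta(data_dir / "genome.fa")
    genes = read_gtf(data_dir / "annotation.gtf")
    gene_by_id = {g.gene_id: g for g in genes}
    pairs = diffexp.read_sample_sheet(data_dir / "sample_sheet.tsv")
    samples = [t for t, _ in pairs] + [n for _, n in pairs]

    # --- index
    logger.info("enumerating candidate circles and building junction library")
    candidates: list[backsplice.CircleCandidate] = []
    for gene in genes:
        candidates.extend(
            backsplice.enumerate_candidate_circles(gene, config.max_span_exons)
        )
    db_rows = backsplice.read_known_db(data_dir / "known_circles.tsv")
    candidates, db_summary = backsplice.annotate_against_db(candidates, db_rows)
    entries = backsplice.build_junction_library(
        candidates, genes, genome, config.flank
    )
    backsplice.write_junction_fasta(entries, outdir / "junction_library.fasta")
    backsplice.write_library_tsv(candidates, entries, outdir / "library.tsv")
    backsplice.write_catalog_bed(candidates, outdir / "catalog.bed")

    # --- quantify
    matrices: dict[str, quantify.CountMatrix] = {}
    for modality, mm in (
        ("rnaseq", config.rna_max_mismatch),
        ("riboseq", config.ribo_max_mismatch),
    ):
        fastqs = {}
        for sample in samples:
            path = data_dir / f"{sample}.{modality}.fastq"
            if not path.exists():
                raise FileNotFoundError(f"missing reads for sample {sample}: {path}")
            fastqs[sample] = str(path)
        logger.info("quantifying %s junction reads (%d samples)", modality, len(fastqs))
        matrix, assignments = quantify.quantify_fastq(
            fastqs, entries, modality, mm, config.min_overlap
        )
        matrix.write(
            outdir / f"{modality}_counts.tsv", outdir / f"{modality}_counts.json"
        )
        assignments.to_csv(outdir / f"{modality}_assignments.tsv", sep="\t", index=False)
        matrices[modality] = matrix

    # --- differential expression
    cpm = diffexp.normalize_cpm(matrices["rnaseq"])
    de = diffexp.differential_circles(cpm, pairs, config.fc_threshold)
    diffexp.write_de_table(
        de,
        outdir / "diffexp.tsv",
        header={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": config.version,
            "fc_threshold": config.fc_threshold,
        },
    )

    # --- translatome filter
    calls = translatome.coding_calls(matrices["riboseq"], config.coding)
    known_ids = {c.circ_id for c in candidates if c.known_db}
    venn = translatome.summarize_venn(de, calls, known_ids)
    cands = translatome.intersect_de_coding(de, calls, config.direction_filter)
    translatome.coding_calls_table(calls).to_csv(
        outdir / "coding_calls.tsv", sep="\t"
    )
    with open(outdir / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2, sort_keys=True)
        fh.write("\n")
    de.loc[cands].join(translatome.coding_calls_table(calls)).to_csv(
        outdir / "candidates.tsv", sep="\t"
    )

    # --- ORF prediction on nominated candidates
    cand_by_id = {c.circ_id: c for c in candidates}
    orf_rows = []
    proteins: dict[str, str] = {}
    for cid in cands:
        cand = cand_by_id[cid]
        circ = orf.circle_sequence(gene_by_id[cand.gene_id], cand, genome)
        orfs = [
            o
            for o in orf.find_circular_orfs(
                circ, config.orf_max_passes, config.orf_min_aa
            )
            if o.spans_junction
        ]
        orf_rows.extend(orfs)
        for o in orfs:
            if o.protein:
                proteins[f"{o.circ_id}|orf{o.start}"] = o.protein
    orf.orf_table(orf_rows).to_csv(outdir / "orfs.tsv", sep="\t", index=False)
    write_fasta(proteins, outdir / "proteins.fa")

    # --- assay summaries at the simulator's study conditions
    rnr = simulate_rnase_r_counts(config.sim)
    frac = simulate_fractionation_counts(config.sim)
    assays = {
        "rnase_r_resistance": diffexp.rnase_r_resistance(
            rnr["circ_treated"],
            rnr["circ_untreated"],
            rnr["linear_treated"],
            rnr["linear_untreated"],
        ),
        "cytoplasmic_fraction": diffexp.fraction_localization(
            frac["nuclear"], frac["cytoplasmic"]
        ),
    }

    report = {
        "version": config.version,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "parameters": config.to_dict(),
        "gates": {
            "n_candidate_library": len(candidates),
            "n_quantified_rnaseq": int((matrices["rnaseq"].counts.sum(axis=1) > 0).sum()),
            "n_quantified_riboseq": int((matrices["riboseq"].counts.sum(axis=1) > 0).sum()),
            "n_de": venn["n_de"],
            "n_de_up": venn["n_de_up"],
            "n_de_down": venn["n_de_down"],
            "n_coding": venn["n_coding"],
            "n_candidates": len(cands),
        },
        "db_annotation": db_summary,
        "venn": venn,
        "assays": assays,
        "candidates": cands,
        "checksums": {},
    }
    report["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("run_report.json",)
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
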
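"""Coding-circRNA filter on ribosome-profiling junction evidence.

A circle is called a potential coding circRNA when unique Ribo-seq junction
reads are seen in at least ``min_samples_with_reads`` samples (default 3)
and the total across samples is strictly greater than
``min_total_reads_exclusive`` (default 8 — a total of exactly 8 fails).
Read uniqueness (zero mismatches, >=8 nt overlap on each side of the
junction, ambiguous assignments discarded) is enforced upstream by the
Ribo-seq quantification mode; this module consumes counts as given.
Candidate nomination intersects coding calls with differentially expressed
circles (by default the upregulated ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .quantify import CountMatrix


@dataclass(frozen=True)
class CodingThresholds:
    min_samples_with_reads: int = 3
    min_total_reads_exclusive: int = 8  # strict: total must exceed this
    max_mismatch: int = 0  # echoed from upstream matching, for provenance
    min_overlap: int = 8

    def __post_init__(self) -> None:
        for name in (
            "min_samples_with_reads",
            "min_total_reads_exclusive",
            "max_mismatch",
            "min_overlap",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class CodingCall:
    circ_id: str
    samples_with_reads: int
    total_junction_reads: int
    passes: bool
    per_sample: dict[str, int] = field(default_factory=dict, compare=False)


def coding_calls(
    ribo: CountMatrix, thresholds: CodingThresholds = CodingThresholds()
) -> list[CodingCall]:
    """Apply the two-clause coding rule to every circle in the Ribo-seq matrix.

    Calls are returned in ascending circ_id order. Passing a non-Ribo-seq
    matrix is a hard error: the rule is only meaningful on footprint counts
    produced under the strict (0-mismatch) matching mode.
    """
    if ribo.modality != "riboseq":
        raise ValueError(
            f"coding filter requires a riboseq count matrix, got {ribo.modality!r}"
        )
    calls = []
    for circ_id in sorted(ribo.counts.index):
        row = ribo.counts.loc[circ_id]
        n_samples = int((row > 0).sum())
        total = int(row.sum())
        calls.append(
            CodingCall(
                circ_id=circ_id,
                samples_with_reads=n_samples,
                total_junction_reads=total,
                passes=(
                    n_samples >= thresholds.min_samples_with_reads
                    and total > thresholds.min_total_reads_exclusive
                ),
                per_sample={s: int(v) for s, v in row.items()},
            )
        )
    return calls


def intersect_de_coding(
    de: pd.DataFrame,
    coding: list[CodingCall],
    direction_filter: tuple[str, ...] = ("up",),
) -> list[str]:
    """Candidate circles: pass the coding filter AND are DE in an accepted
    direction (default upregulated only). Sorted by circ_id."""
    coding_pass = {c.circ_id for c in coding if c.passes}
    de_keep = set(de.index[de["direction"].isin(direction_filter)])
    return sorted(coding_pass & de_keep)


def summarize_venn(
    de: pd.DataFrame, coding: list[CodingCall], known_ids: set[str] | None = None
) -> dict[str, int]:
    """Counts behind the coding-vs-DE Venn diagram.

    ``known_ids`` (circles annotated in the known-circle DB) adds the
    annotated-coding count when available.
    """
    de_called = de[de["direction"] != "unchanged"]
    coding_pass = {c.circ_id for c in coding if c.passes}
    return {
        "n_de": int(len(de_called)),
        "n_de_up": int((de["direction"] == "up").sum()),
        "n_de_down": int((de["direction"] == "down").sum()),
        "n_coding": len(coding_pass),
        "n_coding_annotated": len(coding_pass & known_ids)
        if known_ids is not None
        else 0,
        "n_intersection": len(coding_pass & set(de_called.index)),
    }


def coding_calls_table(calls: list[CodingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "circ_id": [c.circ_id for c in calls],
            "samples_with_reads": [c.samples_with_reads for c in calls],
            "total_junction_reads": [c.total_junction_reads for c in calls],
            "passes": [int(c.passes) for c in calls],
        }
    ).set_index("circ_id")
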
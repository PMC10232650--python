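"""Cross-junction ORF prediction on circular RNAs and related annotations.

A ribosome that initiates on a circle and reads through the backsplice
junction re-enters the sequence at position 0; when the circle length is not
a multiple of 3, each full pass shifts the reading frame by (length mod 3).
This geometric frameshift lets a circle encode protein sequence that does
not exist in the cognate linear mRNA — the unique C-terminal suffix — and
can require several passes before a stop codon is reached in any visited
frame (rolling-circle translation). ORFs that never reach a stop within the
pass budget are reported with an infinite-ORF flag rather than dropped.

Also here: the unique C-terminus relative to the linear protein, average-mass
molecular weight (immunoblot scale), distances of sequence features (e.g. an
IRES) to the junction, and divergent/convergent qPCR primer design — the
divergent pair can only amplify across the backsplice junction, so a product
is diagnostic of the circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq, reverse_complement
from Bio.SeqUtils import molecular_weight as _bio_mw

START_CODON = "ATG"
STOP_CODONS = {"TAA", "TAG", "TGA"}
WATER_DA = 18.0153


@dataclass(frozen=True)
class CircSequence:
    """A circularized RNA sequence (DNA alphabet).

    Position 0 is the first base of the circle's first exon; the backsplice
    point lies between the last and the first base.
    """

    circ_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty circle sequence")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.circ_id}: non-ACGT characters in sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CircOrf:
    circ_id: str
    start: int  # circle coordinate of the A of the initiating ATG
    aa_length: int  # residues, stop codon not included
    protein: str
    spans_junction: bool
    junction_crossings: int
    stop_found: bool  # False => infinite ORF (no stop within the pass budget)
    frame_shift_per_pass: int  # circle length mod 3


@dataclass(frozen=True)
class UniqueSuffix:
    suffix: str
    length: int
    divergence_index: int  # first residue where circle and linear proteins differ


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    orientation: str  # 'divergent' or 'convergent'
    forward_start: int  # circle coordinate of the forward primer 5' end
    reverse_start: int  # circle coordinate of the reverse-primer window start
    amplicon_circle: int | None
    amplicon_linear: int | None
    tm_forward: float
    tm_reverse: float


def circle_sequence(gene, candidate, genome: dict[str, str]) -> CircSequence:
    """Circularized RNA sequence for a candidate (exons spliced 5'->3')."""
    from .backsplice import circle_rna_sequence

    seq = circle_rna_sequence(gene, candidate.first_exon, candidate.last_exon, genome)
    return CircSequence(circ_id=candidate.circ_id, sequence=seq)


def translate_nt(seq: str) -> str:
    """Standard-code translation; stop codons render as '*'."""
    if len(seq) % 3 != 0:
        raise ValueError(f"length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate())


def find_circular_orfs(
    circ: CircSequence, max_passes: int = 4, min_aa: int = 20
) -> list[CircOrf]:
    """All ATG-initiated ORFs on the circle, translated with wraparound.

    From every ATG (including ATGs straddling the junction) translation
    proceeds codon by codon around the circle until a stop codon or until
    3 * max_passes * length nt have been consumed (a frame revisits its
    starting state after at most 3 passes, so exceeding that is provably
    stopless). Emitted are ORFs of at least ``min_aa`` residues plus every
    junction-spanning ORF regardless of length; duplicates in
    (start, protein) are removed.
    """
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    seq = circ.sequence
    L = circ.length
    cap_nt = 3 * max_passes * L
    # enough linear copies to read cap_nt from any start without wrapping
    ext = seq * (3 * max_passes + 2)
    orfs: list[CircOrf] = []
    seen: set[tuple[int, str]] = set()
    for start in range(L):
        if ext[start : start + 3] != START_CODON:
            continue
        aas: list[str] = []
        stop_found = False
        pos = start
        while pos + 3 - start <= cap_nt:
            codon = ext[pos : pos + 3]
            if codon in STOP_CODONS:
                stop_found = True
                break
            aas.append(_CODON_TABLE[codon])
            pos += 3
        consumed = pos + 3 - start if stop_found else pos - start
        # circle coordinate of the last consumed base decides the crossings
        crossings = (start + consumed - 1) // L if consumed > 0 else 0
        protein = "".join(aas)
        key = (start, protein)
        if key in seen:
            continue
        seen.add(key)
        spans = crossings >= 1
        if len(protein) >= min_aa or spans:
            orfs.append(
                CircOrf(
                    circ_id=circ.circ_id,
                    start=start,
                    aa_length=len(protein),
                    protein=protein,
                    spans_junction=spans,
                    junction_crossings=crossings,
                    stop_found=stop_found,
                    frame_shift_per_pass=L % 3,
                )
            )
    orfs.sort(key=lambda o: (o.start, -o.aa_length))
    return orfs


# plain dict lookup is ~20x faster than Seq.translate per codon
_CODON_TABLE = {
    f"{a}{b}{c}": translate_nt(f"{a}{b}{c}")
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
}


def unique_c_terminus(circ_protein: str, linear_protein: str) -> UniqueSuffix:
    """The circle protein's suffix after it diverges from the linear protein.

    Both proteins are compared from their shared start; the divergence index
    is the first differing residue (or the shorter length if one is a prefix
    of the other). For a cross-junction ORF this is the frameshift-derived
    unique C-terminal sequence.
    """
    if not circ_protein or not linear_protein:
        raise ValueError("proteins must be non-empty")
    div = next(
        (i for i, (a, b) in enumerate(zip(circ_protein, linear_protein)) if a != b),
        min(len(circ_protein), len(linear_protein)),
    )
    return UniqueSuffix(
        suffix=circ_protein[div:],
        length=len(circ_protein) - div,
        divergence_index=div,
    )


def molecular_weight_da(protein: str) -> float:
    """Average (not monoisotopic) molecular weight in Da, one water included."""
    if not protein:
        raise ValueError("empty protein")
    return float(_bio_mw(protein, seq_type="protein", monoisotopic=False))


def molecular_weight_kda(protein: str) -> float:
    """Molecular weight in kDa, rounded to 2 decimals (immunoblot scale)."""
    return round(molecular_weight_da(protein) / 1000.0, 2)


def feature_distance_to_junction(circ: CircSequence, feature: str) -> list[dict]:
    """Occurrences of ``feature`` on the circle with upstream distance to
    the junction (nt from the feature 3' end to the backsplice point, 5'->3'
    around the circle). A feature straddling the junction reports distance 0
    with a flag; an absent feature yields an empty list."""
    if not feature:
        raise ValueError("empty feature sequence")
    L = circ.length
    doubled = circ.sequence * 2
    out = []
    pos = doubled.find(feature)
    while pos != -1 and pos < L:
        end = pos + len(feature) - 1
        spans = end >= L
        out.append(
            {
                "start": pos,
                "end": end % L,
                "upstream_distance": 0 if spans else L - 1 - end,
                "spans_junction": spans,
            }
        )
        pos = doubled.find(feature, pos + 1)
    return out


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature: 2C per A/T plus 4C per G/C."""
    return 2.0 * (primer.count("A") + primer.count("T")) + 4.0 * (
        primer.count("G") + primer.count("C")
    )


def design_primers(
    circ: CircSequence,
    primer_len: tuple[int, int] = (18, 22),
    max_amplicon: int = 150,
    orientation: str = "divergent",
    max_pairs: int = 5,
) -> list[PrimerPair]:
    """qPCR primer pairs around (divergent) or away from (convergent) the
    backsplice junction, ranked by Tm balance.

    Divergent pairs point apart on the linear template — no linear product is
    possible — and amplify only across the junction on the circle, so the
    predicted circle amplicon contains position 0. Convergent pairs amplify
    a junction-free segment present on both templates.
    """
    if orientation not in ("divergent", "convergent"):
        raise ValueError(f"unknown orientation {orientation!r}")
    L, S = circ.length, circ.sequence
    lo, hi = primer_len
    if lo > hi or lo < 1:
        raise ValueError("degenerate primer length range")
    if L < 2 * lo:
        raise ValueError("circle shorter than two primers")
    pairs: list[tuple[float, PrimerPair]] = []

    def add(fs: int, rs: int, amp_c: int | None, amp_l: int | None, plen: int) -> None:
        fwd = S[fs : fs + plen]
        rev = reverse_complement(S[rs : rs + plen])
        pair = PrimerPair(
            forward=fwd,
            reverse=rev,
            orientation=orientation,
            forward_start=fs,
            reverse_start=rs,
            amplicon_circle=amp_c,
            amplicon_linear=amp_l,
            tm_forward=wallace_tm(fwd),
            tm_reverse=wallace_tm(rev),
        )
        pairs.append((abs(pair.tm_forward - pair.tm_reverse), pair))

    for plen in range(lo, hi + 1):
        budget = max_amplicon - 2 * plen
        if budget < 0 or L < 2 * plen:
            continue
        if orientation == "divergent":
            # forward primer ends d_f nt before the junction, reverse-primer
            # window begins d_r nt after it: the circle amplicon wraps
            # position 0 and the primers point apart on the linear template
            for d_f in range(0, min(budget, L - plen) + 1):
                fs = L - plen - d_f
                for d_r in range(0, min(budget - d_f, L - plen) + 1):
                    rs = d_r
                    if fs < rs + plen:  # windows may not collide on the circle
                        continue
                    add(fs, rs, d_f + d_r + 2 * plen, None, plen)
        else:
            # convergent: both windows inside the linear sequence, forward
            # upstream of reverse; the product never contains the junction
            for fs in range(0, min(L - 2 * plen, 60) + 1):
                for gap in range(0, min(budget, L - fs - 2 * plen) + 1):
                    rs = fs + plen + gap
                    add(fs, rs, 2 * plen + gap, 2 * plen + gap, plen)
    pairs.sort(key=lambda t: (t[0], t[1].forward_start, t[1].reverse_start))
    return [p for _, p in pairs[:max_pairs]]


def orf_table(orfs: Sequence[CircOrf]):
    import pandas as pd

    return pd.DataFrame(
        {
            "circ_id": [o.circ_id for o in orfs],
            "start": [o.start for o in orfs],
            "aa_length": [o.aa_length for o in orfs],
            "spans_junction": [int(o.spans_junction) for o in orfs],
            "junction_crossings": [o.junction_crossings for o in orfs],
            "stop_found": [int(o.stop_found) for o in orfs],
            "frame_shift_per_pass": [o.frame_shift_per_pass for o in orfs],
            "mw_kda": [
                molecular_weight_kda(o.protein) if o.protein else float("nan")
                for o in orfs
            ],
            "protein": [o.protein for o in orfs],
        }
    )
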
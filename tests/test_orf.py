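"""Rolling-circle ORF prediction, unique C-terminus, MW, features, primers."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from circtrans.annotation import ExonInterval, GeneModel
from circtrans.orf import (
    CircSequence,
    circle_sequence,
    design_primers,
    feature_distance_to_junction,
    find_circular_orfs,
    molecular_weight_da,
    molecular_weight_kda,
    translate_nt,
    unique_c_terminus,
    wallace_tm,
)

WATER = 18.0153


def test_translate_standard_code():
    assert translate_nt("ATG") == "M"
    assert translate_nt("TAA") == "*"
    assert translate_nt("ATGCGTAAA") == "MRK"
    with pytest.raises(ValueError):
        translate_nt("ATGC")


def test_rolling_circle_worked_example():
    """ATG at position 4 of GTAAATGC reads around the circle three times
    before hitting a TAA assembled across passes."""
    orfs = find_circular_orfs(CircSequence("c", "GTAAATGC"), max_passes=4, min_aa=1)
    assert len(orfs) == 1
    (o,) = orfs
    assert o.protein == "MRKCVNA"
    assert o.start == 4
    assert o.aa_length == 7
    assert o.junction_crossings == 3
    assert o.spans_junction
    assert o.stop_found
    assert o.frame_shift_per_pass == 8 % 3


def test_stop_before_junction_does_not_span():
    orfs = find_circular_orfs(CircSequence("c", "ATGTAA"), max_passes=4, min_aa=1)
    (o,) = orfs
    assert o.protein == "M" and not o.spans_junction and o.stop_found


def test_stopless_circle_flagged_infinite():
    orfs = find_circular_orfs(CircSequence("c", "ATGGGG"), max_passes=4, min_aa=1)
    assert any(not o.stop_found for o in orfs)
    inf = next(o for o in orfs if not o.stop_found)
    # translation was cut at the pass budget: 3 * max_passes * L nt
    assert inf.aa_length == 3 * 4 * 6 // 3


def test_multiple_of_three_circle_never_shifts_frame():
    rng = np.random.default_rng(31)
    seq = "".join(rng.choice(list("ACGT"), size=99))
    for o in find_circular_orfs(CircSequence("c", seq), min_aa=1):
        assert o.frame_shift_per_pass == 0


def test_non_acgt_rejected():
    with pytest.raises(ValueError):
        CircSequence("c", "ATGNNN")


def _linear_orfs_on_doubled(seq: str):
    """Independent oracle: plain linear ORF scan of the doubled sequence,
    keeping starts in the first copy and stops reached within it."""
    L = len(seq)
    doubled = seq + seq
    out = {}
    for s in range(L):
        if doubled[s : s + 3] != "ATG":
            continue
        aas = []
        pos = s
        while pos + 3 <= 2 * L:
            codon = doubled[pos : pos + 3]
            if codon in ("TAA", "TAG", "TGA"):
                crossings = (pos + 3 - 1) // L if pos + 3 > s else 0
                out[(s, "".join(aas))] = crossings
                break
            aas.append(translate_nt(codon))
            pos += 3
    return out


def test_single_crossing_orfs_match_doubled_sequence_oracle():
    rng = np.random.default_rng(47)
    for _ in range(60):
        L = int(rng.integers(30, 301))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        oracle = {
            key for key, crossings in _linear_orfs_on_doubled(seq).items()
            if crossings <= 1
        }
        mine = {
            (o.start, o.protein)
            for o in find_circular_orfs(CircSequence("c", seq), min_aa=1)
            if o.stop_found and o.junction_crossings <= 1
        }
        assert mine == oracle


def test_orf_position_bookkeeping_invariants():
    rng = np.random.default_rng(53)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    circ = CircSequence("c", seq)
    L = circ.length
    doubled_many = seq * 20
    for o in find_circular_orfs(circ, min_aa=1):
        if o.stop_found:
            consumed = 3 * (o.aa_length + 1)
            assert (o.start + consumed - 1) // L == o.junction_crossings
        assert o.frame_shift_per_pass == L % 3
        if o.spans_junction and o.aa_length > 0:
            # the codon straddling position 0 translates into the protein
            k = (L - o.start + 2) // 3  # first codon index touching position 0
            codon = doubled_many[o.start + 3 * k : o.start + 3 * k + 3]
            if k < o.aa_length:
                assert o.protein[k] == translate_nt(codon)


def test_minus_strand_circle_sequence_is_reverse_complement():
    genome = {"chrT": "AAGGCCTTACGTACGTAAGGCCTT"}
    #                  0123456789...
    gene = GeneModel(
        gene_id="g",
        contig="chrT",
        strand="-",
        exons=[
            ExonInterval("chrT", 16, 22, "-", 0),
            ExonInterval("chrT", 2, 10, "-", 1),
        ],
    )

    class Cand:
        circ_id, gene_id, first_exon, last_exon = "g:c0-1", "g", 0, 1

    circ = circle_sequence(gene, Cand, genome)
    expected = reverse_complement(genome["chrT"][16:22]) + reverse_complement(
        genome["chrT"][2:10]
    )
    assert circ.sequence == expected
    assert circ.length == 14


def test_unique_c_terminus_rules():
    s = unique_c_terminus("MAAKRRS", "MAAKLLGQQ")
    assert (s.suffix, s.length, s.divergence_index) == ("RRS", 3, 4)
    s = unique_c_terminus("MAAK", "MAAK")
    assert (s.suffix, s.length, s.divergence_index) == ("", 0, 4)
    s = unique_c_terminus("MAAKXYZ", "MAAK")  # linear is a strict prefix
    assert (s.suffix, s.divergence_index) == ("XYZ", 4)


def test_molecular_weight_reference_values_and_additivity():
    assert molecular_weight_da("G") == pytest.approx(75.07, abs=0.01)
    assert molecular_weight_da("GG") == pytest.approx(132.12, abs=0.01)
    assert molecular_weight_da("M") == pytest.approx(149.21, abs=0.01)
    a, b = "MKWVTFISLLFLFSSAYS", "RGVFRR"
    assert molecular_weight_da(a + b) == pytest.approx(
        molecular_weight_da(a) + molecular_weight_da(b) - WATER, abs=1e-6
    )
    assert molecular_weight_kda("G" * 1000) == pytest.approx(57.07, abs=0.01)
    with pytest.raises(ValueError):
        molecular_weight_da("MXB1")


def test_feature_distance_to_junction():
    rng = np.random.default_rng(61)
    seq = "".join(rng.choice(list("ACGT"), size=100))
    feature = seq[85:95]  # ends at position 94, 5 nt before the junction
    hits = feature_distance_to_junction(CircSequence("c", seq), feature)
    assert any(h["upstream_distance"] == 5 and not h["spans_junction"] for h in hits)
    straddle = seq[95:] + seq[:5]
    hits = feature_distance_to_junction(CircSequence("c", seq), straddle)
    assert any(h["spans_junction"] and h["upstream_distance"] == 0 for h in hits)
    absent = "A" * 32  # vanishingly unlikely in a random 100-mer
    assert feature_distance_to_junction(CircSequence("c", seq), absent) == []


def test_wallace_rule_tm():
    assert wallace_tm("ACGT") == 12.0
    assert wallace_tm("AAAA") == 8.0
    assert wallace_tm("GGCC") == 16.0


def test_divergent_primers_amplify_only_across_junction():
    rng = np.random.default_rng(67)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    circ = CircSequence("c", seq)
    pairs = design_primers(circ, orientation="divergent")
    assert pairs
    for p in pairs:
        plen = len(p.forward)
        assert p.forward == seq[p.forward_start : p.forward_start + plen]
        assert p.reverse == reverse_complement(
            seq[p.reverse_start : p.reverse_start + len(p.reverse)]
        )
        assert p.amplicon_linear is None  # primers point apart on the line
        # the circle amplicon wraps the backsplice point
        assert p.amplicon_circle == (200 - p.forward_start) + p.reverse_start + len(p.reverse)
        assert p.amplicon_circle <= 150
        assert p.forward_start >= p.reverse_start + len(p.reverse)


def test_convergent_primers_exclude_junction():
    rng = np.random.default_rng(71)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    pairs = design_primers(CircSequence("c", seq), orientation="convergent")
    assert pairs
    for p in pairs:
        assert p.amplicon_linear == p.amplicon_circle
        assert p.forward_start + len(p.forward) <= p.reverse_start
        assert p.reverse_start + len(p.reverse) <= 200  # junction never inside


def test_primer_pairs_ranked_by_tm_balance():
    rng = np.random.default_rng(73)
    seq = "".join(rng.choice(list("ACGT"), size=150))
    pairs = design_primers(CircSequence("c", seq), orientation="divergent", max_pairs=10)
    gaps = [abs(p.tm_forward - p.tm_reverse) for p in pairs]
    assert gaps == sorted(gaps)
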
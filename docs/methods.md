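# Methods

## The decision chain

`circtrans` models the identification of translated circular RNAs from a
paired tumor/normal design with two sequencing modalities per sample:
circRNA-enriched RNA-seq and ribosome profiling. The backsplice junction is
the load-bearing object throughout. A circle over exons *[i..j]* of a gene
is represented by its junction pseudo-sequence — the last *L* nt of the
circularized exon sequence concatenated with its first *L* nt — and all
read-level evidence is read alignment across that junction:

- an **expression** junction read (RNA-seq) supports the circle's existence
  and abundance;
- a **translation** junction read (Ribo-seq footprint, 26–34 nt) supports
  ribosome occupancy across the junction, which only a translated circle can
  produce.

Candidates are nominated when a circle is both upregulated in tumors
(fold change ≥ 2.5 on CPM-normalized junction counts) and passes the coding
filter (junction footprints in ≥ 3 samples and > 8 footprints in total,
with zero mismatches and ≥ 8 nt junction overlap on each side, uniquely
assigned). Cross-junction ORFs are then predicted on the nominated circles.

## Read matching

Matching is ungapped Hamming comparison of the read against every
pseudo-sequence at every offset that straddles the junction with at least
`min_overlap` nt on each side. The best (fewest-mismatch) alignment is
reported; a tie across distinct circles discards the read, which is what
makes counted reads "unique junction reads". Substitution-only matching is
appropriate because the simulator injects substitution errors only and the
filtering rules are phrased in substitutions; indel tolerance is a non-goal.

For throughput, bulk quantification uses a pigeonhole seed index: the read
is split into `max_mismatch + 1` contiguous segments, so any alignment
within the mismatch budget must leave at least one segment error-free, and
a k-mer (k ≤ 16) at each segment start locates all such alignments in a
precomputed index of the library. This is exactly equivalent to the
all-offsets scan (property-tested against it) whenever
`read_len ≥ (max_mismatch + 1) · k`; shorter reads fall back to the scan.

The flank width *L* defaults to 50 nt, which covers every footprint length.
A read can only be matched if its junction alignment fits inside the
pseudo-sequence, so junction reads overlapping one side by more than *L* are
unmatchable; for exhaustive recovery of 75-nt RNA-seq junction reads the
truth-recovery runs set *L* to the read length. This is a deliberate
trade-off, not a defect: with patient-scale libraries a wide flank only
grows the index, while at desk scale it makes count recovery exact.

## Differential expression

Junction counts are normalized to counts per million library reads (CPM).
Fold change is `(mean tumor CPM + ε) / (mean normal CPM + ε)` with
ε = 0.5 CPM; the pseudocount prevents division by zero without materially
shifting large fold changes. The gate is inclusive (≥ 2.5 calls "up",
≤ 0.4 calls "down") and configurable.

The paired Wilcoxon signed-rank test is exact: zero differences are dropped,
|differences| are mid-ranked on ties, and the null distribution of the
positive-rank sum is enumerated over all 2ⁿ sign assignments (implemented as
a subset-sum recursion over doubled ranks, identical to the enumeration but
O(n·Σranks)); the two-sided p is `2·min(P(W≤w), P(W≥w))` capped at 1.
With n = 4 pairs the smallest attainable p is 2/16 = 0.125, so at this
design size the test cannot clear conventional significance on its own —
the fold-change gate is the primary DE rule and p/q annotate it. q-values
are Benjamini–Hochberg across all tested circles and are an addition to the
raw p-values, labelled as such.

Assay summaries are count ratios: RNase R resistance
`(circ_t/circ_u)/(lin_t/lin_u)` (≈ 18 at the default survivals 0.9 and
0.05) and cytoplasmic fraction `cyto/(cyto+nuc)`. ΔΔCt machinery is not
modelled; the count-ratio abstraction carries the same information.

## Rolling-circle ORF prediction

From every ATG on the circle (including ATGs straddling the junction),
translation proceeds codon by codon with wraparound until a stop codon or
until `3 · max_passes · length` nt are consumed. Because a reading frame
returns to its starting state after at most 3 full passes, exceeding that
budget proves no stop is reachable; such ORFs are reported with
`stop_found = False` (infinite-ORF flag) rather than dropped. The
"ribosomal frameshift at the junction" is modelled geometrically: a circle
of length L ≢ 0 (mod 3) shifts frame by `L mod 3` per pass. Programmed
−1/+1 slippage is intentionally not modelled; the geometric mechanism is
sufficient to generate cross-junction products whose C-terminus diverges
from the linear protein, and the divergence point and unique suffix are
computed by direct comparison with the linear translation.

Start codons are ATG only; IRES-dependent initiation is represented by
letting the caller restrict or supply start positions rather than by IRES
prediction (out of scope). `min_aa` (default 20) suppresses micro-ORF noise,
but junction-spanning ORFs are always emitted because they are the object of
study. Molecular weights use average (not monoisotopic) residue masses plus
one water, matching immunoblot-scale reporting, via Biopython's mass tables.

Primer design enumerates window pairs around the junction (divergent: the
circle amplicon wraps the junction and no linear product is possible because
the primers point apart on the linear template) or inside the linear
sequence (convergent), ranks pairs by |ΔTm| under the Wallace rule
(2 °C per A/T, 4 °C per G/C), and reports predicted amplicon lengths on both
templates.

## The simulator: what it emulates and what it does not

The generator reproduces the *structure* of the study design — 4 tumor/normal
pairs, circles formed from contiguous exon runs of single genes (at most 6
exons by default, like a 6-exon backsplice; 90% under 1000 nt), planted
8-fold tumor fold changes on a subset, a coding subset that alone receives
junction-spanning footprints, 75-nt RNA-seq reads, 26–34 nt footprints,
iid substitution errors (default 0.1%), RNase R survival 0.9 (circle) vs
0.05 (linear), cytoplasmic fraction 0.75, and 50,000 reads per sample and
modality. Abundances are log-normal; reads are allocated multinomially by
abundance and fragment starts are uniform, so the fraction of a circle's
reads spanning the junction is `(read_len − 1)/circle_len` — a closed form
the tests verify binomially.

Not modelled: library-prep chemistry (rRNA depletion, footprinting
nuclease bias), codon-level ribosome dwell times, indels, paired-end reads,
intronic/intergenic circles, UMIs/PCR duplicates, and batch effects.
Consequently, passing tests demonstrate that the *decision rules* behave as
specified under their stated assumptions — they do not demonstrate
robustness to real-data artifacts like coverage bias or duplicated reads.
Quality strings are constant ("I") because no downstream stage consumes
quality. Planted circles are at least as long as the longest read, so no
simulated read wraps more than once, and they are placed in distinct genes
while genes remain, which keeps junction flanks from colliding between
planted circles.

Randomness: one root seed; each stage (genome, circles, reads, counts,
assays) draws from `default_rng([seed, stage_offset])` with fixed offsets,
so identical configurations reproduce byte-identical outputs and stages can
be regenerated independently.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GTF converts at the
  boundary (1-based closed); BED is written natively half-open. One internal
  convention prevents off-by-one drift.
- Minus-strand genes: exon ordinals follow transcription order and
  sequences are reverse-complemented at extraction, so circle formation and
  junction logic are strand-agnostic downstream.
- Known-circle DB matching is exact on (contig, start, end, strand); no
  fuzzy window, so the behaviour is fully testable. Malformed DB rows are
  skipped, warned about and counted.
- "More than eight total junction reads" is implemented strictly (> 8; a
  total of 8 fails), and "≥ 3 samples" counts all Ribo-seq samples; both
  are configurable.
- RNA-seq mismatch allowance defaults to 2 (the zero-mismatch rule is
  specific to footprints); the two-sided ≥ 8 nt overlap applies to both
  modalities by default. No read deduplication is performed and the output
  metadata says so.
- The DE caller treats fold change as primary and the exact Wilcoxon p as
  evidence (see above); the direction filter for candidate nomination
  defaults to upregulated circles only.
- Candidate enumeration caps runs at `max_span_exons`; the simulator's
  `circle_max_exons` (6) keeps planted circles within any cap ≥ 6 so
  end-to-end recovery is well-defined.
- Test problem sizes: read-level recovery runs use 4 pairs × 10 circles ×
  50,000 reads/sample; DE recovery uses 20 seeds of 20 circles with 4
  planted; oracle sweeps use 1000 random count matrices and 500 random
  circles. These sizes make every binomial tolerance in the tests
  comfortably tight while keeping the default suite fast.

## Known limitations

- De-novo circle discovery by split-read alignment against the whole genome
  is replaced by enumerate-then-match over annotated exon runs; the decision
  logic downstream is identical, but novel junctions outside the annotation
  cannot be found.
- Linear-transcript expression is summarized only as library size; no
  isoform quantification.
- The exact Wilcoxon enumeration is limited to n ≤ 25 pairs (beyond that an
  exact test is neither needed nor the paired-design regime this targets).
- Dataset-scale totals from patient cohorts are functions of unavailable
  data and are not reproduced; all quantitative guarantees are stated
  against planted synthetic truth.
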
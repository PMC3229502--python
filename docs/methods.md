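# Methods

`dinogss` re-implements, as a tested library, the bespoke computations of a
dinoflagellate genome/transcriptome survey: spliced-leader (SL) relict
detection in ESTs, tandem-repeat-array discovery and genome-fraction
estimation in clone-end reads, a repetitiveness/feature census, and
stop-codon / polyadenylation-signal statistics. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Sequence model

Sequences are uppercase DNA over `{A,C,G,T,N}`; `U` is mapped to `T` on
input. Coordinates are 0-based half-open. `N` is handled conservatively:
it matches nothing (not even another `N`) in every identity computation and
is excluded from both numerator and denominator of GC content (an all-`N`
sequence has undefined GC and raises). Percentages intended to be compared
with conventionally rounded tables use round-half-up at the table's printed
precision.

`find_polyA_start` locates the 3'-terminal polyA run by walking leftward
from the 3' end: the run must begin with an `A`, may cross up to
`max_mismatch` (default 1) non-`A` bases provided further `A` lie beyond
them, and qualifies once it contains `min_run` (default 10) `A`s. The
synthetic generators place two non-`A` bases immediately 5' of every
planted tail, so the locator recovers planted tail starts exactly; on real
data a tail preceded by genomic `A`s is reported with a correspondingly
earlier start, which only shifts the upstream scan window.

## Spliced-leader relict cascades

Dinoflagellate nuclear mRNAs are trans-spliced with a conserved 22-nt
leader. Recycling of processed mRNAs back into the genome (reverse
transcription and reintegration) leaves *relict* leaders: copies truncated
after nucleotide 7 — i.e. the 15-nt tail downstream of the AG
splice-acceptor — chained directly 3' of the canonical SL, with identity
decaying with age.

* **Canonical detection** scores every 22-nt window in the 5'-most 60
  bases against the IUPAC consensus (default
  `DCCGTAGCCATTTTGGCTCAAG`, the conserved dinoflagellate leader; a
  different consensus can be configured) and accepts the best window at
  ≥ 0.90 identity, ties leftmost.
* **Deduplication** trims each record to its SL start and collapses
  records matching a longer kept representative at ≥ 0.95 identity over
  the shared prefix, keeping the longest (deterministic: longest first,
  ties by id).
* **Relict chaining** is greedy 5'→3': from the end of the previous copy,
  start offsets 0..3 are examined; each 15-nt window is scored by
  IUPAC-aware ungapped identity against the truncated leader, and the best
  window ≥ the floor (0.50) is accepted, ties to the smallest offset. The
  offset slack absorbs the small insertions observed between real relict
  copies; identity is ungapped (alignment of 15-mers at ≤ 50% divergence
  rarely needs gaps, and ungapped scores are exactly reproducible).

**Null behaviour, measured.** Against a 15-nt concrete motif, a random
window matches with P(Binomial(15, 1/4) ≥ 8) ≈ 1.7%; over four nearly
independent offset windows the union is ≈ 6.6%. The chain scan on records
with no planted relict therefore ends with `k = 0` in ≈ 93–94% of cases
(measured 92.8% over 1000 simulated records), not more. The same effect
caps exact cascade-depth recovery on synthetic ESTs at ≈ 93% under the
default configuration, because every record's chain end faces that ≈ 6.6%
chance of one spurious extension; all observed recovery failures are
one-copy over-calls. Raising the floor or shrinking the offset slack would
suppress this at the cost of missing genuinely decayed copies; the
defaults favour sensitivity, as the original search (down to 50%
identity) did.

## Tandem arrays and repeat families

Arrays are detected by self-comparison at all lags (autocorrelation of
matches) rather than suffix-tree repeat finding — simple and exhaustively
testable at read scale (≤ 1.2 kb):

1. For every candidate period `p` (20–300 bp), positions where the
   sequence matches itself at lag `p` are smoothed over one unit length;
   windows with match fraction ≥ the divergent floor (0.85, chosen to
   admit the survey's 88–98%-identity copies with margin) mark a periodic
   region. The union over lags, split into maximal spans, gives candidate
   arrays without cross-period competition.
2. Each span's period is re-estimated inside the span as the smallest lag
   scoring within 0.02 of the best; the tolerance matters because on
   noisy arrays the score at twice the fundamental period fluctuates
   marginally above the fundamental, and a strict argmax reports doubled
   units. Exact arrays are unaffected.
3. The span is trimmed to the longest run of above-floor windows at that
   period (runs separated by < 2 units are merged first, so a divergent
   interior copy does not split an array), the unit consensus is taken by
   per-column majority over complete frames at the best phase (phase =
   smallest within 0.02 of the best mean adjacent-copy identity, so phase
   0 wins unless clearly worse; column ties alphabetical), and per-copy
   identities are computed against that consensus.
4. Spans whose unit is itself short-periodic (period ≤ 6 at ≥ 0.90) are
   discarded: they belong to the simple-repeat annotator.

`n_units` counts complete units (`floor(span/p)`); the fractional trailing
unit is reported separately and excluded from the fraction formula. Since
a read samples a random phase of a long array, this floors away on average
half a unit per read end — a ≈ 6% systematic undercount of family
fractions at the default unit (≈ 88 bp) and read lengths (300–1200 bp),
inside the ±10% band the recovery suite checks.

**Family grouping.** Unit consensus strings are first reduced to a
rotation- and strand-invariant canonical form; distinct canonical units
merge when a rotation-aware comparison finds a window covering ≥ 80% of
the shorter unit at ≥ 90% identity. Rotation-awareness is required because
reads sample arbitrary phases of an array. A consequence worth knowing:
survey repeats 3 and 4 are near-exact cyclic permutations of each other
(rotating one by 60 bp aligns the full 88 bp at 94% identity), so the
default generator's repeat-3 and repeat-4 reads typically land in one
family; the summed family fractions are unaffected.

**`shared_segment`** (the unit-vs-unit comparison exposed in the API)
deliberately uses *linear* offsets on both strands, not rotations, and
returns the longest window ≥ 80% identity. On the published units 3 and 4
this reproduces the printed answer — a 60-bp segment at 56/60 = 93% — 
whereas a rotation-aware search would report the full 88 bp at 94%.

**Fractions.** A family's share of the sample is
`100 × Σ (n_units × unit_length × n_reads) / total_bp`, summed over member
arrays, with `n_reads = 1` per read when arrays are annotated per read
(each read is its own "contig"); a contig→read-count map can be supplied
when arrays come from assembled contigs.

**In-silico digest** cuts at every occurrence of the recognition site on
either strand, with the cut placed at the site start — a documented
simplification: only the fragment-ladder periodicity matters for
diagnosing a tandem array (one cut per unit ⇒ a unit-length ladder).
Fragments always partition the sequence.

## Repetitiveness census

True assembly is replaced by greedy single-linkage overlap clustering:
membership counts, not consensus sequences, drive every downstream number.
The longest unclustered read seeds a cluster; any read sharing an ungapped
overlap ≥ `min_overlap` at ≥ `min_identity` (genomic defaults 100 bp /
0.90; EST mode 40 bp / 0.95 with ≤ 30 mismatches) with any member joins
transitively. Overlaps are found by exact 16-mer seeding on both strands;
shared seeds vote for diagonals and the full ungapped overlap at the
best-voted diagonals is evaluated. The procedure is deterministic and
invariant to input order (seed order: length descending, then id). The
original survey's assembler allowed gaps; the ungapped approximation is
documented, not claimed equivalent — at clone-end error rates the
qualifying overlaps are overwhelmingly ungapped.

Read classes: singleton → `unique`; ≥ 2 reads → `repetitive`; > 20 reads →
`highly_repetitive` (given ≈ 0.006% genome sampling, a cluster of two
already implies a sequence present at least twice genome-wide).

**Simple repeats** (units 1–6 bp) are runs where positions match the base
one unit earlier in local windows at ≥ 90%, with two safeguards: the run
must also match a single per-phase consensus unit at ≥ 90% (pure
lag-matching would chain heterogeneous homopolymer blocks, which match
themselves at every lag, into one bogus call), and window-local flagging
keeps a long run from creeping into flanking sequence on the strength of
its global match fraction. Overlapping calls resolve to the longer span
with boundary trimming; units are reported as the smallest period in
minimal rotation.

**Low complexity** merges sliding 64-bp windows whose mononucleotide
Shannon entropy falls below 1.5 bits; intervals are labelled by the
dominant base (`C-rich`) or, when no base clearly dominates, the top two
(`GA-rich`).

**Whole-read labelling.** The census counts full read lengths per feature
(the survey's own accounting, which double-counts multi-feature reads in
the "pie" view; the "actual" view divides by the true sample bp).
`read_feature_labels` applies two conventions when turning intervals into
read labels: intervals inside a detected tandem-array span are ignored
(a microsatellite-sized repeat inside a long repeat unit is part of the
array — the default units genuinely contain a perfect 12-bp hexamer
doublet at every copy junction), and an interval must reach 20 bp before
it labels a read, mirroring library annotators' minimum scores, since a
lone two-copy hexamer occurs freely in random sequence. The interval-level
APIs keep their 12-bp minimum-span contract.

Genome-size arithmetic: `size_bp = 0.921e9 × DNA_pg`;
`sample % = 100 × sample_bp / size_bp`.

## Coding statistics

Stop codons are read off directly given a reading-frame hint (first
in-frame TAA/TAG/TGA) or from the longest ATG-initiated ORF over forward
frames otherwise. Tables report counts and half-up percentages to one
decimal per set.

The polyA-upstream motif scan emulates the survey's negative result with
an exact, tool-free procedure: windows of 60 (or 30) bases immediately 5'
of each detected polyA are collected; every k-mer (k = 5..9) is scored by
the number of windows containing it at least once, against a
mononucleotide background (pooled window composition, independent
positions), with a one-sided binomial tail. Presence-per-window rather
than occurrence counts avoids the anti-conservative clumping of
self-overlapping motifs; Bonferroni correction runs over the *full* motif
family (Σ 4^k ≈ 349k tests), which keeps the replicate-level familywise
error at α — measured: 3 of 100 matched null replicates produced any hit
at α = 0.05, while a motif planted once per window in 200 windows is
flagged at adjusted p ≪ 10⁻¹⁰. The original survey's hidden-Markov-model
search is not reproduced; only the shared negative-result behaviour on
matched nulls is claimed.

## Synthetic data

The generators define the conditions every recovery suite runs under.

* **SL ESTs** — resolved consensus leader + relict copies for a cascade
  depth drawn from (0.74, 0.21, 0.04, 0.008, 0.002) for depths 0–4
  (echoing the observed cascade frequencies); copy *r* carries
  Binomial(15, r × rate) substitutions (default rate 5% per cycle —
  older copies more diverged, matching the observed 3'-ward decay);
  then a 150–400 bp tail at 53.1% GC (the EST-wide GC) and a 15–30 nt
  polyA. An option resamples reads from a smaller template set with
  per-base resequencing noise for deduplication tests.
* **GSS reads** — 300–1200 bp (uniform; a typical clone-end range),
  drawn from a mixture: the four survey repeat units at their published
  shares (14.79 / 11.15 / 3.75 / 28.11%), simple repeats 13%, low
  complexity 8%, unique background at 60% GC for the remainder. Tandem
  reads are fully tiled unit copies from a random phase, reverse
  complemented half the time; each copy is exact with probability 0.7 and
  otherwise diverged at Uniform(2–12%) — a major repeat type interspersed
  with 88–98%-identity copies. (Making *every* copy 2–12% divergent would
  push read-to-read overlap identity to ≈ 0.87 and defeat 90%-identity
  clustering, inconsistent with the survey's own assembly succeeding.)
  Simple-repeat reads tile one unit — CACG/CATG/CGTG weighted per the
  published abundances, plus CAG — over 60–90% of the read; low-complexity
  reads are i.i.d. draws from GA-rich, GC-rich or C-rich compositions
  weighted like the published prevalences.
* **CDS sets** — a 0–2 nt 5' UTR (shorter than a codon, so no spurious
  upstream in-frame stop), ATG, 50–200 non-stop codons with third
  positions G/C with probability `gc3` (default 0.7, echoing the strong
  GC3 bias), a stop drawn from (0.072, 0.165, 0.763) for (TAA, TAG, TGA),
  a 3' UTR of at least one motif-scan window (60–120 nt) so the
  polyA-proximal window is free of coding signal, and a polyA tail.

Every record draws from its own child of `numpy.random.SeedSequence(seed)`,
so record *i* is byte-identical regardless of how many records are
requested, and a seed fully determines all outputs.

**What the generators do not emulate** — and hence what passing recovery
suites do not show about real data: base-call quality and chromatogram
artefacts, vector contamination, hydroxymethyluracil and other modified
bases, genuine gene content and transposable elements (census categories
for those are pass-through labels only), gapped divergence (indels) within
repeat copies, and any correlation structure between features on one read.

## Problem sizes and runtimes

The recovery suites run at the sizes their conditions state: 500 ESTs for
cascade-depth recovery, a 2,000-read sample for family-fraction recovery
(≈ 25 s), 1,000 CDS for the stop-codon table, 100 replicates × 200 windows
for the motif-scan null (≈ 30 s). The default end-to-end pipeline (300
ESTs, 400 reads, 200 CDS) completes in ≈ 10 s on one CPU.

## Known limitations

* Ungapped identity throughout; gapped divergence shortens detected spans
  rather than being absorbed.
* The chain scan's ≈ 6.6% per-record spurious-extension rate at the
  default floor/offsets (analysed above) is inherent to scanning a 15-nt
  motif down to 50% identity.
* Family grouping can merge repeat families that are cyclic permutations
  of one another (by construction it must); per-family fractions are then
  reported for the merged family.
* Overlap clustering evaluates full-diagonal overlaps: reads that overlap
  only via a short terminal window inside a longer conflicting alignment
  are not joined.
* The census assigns whole reads to features (the survey's accounting);
  interval-level bp is available from the annotators directly.
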
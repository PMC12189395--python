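# Methods

## Background and model

DNBSEQ (MGI) flow cells carry DNA nanoballs at fixed sites; read names are
transparent about geometry: each name carries a camera field-of-view token
(`CxxRxx`) and an ordinal read identifier assigned by position within the
FOV, so physically neighbouring nanoballs receive nearby ordinals.
Demultiplexing uses a separately sequenced 10-base barcode fragment, not
the insert reads themselves. Two artifact families follow from occasional
incorrect resolution of signals from neighbouring nanoballs:

* **misdemultiplexing / improper pairing** — a read pair is assigned to
  one sample while a read inside the pair physically carries another
  sample's barcode, or the forward and reverse reads derive from
  different source fragments;
* **optical duplicates** — the same nanoball's signal is emitted as two
  near-identical reads whose ordinals differ by a small characteristic
  offset (dominant mode 1; minor modes 63, 85, 195, 217 representing
  farther neighbourhood orders).

Both are observable directly in FASTQ. When the insert `l` is shorter
than the read length `R`, the read runs through into technical sequence:
the partial left adapter (`CCAAGCGGTCTTAGGAAGACAA` in forward reads,
`CGTTCTGTGAGCCAAGGAGTTG` in reverse reads) followed by the barcode. The
audit therefore conditions on short inserts: the 10-mer immediately right
of an exact adapter occurrence is the barcode the nanoball actually
carries, and exact-matching it against the run's whitelist yields the
misdemultiplexing rate

    rate = (whitelist matches != target) / (all whitelist matches).

Off-whitelist 10-mers (sequencing errors, filler) are excluded from the
denominator; a zero denominator yields an undefined (NA) rate, not 0.

### Adapter length and the visibility thresholds

The full left adapter on this platform is longer (about 42 bases) than
the 22-base fragment printed above, but every detection step keys only on
the printed 22-mer. The generator therefore emulates exactly the
detectable technical sequence — insert + 22-mer + barcode — giving the
clean arithmetic used throughout:

* adapter visible (CA group)  ⇔ `l <= R - 22` (278 at PE300);
* barcode fully visible       ⇔ `l <= R - 32` (268 at PE300).

An `adapter_pad_f/_r` option prepends extra adapter bases for realism
experiments; the thresholds then shift by the pad length.

## Synthetic run generator

The generator produces truth-labelled paired-end runs under a single
seeded RNG stream (draw order: defaulted barcode panel, defaulted
references; then per FOV and per pair: insert length, class selector,
class-specific draws, filler, substitution noise; then the FOV's
duplicate conversions). Identical configs are byte-reproducible.

Defaults (the study conditions):

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 50,000 | full-size desk run; analyses finish in seconds–minutes |
| `read_length` | 300 | PE300, the option where read-through is most visible |
| insert model | normal(460, 150) truncated to [50, 600] | libraries shorter than the recommended 2R, leaving ~10% of inserts barcode-visible |
| `misdemux_rate` | 0.05 | a strongly affected barcode (per-barcode rates of a few percent) |
| `misdemux_reverse_fraction` | 0.2 | reproduces the ~5-fold forward/reverse asymmetry |
| `improper_pair_rate` | 0.02 | few-percent improper pairing |
| `duplicate_rate` | 0.02 | ~2% optical duplicates |
| offset weights | {1: .80, 63/85/195/217: .05 each} | dominant nearest-neighbour mode plus four minor modes |
| `chimera_rate` | 0.001 | chimeras are extremely rare |
| `substitution_error_rate` | 0.001 | low post-filter substitution noise |
| `n_fovs` | 50 | the number of FOVs analysed per run |
| references | two random 250 kb sequences (`target`, `contaminant`) | see "source complexity" below |

Class semantics: *misdemux* pairs keep one fragment but carry a uniformly
chosen non-target panel barcode in the forward read (and, with
probability `misdemux_reverse_fraction`, the same wrong barcode in the
reverse); *improper* pairs combine a forward read from a contaminant
fragment (with a non-target barcode) with a reverse read from a target
fragment; *duplicates* are planted by converting a clean pair into a
noised copy of an earlier same-FOV pair at an offset drawn from the
weights (each source used at most once, so planted offsets are exactly
the histogram support); *chimeras* concatenate two half-inserts from
different sources inside one read. Classes are mutually exclusive per
pair; `truth_rates` reports realized fractions.

Two optional couplings model what real runs show: `improper_short_enrichment`
multiplies the improper-pair probability for barcode-visible inserts
(short inserts are more artifact-prone), and `duplicate_artifact_bias`
weights artifact pairs when choosing duplicate sources (signal mix-ups
and duplicates share the neighbourhood cause).

**Source complexity.** A real flow-cell pool draws from sources complex
enough that two unrelated same-FOV reads are essentially never ≥95%
identical over their full length; a desk-scale random reference would
produce such coincidences by overlapping fragment draws. The generator
therefore keeps fragment endpoints within one FOV at least 32 bases
apart (reads from fragments offset by `d` align at identity about
`(L-d)/(L+d)`, so separation ≥16 already stays safely below the 95% call
line); when a reference is too crowded to satisfy this the constraint
degrades gracefully to an unconstrained draw.

What the generator does **not** emulate: rolling-circle amplification
chemistry, signal intensities, realistic quality strings (qualities are
constant `I`; no analysis uses them), PCR duplicates (the library
preparation has no classical PCR step), indel sequencing errors, or
genomic repeat structure. Passing tests therefore demonstrate correctness
of the audit logic under substitution-type noise and unique-ish source
sequence — not performance on repeat-rich genomes, where coincidental
high-identity read pairs are possible and the duplicate scan would count
them.

## Duplicate scanning

Reads are bucketed by FOV key (lane, column, row) and sorted by ordinal.
A pair of reads is a duplicate when the end-to-end (Needleman–Wunsch, via
edlib) alignment has identity ≥95% — matched columns over all columns —
and alignment length ≥ the read length. Zero ordinal differences are
skipped.

* **all-to-all**: frames of 1000 consecutive reads sliding by 500; every
  unordered pair sharing a frame is tested exactly once (the frame
  iteration skips pairs already covered by the previous overlapping
  frame, so nothing is double-counted). A vectorised Hamming pre-screen
  discards equal-length pairs with more than 35% positional mismatches
  before the alignment; this is exact for substitution-type divergence
  (Hamming ≥ edit distance), and only an indel-shifted near-identical
  pair — which the platform's duplicates do not exhibit — could be
  screened away. Survivors get a bounded-distance edlib check and then
  the exact alignment.
* **fast**: only pairs whose within-FOV ordinal difference lies in
  {1, 2, 61–65, 83–87, 193–197, 215–219} (each mode widened by its
  observed spread) are tested, with identical hit criteria. Because reads
  are ordinal-sorted, index distance never exceeds ordinal distance, so
  every fast-tested pair is also all-to-all-tested: fast hits are a
  subset by construction.

The optical-duplicate rate counts each read once however many partners
it has: reads-with-duplicates / reads-processed.

## Insert estimation and pair classification

The overlap merger scans all innie placements of the forward read against
the reverse-complemented reverse read (including engulfed/read-through
placements, where the insert is shorter than the read), scoring each
overlap by mismatch ratio; minimal ratio wins, ties go to the longest
overlap, and the scan visits placements in decreasing overlap order so a
perfect overlap terminates early. A merge requires overlap ≥10 and
mismatch ratio ≤0.25 (the conventional merge-tool defaults). The insert
equals `lenF + lenR − overlap` for standard innie placements and the
overlap-region length for engulfed ones; inserts above `2R − 10` are
genuinely unmergeable (overlap below the minimum) and stay unmerged.

The mapper is a minimal k-mer seed-and-extend: 15-mers sampled across the
read vote for (reference, diagonal) placements on both strands; the best
diagonals are extended ungapped, taking the maximum-scoring local segment
(match +1, mismatch −2) so technical tails are soft-clipped; a read maps
if segment identity ≥0.90 over ≥50% of the read. Only the mapper's
decisions (mapped? to which labelled reference? which strand?) feed the
classification. Reads whose genuine part covers less than half the read
(inserts under ~R/2 at the default coverage) go unmapped — a known,
accepted difference from a full soft-clipping aligner.

Four-case classification (short = forward contains the adapter; barcode
"incorrect" means an exact match to a non-target whitelist barcode —
unextractable or off-whitelist 10-mers are never evidence):

1. **case1** short, mates do not merge, forward barcode incorrect —
   improperly paired, short insert;
2. **case2** short, mates fully merge, both barcodes incorrect —
   properly paired but misdemultiplexed;
3. **case3** long, mates do not merge, forward does not map to the
   target reference while the reverse maps — improperly paired, long
   insert;
4. **case4** long, merged, both mates consistent with one non-target
   reference — labelled `case4_excluded` and never counted as a device
   artifact, because it cannot be told apart from physical
   cross-contamination.

Everything else is `proper` (merged short pairs with target barcode;
long pairs that merge or map consistently to the target) or
`unclassified`. The recommended preprocessing filter simply discards
every pair whose forward read contains the 22-mer adapter; it is exact
with respect to that predicate, order-preserving and idempotent.

## Association statistics

Selected-vs-baseline neighbourhood enrichment is a 2×2 contingency:
Pearson chi-square (1 df, no continuity correction, no multiple-testing
adjustment) with the upper-tail p-value; p-values below the representable
range render as "< 1e-300". Two effect sizes are always reported and
labelled apart: the **rate ratio** (ratio of the two proportions) and
the textbook cross-product **odds ratio** — on published per-group
proportions it is the proportion ratio that reproduces the printed
effect sizes. The baseline is the full pool, so selecting the whole pool
gives a rate ratio of exactly 1.

Two indicator modes: *case13* — the pair's reverse read appears in a
duplicate hit from a scan over the same pool's reverse reads; *case2* —
some same-pool read sits in the same FOV at an ordinal offset from the
fast-scan set.

A planting caveat: duplicate *recipients* are always clean pairs, so
under unbiased planting artifact pairs can only be flagged as duplicate
*sources*, and their null flag probability is roughly half the pool's
(rate ratio ≈ 0.65, not 1). The association tests therefore validate
against the truth-table-derived oracle (exact agreement of the 2×2
counts) and against detection of deliberately biased planting, rather
than asserting a null ratio of 1.

## Numerical choices and degenerate inputs

* Exact matching for adapter and barcode throughout (the audit's defining
  convention); the first adapter occurrence is used when several occur.
* Barcode-inference ties break lexicographically (ties do not occur in
  practice; determinism requires a rule).
* All coordinates 0-based half-open; mapping positions are the leftmost
  aligned base on the reference forward strand.
* Empty observation → inference error; zero scan pool or zero 2×2 margin
  → explicit errors rather than NaN propagation.
* Duplicate planting falls back to "none" when no valid in-FOV source
  exists after 100 offset resamples; a configuration whose smallest
  offset exceeds the FOV size is rejected outright.

## Problem sizes

The default analyses and the acceptance script use 50,000 pairs across
50 FOVs (≈1000 reads per FOV, matching one all-to-all frame per FOV);
unit tests use 400–20,000 pairs. At these sizes a full pipeline pass —
generation, both scans, both misdemultiplexing audits and the
classification of the adapter-containing subset — takes well under a
minute on one core.

## Known limitations

* The scanner's Hamming pre-screen and the generator's substitution-only
  noise mean indel-type duplicate divergence is untested (and unobserved
  on the platform).
* The k-mer mapper is not a general aligner: no gapped extension, no
  mapping-quality model; short inserts (<~R/2) go unmapped where a
  soft-clipping aligner would map them, which inflates the CA group's
  unmapped percentage relative to a production mapper.
* Misdemultiplexing estimates condition on barcode-visible (short-insert)
  pairs; as in the real protocol, nothing can be said about reads whose
  inserts are too long to expose technical sequence.
* The chimera class is generated (for robustness testing) but no chimera
  detector is provided; chimeric structure is too fluid for formal rules.
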
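# Methods

This note documents the models, parameters and numerical choices behind
`hemitect`, and what its synthetic-data tests do and do not demonstrate.

## Library model

A hemi-specific TGS amplicon is modeled as the TE 3'-terminal prefix
(`prefix_len` nt, derived from the nested-primer start: 52 nt for the
bundled P-element-style layout) followed by flanking genomic sequence out to
a degenerate-primer binding site, with total length in
[`amplicon_min`, `amplicon_max`] = [300, 500] bp (the gel-isolated size
range). Read-1 is the first `read_len` = 150 nt of the amplicon, read-2 the
reverse complement of its last 150 nt; adapters are not emitted because
amplicons (≥ 300 nt) always exceed the read length. Primer binding is exact:
an amplicon ends wherever the reverse complement of a primer pentamer
occurs on the flank in read orientation; the five fully degenerate N bases
of a real primer are assumed to always bind. This is the simplest model
consistent with a primer panel designed to recognise many chromosomal
sites; it ignores annealing mismatches and thermodynamics, which is why the
number of primers supporting a simulated insertion (typically 1–6 of 15) is
lower and noisier than in deep real libraries. Tests that need a minimum
per-insertion yield therefore select plantable sites with at least one
primer site (`pick_insertion_sites`), which mirrors the fact that only
amplifiable insertions are observable by this assay at all.

Errors are independent per-base substitutions at
`sub_rate_polymerase + sub_rate_sequencer` = 0.003% + 0.8% = 0.803%, the
Taq and MiSeq rates relevant to this library chemistry; indel errors and
quality-score decay are not modeled (qualities are constant Q40). WGS
fragments are drawn from the inserted haplotype with probability `freq`,
with Normal(300, 50) fragment lengths truncated at `2·read_len`, 100-nt
mates, and a 0.1% substitution rate.

The bundled consensus (`simulate.synthetic_consensus`) is a deterministic
random 2907-nt sequence — a synthetic stand-in carrying the real landmark
coordinates (enrich primer 2752–2774, nested primer 2856–2877). Every
pipeline property exercised here depends on length and landmarks only, not
on the actual P-element sequence; runs on real data should supply the real
consensus FASTA. The 15 default pentamers are likewise synthetic stand-ins
for a genome-derived common-pentamer panel.

## Read classification

The classifier solves an anchored alignment problem: the alignment must
start at read-1's first base (the nested primer is sequenced first) and
reach the consensus's final base (amplicons run through the TE end). Under
the caps — at most one mismatch and one gap — the optimum is found exactly
by enumerating the three alignment shapes (gapless, one interior read
insertion, one interior read deletion) over all prefix lengths, using
cumulative mismatch counts per diagonal; alignments are ranked by score
(match +1, mismatch −1, gap −2), which reproduces what a local aligner
would report while the caps are enforced exactly rather than heuristically.
Terminal gaps are disallowed so the alignment can never consume genomic
bases past the consensus terminus; only single-base gaps are modeled (the
published cap). The keep rule is strict: more than `min_len` = 20 read
bases must be aligned, so 21 is the smallest kept match. A mismatch/gap
budget read as "≤ 1 each, jointly" was chosen over "one or the other".
Correctness is checked against an exhaustive alignment-path enumeration
oracle on short windows.

At the default error rate about 6.6% of true TE reads carry ≥ 2 substitutions
inside the 52-nt prefix and are rejected, so simulated libraries classify
~93.4% of pairs as TE-derived; the suite asserts the > 93% property on a
20 000-pair library.

Trimming removes the measured TE prefix from read-1, then adapter
occurrences (full internal match or a ≥ 3-nt read-suffix/adapter-prefix
overlap), then trailing bases below Q20 (no published cutoff exists; Q20 is
the common default). Trimming is idempotent.

## Alignment and pair classes

The bundled aligner is for desk-scale references only: an exact 20-mer
index over the plus strand, tiled query seeds on both strands, and edlib
(banded edit distance, infix mode with ±5 padding) to score each candidate
placement end-to-end. All equal-best hits are reported (`NH` tag), so
"uniquely aligned" means exactly one equal-best hit; suboptimal secondaries
do not break uniqueness. MAPQ is 42 for unique hits and 0 otherwise —
deliberately coarse, since downstream rules only ever threshold MAPQ.
Placements beyond 10% edits are discarded. Production runs can substitute
any SAM-producing aligner; the pipeline consumes SAM and never shells out.

A pair is *unique-concordant* when both mates have single hits on one
chromosome in facing (FR) orientation with outer fragment span — leftmost
to rightmost inclusive — of at most 500 bp (inclusive at 500). Any mate
with multiple equal-best hits makes the pair *multi*; a hitless mate makes
it *unaligned*; the remainder are *discordant*.

`local_align` is an exact Smith–Waterman (linear gap penalty) with a
deterministic tie-break: among maximal cells, smallest target end then
smallest query end, with diagonal-preferring traceback. N never matches
anything, including N.

## Breakpoint calls, clustering, tiers

With TSD length `tsd_len` (default 8) and breakpoint defined as the TSD's
3' end on the plus strand: plus-strand read-1 gives
`b = leftmost + tsd_len − 1`; minus-strand read-1 gives `b = rightmost`.
The offset is always derived from `tsd_len`, never hard-coded, so the tool
generalises to TEs with other TSD lengths.

Clustering is per (chromosome, orientation) — a 3'-only primer design
amplifies an insertion from one side only, so opposite-strand calls are
never merged. The modal breakpoint (ties to the smaller coordinate) seeds
each cluster and absorbs calls within ±`merge_window` = 3 bp; real
amplicons from one insertion share a junction exactly, so the window exists
only to absorb rare indel-error jitter, and the choice is conservative and
configurable. Tiers: ≥ 20 pairs (inclusive) ⇒ annotated; ≥ 100 pairs *and*
≥ 4 primer libraries ⇒ high-confidence. The filter upgrades, never deletes.
RPM is computed per source library against that library's total sequenced
pairs and summed, making it invariant under uniform duplication of a
library.

## Contigs and rescue

A contig is upstream-flank + oriented consensus + downstream-flank, where
each 500-bp flank *contains* one TSD copy (total length 2·500 + 2907 =
3907). Rescue aligns each multimapping mate to every contig with edlib and
accepts ≤ 5 mismatches and ≤ 2 gap openings, a gap of any length counting
once against the gap budget (the caps leave gap-length accounting open;
per-opening is the lenient reading). Single-mate evidence suffices — the
amplicon structure guarantees mate-1 derives from the insertion whenever
mate-2 does.

## Cross-mapping screen

Substitution errors (~0.8%/base) can relocate a small fraction of a true
insertion's reads onto similar sequence elsewhere, creating a spurious
annotation supported at roughly the error rate times the true support. The
screen aligns 800-bp windows (400 bp per side of each breakpoint) for all
annotation pairs on both strands; identity is matches / alignment columns
with gaps counting as non-matches. Reporting floor: identity ≥ 0.80 over
≥ 80 columns; within a reported pair the lower-support member is flagged
iff its support is < 1% of its partner's. These floors generalise the
observed artifact regime (≈ 84–94% identity over 83–446 bp, support ratios
< 1%) and are configurable. Flagged annotations are reported, never
removed — demotion is left to the analyst.

## WGS frequency estimation

WGS pairs are aligned to a hybrid reference (genome chromosomes + contig
records). Alignments with MAPQ ≤ 10 are discarded — with the bundled
aligner this removes exactly the flank-only reads that fit genome and
contig equally well, implementing "significantly better alignment to one
allele" as best-unique-placement. A retained pair supports the insertion if
a mate's contig alignment covers ≥ `span_margin` = 5 bases on both sides of
either junction, and the reference if a genome alignment covers the
breakpoint the same way; `freq = n_ins / (n_ins + n_ref)`, reported as
missing when no pair is informative. The margin (no published value exists)
is set to 5 because a 1-base rule is fragile to soft-clipping at junctions.

Two geometric facts make the raw proportion a biased estimator of the
haplotype frequency at intermediate frequencies: a contig exposes two
junctions while the reference exposes one breakpoint, and the 8-bp TSD
makes reference reads that do not span the entire duplication ambiguous
(they are removed by the MAPQ filter rather than guessed). At the fixed
(freq ≈ 1) insertions this assay targets, the bias vanishes — `n_ref = 0`
gives exactly 1.0. Tests therefore validate the estimator against the
truth-fragment ratio computed under the same junction-spanning rules, not
against the planted haplotype frequency.

`permutation_median_test` is a two-sided paired sign-flip test on
`median(x − y)`: exact enumeration of all 2ⁿ sign vectors when 2ⁿ ≤ n_perm
(p = hits/2ⁿ), otherwise `n_perm` sampled flips with the add-one estimate
(hits+1)/(n_perm+1); comparisons use a 1e-12 absolute tolerance so exact
ties count as hits.

## Problem sizes used in the suite

Test simulations use 12–200-kb genomes, 1–10 planted insertions with ≥ 20
pairs each, five seeds for the error-rate recovery check, and WGS at 100×
on a 12-kb single-insertion genome at frequencies 0.1/0.5/0.9/1.0 × 3
seeds; the whole suite runs in about a minute on one core. These sizes give
the truth-recovery and interval checks comfortable counting statistics
while keeping the bundled aligner (dictionary k-mer index, per-candidate
edlib) in its intended desk-scale regime.

## Known limitations

* Tail-to-tail element pairs are invisible by construction (3'-only
  priming yields TE-only "flanks"); the simulator has a planting mode that
  reproduces this false-negative class and the suite asserts it.
* The simulator omits PCR duplicates, chimeras (beyond tail-to-tail),
  primer-efficiency variation, indel sequencing errors and quality decay;
  passing tests show pipeline correctness under the stated read
  architecture and substitution-error model, not robustness to every
  artifact of real libraries.
* The bundled aligner is not a production aligner: no FM-index, no spliced
  alignment, O(genome) memory; use bowtie2/bwa SAM for real genomes.
* Internally deleted TE variants are not modeled; contigs always carry the
  full-length consensus.
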
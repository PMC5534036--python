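# hemitect

Transposable-element (TE) insertion calling from **hemi-specific PCR
targeted genome sequencing (TGS)**, with contig-based estimation of
insertion frequencies from whole-genome sequencing (WGS) data.

## The problem

TE insertion sites are highly polymorphic within species, and annotating
them from WGS alone is hard: polymorphic insertions are supported by few
reads, and insertions in repeat-rich heterochromatin rarely attract uniquely
mapping reads at all. Hemi-specific PCR sidesteps this by pairing a primer
anchored in the TE 3' terminus (for the *Drosophila melanogaster* P-element,
a 2907-nt DNA transposon) with a panel of degenerate reverse primers, so
that each sequencing library contains amplicons spanning a TE 3' end and its
unknown flanking sequence at very high depth. `hemitect` implements the
computational half of this design for anyone analysing such libraries: it
classifies TE-derived read pairs, calls precise insertion breakpoints from
split reads, filters by read and primer support, reconstructs inserted-allele
contigs, screens for cross-mapping artifacts, and estimates per-insertion
population frequencies from WGS pairs aligned concurrently to the genome and
the contigs. A fully deterministic simulator generates libraries and WGS
pairs with known truth, so the whole pipeline is testable without external
data.

## The method

Read-1 of every hemi-specific pair is a *split read*: it begins with a
fixed-length TE 3'-terminal prefix (52 nt under the bundled nested-primer
layout, positions 2856–2907 of 2907) followed by genomic flank. The stages
are:

1. **Classify/trim** — read-1 is aligned, doubly anchored (read start,
   consensus 3' terminus), against the consensus 3' end; a pair is kept when
   the alignment is longer than 20 nt with ≤ 1 mismatch and ≤ 1 gap. The TE
   prefix, adapters and low-quality tails are trimmed.
2. **Align + pair classes** — trimmed pairs are aligned end-to-end
   (bundled seed-and-extend aligner for desk-scale references, or any SAM
   producer) and partitioned into unique-concordant (FR orientation, outer
   span ≤ 500 bp), multi, discordant, unaligned.
3. **Breakpoint calling** — transposition creates an 8-bp target-site
   duplication (TSD); the breakpoint *b* is the TSD's 3' end on the plus
   strand. For read-1 on the plus strand, `b = leftmost + (tsd_len − 1)`
   (the "+7" rule); on the minus strand, `b = rightmost`.
4. **Clustering + tiers** — calls cluster around the modal breakpoint
   (±3 bp); ≥ 20 unique-concordant pairs ⇒ *annotated*; ≥ 100 pairs from
   ≥ 4 degenerate primers ⇒ *high-confidence*. Support is also reported as
   reads-per-million (RPM) per library.
5. **Contigs + rescue** — each annotation yields a putative inserted-allele
   contig: 500 bp upstream flank ending in the TSD, the oriented consensus,
   500 bp downstream flank beginning with the TSD. Multimapping pairs are
   rescued by alignment to the contig set (≤ 5 mismatches, ≤ 2 gaps).
6. **Cross-mapping screen** — 800-bp windows around all breakpoint pairs
   are locally aligned; highly similar pairs whose support ratio is < 1%
   mark the low-support member as a likely substitution-driven artifact.
7. **WGS frequency** — WGS pairs are aligned to genome + contigs; after a
   strict MAPQ > 10 filter, a pair supports the insertion if it spans a
   contig junction and the reference if it spans the breakpoint, each by
   ≥ 5 bp on both sides. The frequency is
   `f = n_ins / (n_ins + n_ref)`. A paired sign-flip permutation test on
   `median(f_A − f_B)` (exact when 2ⁿ ≤ n_perm) compares estimate sets.

The published P-element consensus is not redistributed; the package bundles
a deterministic **synthetic** 2907-nt stand-in with the real primer-landmark
coordinates, which preserves every positional property of the pipeline.

## Worked example

Simulate a 120-kb genome with three planted insertions and run the full
pipeline:

```sh
hemitect simulate --genome-length 120000 --n-insertions 3 --seed 11 --out-dir demo
# -> wrote 330 pairs to demo
hemitect run-all --config demo.yaml   # genome/consensus/libraries from demo/
cat demo/out/annotations.tsv
```

```text
chrom	breakpoint_1based	orientation	read_pairs	rpm	n_primers	tier
chr_sim	59918	+	80	2666666.666666667	3	annotated
chr_sim	103832	-	140	2800000.0	4	high_confidence
chr_sim	118850	+	83	1833333.3333333333	3	annotated
```

The simulator's truth table (`demo/truth.tsv`) lists planted breakpoints
59918/+, 103832/− and 118850/+ — all three are recovered at the exact
coordinate and orientation. `read_pairs` is unique-concordant split-read
support, `rpm` the summed per-library reads-per-million, and `n_primers` the
number of degenerate-primer libraries contributing evidence; the insertion
supported by ≥ 4 primers and ≥ 100 pairs is promoted to `high_confidence`.
`run-all` also writes contigs, a multimapper-rescue table, a cross-mapping
screen report and a JSON run summary, and accepts a `wgs:` entry to add
frequency estimation.

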
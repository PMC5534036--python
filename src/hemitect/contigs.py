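"""Putative inserted-allele contigs and multimapper rescue.

A contig reconstructs the inserted allele around one annotated breakpoint
``b`` (TSD start ``t = b - tsd_len + 1``): 500 bp of upstream flank ending
in the TSD, the oriented TE consensus, then 500 bp of downstream flank
beginning with the TSD — the duplicated target site therefore appears once
on each side of the TE, *inside* each 500-bp flank.  Reads that align to the
reference in multiple places can then be rescued by alignment to the contig
set, which measures how much of the multimapping signal is explained by the
annotated insertions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib

from .insertion_caller import InsertionAnnotation
from .io_formats import Genome, ReadPairRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass
class InsertionContig:
    name: str
    seq: str
    junction5: int  # 1-based contig coordinate of the last flank base before the TE
    junction3: int  # 1-based contig coordinate of the first flank base after the TE
    tsd_seq: str
    annotation: InsertionAnnotation | None = None
    truncated5: bool = False
    truncated3: bool = False


def build_contig(
    genome: Genome,
    annotation: InsertionAnnotation,
    consensus_seq: str,
    flank: int = 500,
    tsd_len: int = 8,
) -> InsertionContig:
    """Build the inserted-allele contig for one annotation.

    With breakpoint ``b`` and TSD start ``t = b - tsd_len + 1``: upstream
    flank ``genome[b-flank+1 .. b]``, then the consensus (reverse-complemented
    for '-' orientation), then downstream flank ``genome[t .. t+flank-1]``.
    Flanks truncated at chromosome ends are flagged.
    """
    b = annotation.breakpoint
    t = b - tsd_len + 1
    clen = genome.length(annotation.chrom)
    up_start = b - flank + 1
    truncated5 = up_start < 1
    if truncated5:
        logger.warning("contig %s: upstream flank truncated", annotation.name)
        up_start = 1
    down_end = t + flank - 1
    truncated3 = down_end > clen
    if truncated3:
        logger.warning("contig %s: downstream flank truncated", annotation.name)
        down_end = clen
    upstream = genome.fetch(annotation.chrom, up_start, b)
    downstream = genome.fetch(annotation.chrom, t, down_end)
    te = consensus_seq if annotation.orientation == "+" else revcomp(consensus_seq)
    seq = upstream + te + downstream
    junction5 = len(upstream)
    junction3 = junction5 + len(te) + 1
    return InsertionContig(
        name=annotation.name,
        seq=seq,
        junction5=junction5,
        junction3=junction3,
        tsd_seq=genome.fetch(annotation.chrom, t, b),
        annotation=annotation,
        truncated5=truncated5,
        truncated3=truncated3,
    )


def build_contigs(genome, annotations, consensus_seq, flank=500, tsd_len=8):
    return [
        build_contig(genome, a, consensus_seq, flank=flank, tsd_len=tsd_len)
        for a in annotations
    ]


def write_contigs(contigs: list[InsertionContig], path) -> None:
    from .io_formats import write_fasta

    write_fasta({c.name: c.seq for c in contigs}, path)


# ---------------------------------------------------------------------------
# Multimapper rescue
# ---------------------------------------------------------------------------


def _within_caps(query: str, target: str, max_mismatch: int, max_gaps: int) -> bool:
    """True when ``query`` aligns end-to-end somewhere in ``target`` with at
    most ``max_mismatch`` substitutions and ``max_gaps`` gap openings (a gap
    of any length counts once)."""
    res = edlib.align(
        query, target, mode="HW", task="path", k=max_mismatch + 4 * max_gaps
    )
    if res["editDistance"] < 0:
        return False
    cigar = res["cigar"] or ""
    gap_bases = gap_opens = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "ID":
                gap_bases += int(num)
                gap_opens += 1
            num = ""
    mismatches = res["editDistance"] - gap_bases
    return mismatches <= max_mismatch and gap_opens <= max_gaps


def mate_explained_by_contigs(
    seq: str, contigs: list[InsertionContig], max_mismatch: int = 5, max_gaps: int = 2
) -> bool:
    for contig in contigs:
        for oriented in (seq, revcomp(seq)):
            if _within_caps(oriented, contig.seq, max_mismatch, max_gaps):
                return True
    return False


@dataclass
class RescueSummary:
    library_id: str
    n_multi: int
    n_explained: int

    @property
    def fraction(self) -> float | None:
        """Explained fraction, or ``None`` when the library had no
        multimapping pairs (never 0/0)."""
        if self.n_multi == 0:
            return None
        return self.n_explained / self.n_multi


def rescue_multimappers(
    multi_pairs_by_library: dict[str, list[ReadPairRecord]],
    contigs: list[InsertionContig],
    max_mismatch: int = 5,
    max_gaps: int = 2,
) -> dict[str, RescueSummary]:
    """Align multiply-mapping pairs to the contig set, per library.

    A pair counts as *explained* when either mate aligns end-to-end to at
    least one contig within the mismatch/gap caps (up to 5 mismatches and
    2 gaps at the published settings).
    """
    if not contigs:
        raise ValueError("rescue_multimappers requires a non-empty contig set")
    out: dict[str, RescueSummary] = {}
    for lib, pairs in multi_pairs_by_library.items():
        n_explained = 0
        for pair in pairs:
            if mate_explained_by_contigs(
                pair.seq1, contigs, max_mismatch, max_gaps
            ) or mate_explained_by_contigs(
                pair.seq2, contigs, max_mismatch, max_gaps
            ):
                n_explained += 1
        out[lib] = RescueSummary(lib, n_multi=len(pairs), n_explained=n_explained)
    return out
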
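"""Standard-format I/O and the package's on-disk report dialects.

Coordinate conventions
----------------------
All genomic coordinates held in memory are **1-based inclusive**.  BED export
is 0-based half-open (a breakpoint at 1-based position ``b`` becomes the
interval ``[b-1, b)``).  SAM positions are converted to 1-based
leftmost/rightmost on ingest using the reference-consumed CIGAR length.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named chromosome sequences (uppercase A/C/G/T/N).

    ``fetch`` uses 1-based inclusive coordinates, the convention used for all
    position arithmetic in this package.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"invalid bases {sorted(bad)} in {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        if start < 1 or end > len(self.sequences[chrom]) or start > end:
            raise ValueError(f"bad range {chrom}:{start}-{end}")
        return self.sequences[chrom][start - 1 : end]


@dataclass
class ReadPairRecord:
    """One paired-end read with its source degenerate-primer library."""

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    library_id: str = ""

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"seq/qual length mismatch for {self.read_id!r}")


@dataclass
class AlignmentRecord:
    """One reported alignment of one mate, with 1-based inclusive span."""

    read_id: str
    mate: int  # 1 or 2
    chrom: str | None
    pos_leftmost: int  # 1-based
    pos_rightmost: int  # 1-based inclusive
    strand: str  # '+' or '-'
    mapq: int
    cigar: str
    n_hits: int = 1
    is_unaligned: bool = False
    missing_mate: bool = False
    edit_distance: int = 0


def read_fasta(path: str | os.PathLike) -> Genome:
    """Load a FASTA file into a :class:`Genome`; mixed case is uppercased.

    Raises on duplicate record names and on empty files.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(genome: Genome | dict[str, str], path: str | os.PathLike) -> None:
    seqs = genome.sequences if isinstance(genome, Genome) else genome
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq_pair(
    path1: str | os.PathLike, path2: str | os.PathLike, library_id: str = ""
) -> Iterator[ReadPairRecord]:
    """Iterate mate-synchronised records from two phred+33 FASTQ files."""
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2, strict=True):
        yield ReadPairRecord(
            read_id=r1.id,
            seq1=str(r1.seq).upper(),
            seq2=str(r2.seq).upper(),
            qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
            qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            library_id=library_id,
        )


def write_fastq_pair(
    pairs: Iterable[ReadPairRecord], path1: str | os.PathLike, path2: str | os.PathLike
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string (M/D/N/=/X)."""
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in _REF_CONSUMING:
                span += int(num)
            num = ""
    return span


def _record_from_pysam(aln: pysam.AlignedSegment) -> AlignmentRecord:
    mate = 2 if aln.is_read2 else 1
    if aln.is_unmapped:
        return AlignmentRecord(
            read_id=aln.query_name,
            mate=mate,
            chrom=None,
            pos_leftmost=0,
            pos_rightmost=0,
            strand="+",
            mapq=0,
            cigar="*",
            n_hits=0,
            is_unaligned=True,
        )
    leftmost = aln.reference_start + 1  # pysam is 0-based
    cigar = aln.cigarstring or "*"
    rightmost = leftmost + cigar_reference_span(cigar) - 1
    n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
    nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
    return AlignmentRecord(
        read_id=aln.query_name,
        mate=mate,
        chrom=aln.reference_name,
        pos_leftmost=leftmost,
        pos_rightmost=rightmost,
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
        cigar=cigar,
        n_hits=int(n_hits),
        edit_distance=int(nm),
    )


def read_sam(
    path_or_stream: str | os.PathLike | io.IOBase,
) -> Iterator[tuple[str, list[AlignmentRecord], list[AlignmentRecord]]]:
    """Yield ``(read_id, mate1_records, mate2_records)`` grouped by read id.

    Accepts a SAM path or an open text stream.  Records for a read id need not
    be adjacent; grouping is done in memory (this package targets desk-scale
    inputs).  A mate with no records (orphan) is emitted with a single record
    flagged ``missing_mate``.
    """
    groups: dict[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]] = {}
    order: list[str] = []
    mode = "r"
    with pysam.AlignmentFile(path_or_stream, mode, check_sq=False) as sam:
        for aln in sam:
            rec = _record_from_pysam(aln)
            if rec.read_id not in groups:
                groups[rec.read_id] = ([], [])
                order.append(rec.read_id)
            groups[rec.read_id][rec.mate - 1].append(rec)
    for read_id in order:
        m1, m2 = groups[read_id]
        if not m1:
            m1 = [
                AlignmentRecord(
                    read_id=read_id, mate=1, chrom=None, pos_leftmost=0,
                    pos_rightmost=0, strand="+", mapq=0, cigar="*",
                    n_hits=0, is_unaligned=True, missing_mate=True,
                )
            ]
        if not m2:
            m2 = [
                AlignmentRecord(
                    read_id=read_id, mate=2, chrom=None, pos_leftmost=0,
                    pos_rightmost=0, strand="+", mapq=0, cigar="*",
                    n_hits=0, is_unaligned=True, missing_mate=True,
                )
            ]
        yield read_id, m1, m2


# ---------------------------------------------------------------------------
# Annotation reports
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom",
    "breakpoint_1based",
    "orientation",
    "read_pairs",
    "rpm",
    "n_primers",
    "tier",
]


def write_annotations(annotations, tsv_path, bed_path=None) -> None:
    """Write insertion annotations as a TSV report and an optional BED file.

    The TSV holds the full record (1-based breakpoints); the BED uses 0-based
    half-open intervals ``[b-1, b)``.
    """
    rows = [
        {
            "chrom": a.chrom,
            "breakpoint_1based": a.breakpoint,
            "orientation": a.orientation,
            "read_pairs": a.n_read_pairs,
            "rpm": a.rpm,
            "n_primers": a.primer_support,
            "tier": a.tier,
        }
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as bed:
            bed.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
            for a in annotations:
                name = f"{a.chrom}:{a.breakpoint}:{a.orientation}"
                bed.write(
                    f"{a.chrom}\t{a.breakpoint - 1}\t{a.breakpoint}\t"
                    f"{name}\t{a.n_read_pairs}\t{a.orientation}\n"
                )


def read_annotations(tsv_path) -> pd.DataFrame:
    """Read an annotation TSV back into a DataFrame (columns as written)."""
    return pd.read_csv(tsv_path, sep="\t")
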
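"""Minimal alignment machinery for desk-scale references.

Three layers:

* :func:`local_align` — exact Smith–Waterman with a configurable linear gap
  penalty, used by the read classifier and the cross-mapping screen.
* :class:`ReferenceIndex` / :func:`align_read` — a seed-and-extend end-to-end
  aligner (exact 20-mer seeds, edlib banded extension) that reports **all
  equal-best hits**, so the reported hit count is meaningful for uniqueness
  filtering.  It exists for testing and desk-scale runs; production pipelines
  may supply SAM from any aligner.
* :func:`classify_pair` — partition aligned pairs into
  unique-concordant / multi / discordant / unaligned, with concordance
  defined as facing (FR) orientation on one chromosome with outer fragment
  span within 500 bp, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .io_formats import AlignmentRecord, Genome, ReadPairRecord, revcomp

MAPQ_UNIQUE = 42
MAPQ_MULTI = 0


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class LocalAlignment:
    """A local alignment between ``query[q_start:q_end]`` and
    ``target[t_start:t_end]`` (0-based half-open string offsets)."""

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    n_matches: int
    n_mismatches: int
    n_gap_bases: int
    n_gap_opens: int

    @property
    def aligned_columns(self) -> int:
        return self.n_matches + self.n_mismatches + self.n_gap_bases

    @property
    def identity(self) -> float:
        cols = self.aligned_columns
        return self.n_matches / cols if cols else 0.0


def _encode(s: str) -> np.ndarray:
    # N (or any non-ACGT) gets a code that never matches, including itself.
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    arr = table[np.frombuffer(s.encode(), dtype=np.uint8)]
    return arr


def local_align(query: str, target: str, scoring: Scoring = Scoring()) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment under ``scoring``.

    N bases never match anything (including another N).  Deterministic
    tie-break: among maximal cells the one with the smallest target end, then
    smallest query end, is chosen; traceback prefers diagonal over deletion
    over insertion.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    q = _encode(query)
    t = _encode(target)
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    sub_match = np.int32(scoring.match)
    sub_mis = np.int32(scoring.mismatch)
    gap = np.int32(scoring.gap)
    for i in range(1, n + 1):
        qi = q[i - 1]
        sub = np.where((t == qi) & (qi != 4), sub_match, sub_mis)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] + gap
        row = np.maximum(np.maximum(diag, up), 0)
        # left-dependency needs a serial pass
        prev = np.int32(0)
        Hi = H[i]
        for j in range(1, m + 1):
            v = row[j - 1]
            left = prev + gap
            if left > v:
                v = left
            Hi[j] = v
            prev = v
    best = int(H.max())
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, 0, 0)
    # smallest target end, then smallest query end
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = (int(x) for x in cells[order[0]])
    # traceback
    n_match = n_mis = n_gapb = n_opens = 0
    end_i, end_j = i, j
    last_move = "D"  # diagonal
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        match_here = q[i - 1] == t[j - 1] and q[i - 1] != 4
        sub = scoring.match if match_here else scoring.mismatch
        if h == H[i - 1, j - 1] + sub:
            if match_here:
                n_match += 1
            else:
                n_mis += 1
            i -= 1
            j -= 1
            last_move = "D"
        elif h == H[i - 1, j] + scoring.gap:
            n_gapb += 1
            if last_move != "U":
                n_opens += 1
            i -= 1
            last_move = "U"
        else:
            n_gapb += 1
            if last_move != "L":
                n_opens += 1
            j -= 1
            last_move = "L"
    return LocalAlignment(
        score=best,
        q_start=i,
        q_end=end_i,
        t_start=j,
        t_end=end_j,
        n_matches=n_match,
        n_mismatches=n_mis,
        n_gap_bases=n_gapb,
        n_gap_opens=n_opens,
    )


def local_align_both_strands(
    query: str, target: str, scoring: Scoring = Scoring()
) -> tuple[LocalAlignment, str]:
    """Best local alignment of ``query`` against either strand of ``target``.

    Returns ``(alignment, strand)``; on a tie the plus strand wins.
    """
    fwd = local_align(query, target, scoring)
    rev = local_align(query, revcomp(target), scoring)
    if rev.score > fwd.score:
        return rev, "-"
    return fwd, "+"


# ---------------------------------------------------------------------------
# Seed-and-extend read aligner
# ---------------------------------------------------------------------------


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(gap_bases, gap_opens) from a standard M/I/D cigar."""
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
    return gap_bases, gap_opens


class ReferenceIndex:
    """Exact k-mer index over the plus strand of a small reference."""

    def __init__(self, genome: Genome, k: int = 20):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i + 1))  # 1-based


def align_read(
    seq: str,
    index: ReferenceIndex,
    read_id: str = "",
    mate: int = 1,
    max_edit_frac: float = 0.10,
    pad: int = 5,
    max_hits: int = 50,
) -> list[AlignmentRecord]:
    """End-to-end alignment of one read; returns all equal-best hits.

    Seeds of length ``k`` are taken at tiled offsets on both strands; each
    candidate placement is scored by edit distance over a padded reference
    window (edlib, infix mode).  Hits beyond ``max_edit_frac * len(seq)``
    edits are discarded.  MAPQ is 42 for a unique best hit, 0 otherwise.
    """
    k = index.k
    genome = index.genome
    if len(seq) < k:
        return []
    max_edit = int(np.floor(max_edit_frac * len(seq)))
    candidates: set[tuple[str, int, str]] = set()
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        offsets = list(range(0, len(oriented) - k + 1, k))
        if offsets[-1] != len(oriented) - k:
            offsets.append(len(oriented) - k)
        for off in offsets:
            kmer = oriented[off : off + k]
            for chrom, pos in index.index.get(kmer, ()):
                start = pos - off  # putative 1-based leftmost
                candidates.add((chrom, start, strand))
    hits: list[tuple[int, str, int, int, str, str]] = []
    seen: set[tuple[str, int, str]] = set()
    for chrom, start, strand in candidates:
        clen = genome.length(chrom)
        w_start = max(1, start - pad)
        w_end = min(clen, start + len(seq) - 1 + pad)
        window = genome.sequences[chrom][w_start - 1 : w_end]
        oriented = seq if strand == "+" else revcomp(seq)
        res = edlib.align(oriented, window, mode="HW", task="path", k=max_edit)
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        leftmost = w_start + loc[0]
        rightmost = w_start + loc[1]
        key = (chrom, leftmost, strand)
        if key in seen:
            continue
        seen.add(key)
        hits.append(
            (res["editDistance"], chrom, leftmost, rightmost, strand, res["cigar"] or "*")
        )
    if not hits:
        return [
            AlignmentRecord(
                read_id=read_id, mate=mate, chrom=None, pos_leftmost=0,
                pos_rightmost=0, strand="+", mapq=0, cigar="*", n_hits=0,
                is_unaligned=True,
            )
        ]
    best = min(h[0] for h in hits)
    best_hits = sorted(h for h in hits if h[0] == best)[:max_hits]
    n_hits = len(best_hits)
    mapq = MAPQ_UNIQUE if n_hits == 1 else MAPQ_MULTI
    return [
        AlignmentRecord(
            read_id=read_id, mate=mate, chrom=chrom, pos_leftmost=left,
            pos_rightmost=right, strand=strand, mapq=mapq, cigar=cigar,
            n_hits=n_hits, edit_distance=dist,
        )
        for dist, chrom, left, right, strand, cigar in best_hits
    ]


def align_pairs_to_reference(
    pairs: Iterable[ReadPairRecord],
    genome: Genome,
    k: int = 20,
    max_edit_frac: float = 0.10,
    index: ReferenceIndex | None = None,
) -> dict[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]]:
    """Align both mates of every pair; returns ``read_id -> (hits1, hits2)``."""
    if index is None:
        index = ReferenceIndex(genome, k=k)
    out: dict[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]] = {}
    for pair in pairs:
        h1 = align_read(pair.seq1, index, read_id=pair.read_id, mate=1,
                        max_edit_frac=max_edit_frac)
        h2 = align_read(pair.seq2, index, read_id=pair.read_id, mate=2,
                        max_edit_frac=max_edit_frac)
        out[pair.read_id] = (h1, h2)
    return out


def write_sam(
    alignments: dict[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]],
    genome: Genome,
    path,
    reads: dict[str, ReadPairRecord] | None = None,
) -> None:
    """Write grouped alignments as SAM (text) with NH tags."""
    import pysam

    names = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": genome.length(n)} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, (h1, h2) in alignments.items():
            for recs, mate in ((h1, 1), (h2, 2)):
                for i, rec in enumerate(recs):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = read_id
                    flag = 0x1 | (0x40 if mate == 1 else 0x80)
                    if rec.is_unaligned:
                        flag |= 0x4
                    else:
                        if rec.strand == "-":
                            flag |= 0x10
                        if i > 0:
                            flag |= 0x100
                    a.flag = flag
                    if reads is not None and read_id in reads:
                        pr = reads[read_id]
                        seq = pr.seq1 if mate == 1 else pr.seq2
                        qual = pr.qual1 if mate == 1 else pr.qual2
                        if not rec.is_unaligned and rec.strand == "-":
                            seq, qual = revcomp(seq), qual[::-1]
                        a.query_sequence = seq
                        a.query_qualities = pysam.qualitystring_to_array(qual)
                    if not rec.is_unaligned:
                        a.reference_id = tid[rec.chrom]
                        a.reference_start = rec.pos_leftmost - 1
                        a.mapping_quality = rec.mapq
                        cig = rec.cigar
                        if cig in ("*", ""):
                            cig = f"{rec.pos_rightmost - rec.pos_leftmost + 1}M"
                        a.cigarstring = cig.replace("=", "M").replace("X", "M")
                        a.set_tag("NH", rec.n_hits)
                        a.set_tag("NM", rec.edit_distance)
                    out.write(a)


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

PAIR_STATUSES = ("unique_concordant", "multi", "discordant", "unaligned")


def classify_pair(
    mate1: Sequence[AlignmentRecord],
    mate2: Sequence[AlignmentRecord],
    max_mate_dist: int = 500,
) -> str:
    """Classify a pair from its equal-best hit lists.

    ``unique_concordant`` requires exactly one hit per mate, same chromosome,
    facing (FR) orientation, and outer fragment span (leftmost of the pair to
    rightmost of the pair, inclusive) <= ``max_mate_dist``.  Any mate with
    more than one equal-best hit makes the pair ``multi``; a mate with no
    hits makes it ``unaligned``; everything else is ``discordant``.
    """
    a1 = [r for r in mate1 if not r.is_unaligned]
    a2 = [r for r in mate2 if not r.is_unaligned]
    if len(a1) == 1 and len(a2) == 1:
        r1, r2 = a1[0], a2[0]
        if r1.chrom == r2.chrom and r1.strand != r2.strand:
            fwd, rev = (r1, r2) if r1.strand == "+" else (r2, r1)
            facing = fwd.pos_leftmost <= rev.pos_rightmost
            outer = max(r1.pos_rightmost, r2.pos_rightmost) - min(
                r1.pos_leftmost, r2.pos_leftmost
            ) + 1
            if facing and outer <= max_mate_dist:
                return "unique_concordant"
    if len(a1) > 1 or len(a2) > 1:
        return "multi"
    if not a1 or not a2:
        return "unaligned"
    return "discordant"
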
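"""Identify read pairs derived from the target TE's 3' end, and trim them.

Every read-1 produced by the hemi-specific library design starts with the
3'-terminal segment of the TE consensus that lies downstream of the nested
primer (52 nt for the bundled P-element-style consensus), followed by
flanking genomic sequence.  The classifier aligns the start of read-1 against
the consensus 3' terminus and keeps the pair when that alignment is longer
than ``min_len`` nucleotides (strictly; the published setting keeps >=21)
with at most one mismatch and one gap.

The alignment is doubly anchored: it must begin at the first base of read-1
(the nested primer is the first thing sequenced) and must reach the final
base of the consensus (amplicons run through the TE end into the flank).
Under the <=1 mismatch / <=1 single-base gap caps this anchored problem is
solved exactly by enumerating the three alignment shapes (gapless, one read
insertion, one read deletion); alignments are ranked by the classification
score (match +1, mismatch -1, gap -2).  Terminal gaps are disallowed so the
alignment can never consume read bases past the consensus terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ReadPairRecord

DEFAULT_WINDOW = 160


@dataclass
class TEConsensus:
    """The target TE consensus with its primer landmarks.

    ``enrich_primer_span`` / ``nested_primer_span`` are 1-based inclusive
    intervals on the consensus (P-element: 2752-2774 and 2856-2877 of 2907).
    ``window`` is the length of the 3'-terminal region used for read
    classification.
    """

    seq: str
    enrich_primer_span: tuple[int, int] = (2752, 2774)
    nested_primer_span: tuple[int, int] = (2856, 2877)
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        L = len(self.seq)
        for span in (self.enrich_primer_span, self.nested_primer_span):
            if not (1 <= span[0] <= span[1] <= L):
                raise ValueError(f"primer span {span} outside consensus [1, {L}]")
        if self.nested_primer_span[0] < self.enrich_primer_span[0]:
            raise ValueError("nested primer span must lie 3' of the enrich span")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def prefix_len(self) -> int:
        """Read-1 TE prefix length implied by the nested primer placement:
        every amplicon carries the consensus from the nested primer start
        through the 3' terminus (52 nt for the P-element layout)."""
        return self.length - self.nested_primer_span[0] + 1

    @property
    def terminal_window(self) -> str:
        return self.seq[-self.window:]


@dataclass
class ClassifiedPair:
    pair: ReadPairRecord
    keep: bool
    prefix_match_len: int
    n_mismatches: int
    n_gap_bases: int
    score: int
    trim1_start: int  # 1-based first retained base of read-1 after the TE prefix


def _mismatch_cumsum(read: str, window: str, max_p: int) -> np.ndarray:
    """Cz[s, j] = number of mismatching positions among read[0..j-1] vs
    window[s..s+j-1] (window padded with sentinels past its end); shape
    (len(window)+1, max_p+1) with a leading zero column."""
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    r = table[np.frombuffer(read[:max_p].encode(), dtype=np.uint8)]
    w = table[np.frombuffer(window.encode(), dtype=np.uint8)]
    W = len(w)
    pad = np.full(max_p + 1, 5, dtype=np.int8)  # never matches anything
    wp = np.concatenate([w, pad])
    shifts = np.lib.stride_tricks.sliding_window_view(wp, max_p)[: W + 1]
    mism = (shifts != r) | (r == 4) | (shifts == 4)
    Cz = np.zeros((W + 1, max_p + 1), dtype=np.int32)
    np.cumsum(mism, axis=1, out=Cz[:, 1:])
    return Cz


def classify_read_pair(
    pair: ReadPairRecord,
    consensus: TEConsensus,
    min_len: int = 20,
    max_mismatch: int = 1,
    max_gap: int = 1,
) -> ClassifiedPair:
    """Classify one pair by its read-1 match to the consensus 3' terminus.

    ``min_len`` is exclusive: the best-scoring anchored alignment must consume
    strictly more than ``min_len`` read bases for the pair to be kept.  At
    most one gap is modeled (the published cap).
    """
    read = pair.seq1
    window = consensus.terminal_window
    W = len(window)
    if not read:
        return ClassifiedPair(pair, False, 0, 0, 0, 0, 1)
    max_p = min(len(read), W + 1)
    Cz = _mismatch_cumsum(read, window, max_p)

    best = (-(10**9), 0, 0, 0)  # (score, p, -gapbases, -mm) maximized
    # gapless: read[0:p] vs window suffix of length p
    ps = np.arange(1, min(max_p, W) + 1)
    mm0 = Cz[W - ps, ps]
    ok = mm0 <= max_mismatch
    if ok.any():
        scores = ps - 2 * mm0
        idx = np.flatnonzero(ok)
        j = idx[np.lexsort((idx, scores[idx]))[-1]]  # max score, then max p
        best = max(best, (int(scores[j]), int(ps[j]), 0, -int(mm0[j])))

    if max_gap >= 1:
        big = np.int32(10**6)
        # one read deletion: p read bases vs p+1 window bases, an interior
        # window base skipped at offset h in 1..p-1:
        #   mm(p) = Cz[s+1, p] + min_h (Cz[s, h] - Cz[s+1, h]),  s = W-p-1
        pd = np.arange(2, min(max_p, W - 1) + 1)
        if pd.size:
            D = Cz[:-1, :] - Cz[1:, :]
            D[:, 0] = big  # h >= 1
            Dmin = np.minimum.accumulate(D, axis=1)
            s = W - pd - 1
            mm = Cz[s + 1, pd] + Dmin[s, pd - 1]
            ok = mm <= max_mismatch
            if ok.any():
                scores = pd - 2 - 2 * mm
                idx = np.flatnonzero(ok)
                j = idx[np.lexsort((idx, scores[idx]))[-1]]
                best = max(best, (int(scores[j]), int(pd[j]), -1, -int(mm[j])))
        # one read insertion: p read bases vs p-1 window bases, an interior
        # read base unaligned at offset g in 1..p-2:
        #   mm(p) = Cz[s-1, p] + min_g (Cz[s, g] - Cz[s-1, g+1]),  s = W-p+1
        pi = np.arange(3, min(max_p, W) + 1)
        if max_p >= W + 1 >= 3:
            # insertion alignment spanning the whole window (p = W + 1); the
            # shifted row would lie outside the cumsum matrix, score directly:
            # read[0:g] vs window[0:g], then read[g+1:p] vs window[g:W]
            p = W + 1
            t = np.fromiter(
                (
                    read[i] != window[i - 1] or read[i] == "N" or window[i - 1] == "N"
                    for i in range(1, p)
                ),
                dtype=np.int32,
            )
            T = np.concatenate(([0], np.cumsum(t)))  # T[j] = sum of t over i<=j
            gs = np.arange(1, p - 1)
            mm = Cz[0, gs] + (T[p - 1] - T[gs])
            m = int(mm.min())
            if m <= max_mismatch:
                best = max(best, (p - 3 - 2 * m, p, -1, -m))
        if pi.size:
            E = np.full_like(Cz, big)
            E[1:, 1:-1] = Cz[1:, 1:-1] - Cz[:-1, 2:]
            E[:, 0] = big  # g >= 1
            Emin = np.minimum.accumulate(E, axis=1)
            s = W - pi + 1
            mm = Cz[s - 1, pi] + Emin[s, pi - 2]
            ok = mm <= max_mismatch
            if ok.any():
                scores = pi - 3 - 2 * mm
                idx = np.flatnonzero(ok)
                j = idx[np.lexsort((idx, scores[idx]))[-1]]
                best = max(best, (int(scores[j]), int(pi[j]), -1, -int(mm[j])))

    score, p, neg_gap, neg_mm = best
    if p == 0:
        return ClassifiedPair(pair, False, 0, 0, 0, 0, 1)
    keep = p > min_len
    return ClassifiedPair(
        pair=pair,
        keep=keep,
        prefix_match_len=p,
        n_mismatches=-neg_mm,
        n_gap_bases=-neg_gap,
        score=score,
        trim1_start=p + 1,
    )


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


def _trim_adapter(seq: str, qual: str, adapters: tuple[str, ...], min_overlap: int = 3):
    """Remove an adapter occurrence (full internal match, or a read suffix
    matching an adapter prefix with >= ``min_overlap`` exact bases)."""
    cut = len(seq)
    for ad in adapters:
        if not ad:
            continue
        pos = seq.find(ad)
        if pos != -1:
            cut = min(cut, pos)
            continue
        for ov in range(min(len(ad), len(seq)) - 1, min_overlap - 1, -1):
            if seq.endswith(ad[:ov]):
                cut = min(cut, len(seq) - ov)
                break
    return seq[:cut], qual[:cut]


def _trim_quality(seq: str, qual: str, cutoff: int):
    """Drop trailing bases with phred quality below ``cutoff``."""
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < cutoff:
        end -= 1
    return seq[:end], qual[:end]


def trim_pair(
    classified: ClassifiedPair,
    adapters: tuple[str, ...] = (),
    qual_cutoff: int = 20,
) -> ReadPairRecord | None:
    """Trim a kept pair: remove the TE prefix from read-1, adapter suffixes
    and low-quality 3' ends from both mates.  Returns ``None`` when either
    mate is fully trimmed away (the caller counts dropped pairs)."""
    if not classified.keep:
        raise ValueError("trim_pair requires a kept (TE-derived) pair")
    p = classified.pair
    s1, q1 = p.seq1[classified.trim1_start - 1 :], p.qual1[classified.trim1_start - 1 :]
    s2, q2 = p.seq2, p.qual2
    s1, q1 = _trim_adapter(s1, q1, adapters)
    s2, q2 = _trim_adapter(s2, q2, adapters)
    s1, q1 = _trim_quality(s1, q1, qual_cutoff)
    s2, q2 = _trim_quality(s2, q2, qual_cutoff)
    if not s1 or not s2:
        return None
    return ReadPairRecord(
        read_id=p.read_id, seq1=s1, seq2=s2, qual1=q1, qual2=q2,
        library_id=p.library_id,
    )


def classify_library(
    pairs,
    consensus: TEConsensus,
    min_len: int = 20,
    max_mismatch: int = 1,
    max_gap: int = 1,
    adapters: tuple[str, ...] = (),
    qual_cutoff: int = 20,
):
    """Classify and trim a whole library.

    Returns ``(trimmed_kept_pairs, summary)`` where summary carries the
    per-library totals used downstream for reads-per-million normalisation.
    """
    kept: list[ReadPairRecord] = []
    total = n_te = n_dropped_empty = 0
    for pair in pairs:
        total += 1
        cls = classify_read_pair(pair, consensus, min_len, max_mismatch, max_gap)
        if not cls.keep:
            continue
        n_te += 1
        trimmed = trim_pair(cls, adapters, qual_cutoff)
        if trimmed is None:
            n_dropped_empty += 1
            continue
        kept.append(trimmed)
    summary = {
        "total_pairs": total,
        "te_derived_pairs": n_te,
        "fraction_te": n_te / total if total else float("nan"),
        "dropped_empty": n_dropped_empty,
    }
    return kept, summary
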
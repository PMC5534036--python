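"""Insertion-frequency estimation from WGS pairs, and the paired
permutation test used to compare frequency-estimate sets.

WGS read pairs are aligned concurrently to a *hybrid reference* — the
reference genome plus one putative insertion contig per annotation — so that
junction-spanning reads can vote for the allele they actually come from.
Ambiguous placements (flank-only reads, which fit both references equally)
receive MAPQ 0 from the bundled aligner and are removed by the strict
``MAPQ > mapq_min`` filter.  A pair supports the insertion when a retained
mate alignment to the contig spans one of its TE junctions by at least
``span_margin`` bases on each side, and supports the reference when a
genome alignment spans the breakpoint the same way.  The estimated
frequency is the proportion of insertion-supporting pairs among pairs
supporting either allele.

Because the 8-bp TSD is duplicated, a read ending inside the TSD cannot
distinguish the alleles; the margin rule plus the MAPQ filter excludes such
reads rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .contigs import InsertionContig
from .io_formats import AlignmentRecord, Genome


@dataclass
class FrequencyEstimate:
    annotation: str
    n_ins: int  # junction-spanning pairs supporting the inserted allele
    n_ref: int  # breakpoint-spanning pairs supporting the reference allele

    @property
    def freq(self) -> float | None:
        """Insertion frequency, or ``None`` when no pair is informative."""
        total = self.n_ins + self.n_ref
        if total == 0:
            return None
        return self.n_ins / total


def hybrid_reference(genome: Genome, contigs: list[InsertionContig]) -> Genome:
    """Reference genome plus one record per insertion contig."""
    seqs = dict(genome.sequences)
    for c in contigs:
        if c.name in seqs:
            raise ValueError(f"contig name {c.name!r} collides with a chromosome")
        seqs[c.name] = c.seq
    return Genome(seqs)


def _spans(rec: AlignmentRecord, pos: int, margin: int) -> bool:
    return rec.pos_leftmost <= pos - margin + 1 and rec.pos_rightmost >= pos + margin


def estimate_frequencies(
    alignments: Mapping[str, tuple[list[AlignmentRecord], list[AlignmentRecord]]]
    | Iterable[tuple[str, list[AlignmentRecord], list[AlignmentRecord]]],
    contigs: list[InsertionContig],
    mapq_min: int = 10,
    span_margin: int = 5,
) -> list[FrequencyEstimate]:
    """Estimate each annotated insertion's frequency from hybrid alignments.

    ``alignments`` maps read ids to per-mate hit lists against the hybrid
    reference.  Alignments with MAPQ <= ``mapq_min`` are discarded (strict
    inequality, the published rule).  Per annotation, a pair counts for the
    insertion if a retained mate alignment to the contig covers at least
    ``span_margin`` bases on both sides of either junction, and for the
    reference if a genome alignment covers the breakpoint the same way;
    pairs supporting neither are ignored.  Estimates with no informative
    pairs are emitted with counts 0/0 (``freq`` is ``None``).
    """
    if hasattr(alignments, "items"):
        items = ((rid, h1, h2) for rid, (h1, h2) in alignments.items())
    else:
        items = iter(alignments)
    counts = {c.name: [0, 0] for c in contigs}
    by_name = {c.name: c for c in contigs}
    for _, hits1, hits2 in items:
        kept = [
            r
            for r in (*hits1, *hits2)
            if not r.is_unaligned and r.mapq > mapq_min
        ]
        if not kept:
            continue
        for name, contig in by_name.items():
            ann = contig.annotation
            supports_ins = any(
                r.chrom == name
                and (
                    _spans(r, contig.junction5, span_margin)
                    or _spans(r, contig.junction3, span_margin)
                )
                for r in kept
            )
            if supports_ins:
                counts[name][0] += 1
                continue
            supports_ref = any(
                r.chrom == ann.chrom and _spans(r, ann.breakpoint, span_margin)
                for r in kept
            )
            if supports_ref:
                counts[name][1] += 1
    return [
        FrequencyEstimate(annotation=name, n_ins=c[0], n_ref=c[1])
        for name, c in counts.items()
    ]


def write_frequencies(estimates: list[FrequencyEstimate], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "annotation": e.annotation,
                "n_ins": e.n_ins,
                "n_ref": e.n_ref,
                "freq": "" if e.freq is None else e.freq,
            }
            for e in estimates
        ],
        columns=["annotation", "n_ins", "n_ref", "freq"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Paired permutation test
# ---------------------------------------------------------------------------


def permutation_median_test(
    x: Iterable[float],
    y: Iterable[float],
    n_perm: int = 10**6,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided paired sign-flip permutation test on the median difference.

    The statistic is ``median(x - y)`` over pairs matched by insertion; the
    null distribution flips the sign of each paired difference independently.
    When ``2**n <= n_perm`` all sign assignments are enumerated and the
    p-value is exact; otherwise ``n_perm`` random flips are drawn and the
    add-one estimate ``(hits + 1) / (n_perm + 1)`` is returned.

    Returns ``(observed_median_difference, p_value)``.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = xa - ya
    observed = float(np.median(d))
    thresh = abs(observed) - 1e-12
    if 2**n <= n_perm:
        hits = total = 0
        chunk = 1 << 16
        codes = np.arange(2**n, dtype=np.int64)
        bits = np.arange(n, dtype=np.int64)
        for lo in range(0, 2**n, chunk):
            block = codes[lo : lo + chunk]
            signs = (((block[:, None] >> bits) & 1) * 2 - 1).astype(np.int8)
            stats = np.median(signs * d, axis=1)
            hits += int(np.count_nonzero(np.abs(stats) >= thresh))
            total += block.size
        return observed, hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = 1 << 14
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
        stats = np.median(signs * d, axis=1)
        hits += int(np.count_nonzero(np.abs(stats) >= thresh))
        remaining -= m
    return observed, (hits + 1) / (n_perm + 1)
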
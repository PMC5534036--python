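"""Cross-mapping screen over annotated insertion flanks.

Substitution errors introduced during PCR and sequencing can make a small
fraction of the reads from a true insertion align better to a similar
sequence elsewhere in the genome, producing a spurious second annotation.
Such pairs are recognisable because the two flanking regions are highly
similar while the suspect member carries a tiny fraction of its partner's
read support (on the order of the per-base substitution rate).  The screen
compares the genomic window around every pair of breakpoints (both strands),
reports pairs above an identity/length floor, and flags the lower-support
member when its support falls below ``support_ratio_max`` times the
partner's.  Flagged annotations are reported, never deleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .align_core import Scoring, local_align_both_strands
from .insertion_caller import InsertionAnnotation
from .io_formats import Genome

logger = logging.getLogger(__name__)


@dataclass
class CrossMappingHit:
    annotation_a: InsertionAnnotation
    annotation_b: InsertionAnnotation
    identity: float
    aligned_len: int
    strand: str
    support_a: int
    support_b: int
    flagged: InsertionAnnotation | None  # the suspect (lower-support) member


def _window(genome: Genome, annotation: InsertionAnnotation, window: int) -> str:
    half = window // 2
    b = annotation.breakpoint
    clen = genome.length(annotation.chrom)
    start = max(1, b - half + 1)
    end = min(clen, b + half)
    if start == 1 or end == clen:
        logger.warning(
            "screen window truncated at chromosome edge for %s", annotation.name
        )
    return genome.fetch(annotation.chrom, start, end)


def flag_cross_mapping(
    annotations: list[InsertionAnnotation],
    genome: Genome,
    window: int = 800,
    min_identity: float = 0.80,
    min_len: int = 80,
    support_ratio_max: float = 0.01,
    scoring: Scoring = Scoring(),
) -> list[CrossMappingHit]:
    """Report annotation pairs whose breakpoint windows are mutually similar.

    For every unordered pair the ``window``-bp regions centred on the two
    breakpoints are locally aligned on both strands; pairs reaching
    ``min_identity`` over at least ``min_len`` alignment columns are
    reported.  Within a reported pair the lower-support member is flagged as
    a suspected cross-mapping artifact iff its read support is below
    ``support_ratio_max`` times the partner's.  Output order is independent
    of input order.
    """
    if len(annotations) < 2:
        return []
    ordered = sorted(annotations, key=lambda a: (a.chrom, a.breakpoint, a.orientation))
    windows = {a.name: _window(genome, a, window) for a in ordered}
    hits: list[CrossMappingHit] = []
    for a, b in combinations(ordered, 2):
        aln, strand = local_align_both_strands(windows[a.name], windows[b.name], scoring)
        if aln.aligned_columns < min_len or aln.identity < min_identity:
            continue
        low, high = (a, b) if a.n_read_pairs <= b.n_read_pairs else (b, a)
        flagged = None
        if (
            low.n_read_pairs < high.n_read_pairs
            and low.n_read_pairs < support_ratio_max * high.n_read_pairs
        ):
            flagged = low
        hits.append(
            CrossMappingHit(
                annotation_a=a,
                annotation_b=b,
                identity=aln.identity,
                aligned_len=aln.aligned_columns,
                strand=strand,
                support_a=a.n_read_pairs,
                support_b=b.n_read_pairs,
                flagged=flagged,
            )
        )
    return hits


def write_screen_report(hits: list[CrossMappingHit], path) -> None:
    import pandas as pd

    rows = [
        {
            "annotationA": h.annotation_a.name,
            "annotationB": h.annotation_b.name,
            "identity": round(h.identity, 4),
            "aligned_len": h.aligned_len,
            "strand": h.strand,
            "supportA": h.support_a,
            "supportB": h.support_b,
            "flagged": h.flagged.name if h.flagged else "",
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "annotationA", "annotationB", "identity", "aligned_len",
            "strand", "supportA", "supportB", "flagged",
        ],
    ).to_csv(path, sep="\t", index=False)
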
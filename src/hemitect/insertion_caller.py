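"""Breakpoint calling, clustering, and support-based filtering.

The breakpoint of an insertion is defined as the 3' end of the
``tsd_len``-bp target-site duplication on the plus genomic strand.  Because
read-1 of a hemi-specific pair starts at the TE 3' terminus and continues
into the flank:

* a read-1 aligned to the **plus** strand implies a TE in plus orientation,
  and the breakpoint is its leftmost aligned coordinate plus
  ``tsd_len - 1`` (the ``+7`` rule for 8-bp TSDs);
* a read-1 aligned to the **minus** strand implies a TE in minus
  orientation, and the breakpoint is its rightmost aligned coordinate.

Calls sharing chromosome and orientation are clustered around the modal
breakpoint within a small merge window; an insertion is *annotated* at >= 20
supporting pairs and *high-confidence* at >= 100 pairs from >= 4 degenerate
primers.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .io_formats import AlignmentRecord


@dataclass(frozen=True)
class BreakpointCall:
    chrom: str
    breakpoint: int  # 1-based, 3' end of the TSD on the plus strand
    orientation: str  # '+' or '-', TE orientation relative to the plus strand
    library_id: str
    read_id: str


@dataclass
class InsertionAnnotation:
    chrom: str
    breakpoint: int
    orientation: str
    n_read_pairs: int
    library_counts: dict[str, int] = field(default_factory=dict)
    rpm: float = float("nan")
    tier: str = "candidate"

    @property
    def primer_support(self) -> int:
        """Number of primer libraries with at least one supporting pair."""
        return sum(1 for v in self.library_counts.values() if v > 0)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.breakpoint}:{self.orientation}"


def call_breakpoint(read1_aln: AlignmentRecord, tsd_len: int = 8,
                    library_id: str = "") -> BreakpointCall:
    """Convert a unique-concordant read-1 alignment into a breakpoint call.

    The ``tsd_len - 1`` offset generalises the published ``+7 bp`` rule to
    TEs with other TSD lengths.
    """
    if read1_aln is None or read1_aln.is_unaligned:
        raise ValueError("call_breakpoint requires an aligned read-1 record")
    if read1_aln.strand == "+":
        return BreakpointCall(
            chrom=read1_aln.chrom,
            breakpoint=read1_aln.pos_leftmost + tsd_len - 1,
            orientation="+",
            library_id=library_id or "",
            read_id=read1_aln.read_id,
        )
    return BreakpointCall(
        chrom=read1_aln.chrom,
        breakpoint=read1_aln.pos_rightmost,
        orientation="-",
        library_id=library_id or "",
        read_id=read1_aln.read_id,
    )


def cluster_calls(
    calls: list[BreakpointCall],
    merge_window: int = 3,
    min_support: int = 20,
    library_totals: dict[str, int] | None = None,
) -> list[InsertionAnnotation]:
    """Cluster calls into insertion annotations.

    Calls are grouped by (chromosome, orientation); within a group, the modal
    breakpoint (ties broken toward the smaller coordinate) seeds a cluster
    that absorbs all calls within ``merge_window`` bp, and the process
    repeats on the remainder.  Reads-per-million support is computed per
    source library against ``library_totals`` and summed.  Clusters with at
    least ``min_support`` pairs are tiered ``annotated``, the rest
    ``candidate``.
    """
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    members: dict[tuple[str, str], dict[int, list[BreakpointCall]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for call in calls:
        key = (call.chrom, call.orientation)
        groups[key][call.breakpoint] += 1
        members[key][call.breakpoint].append(call)
    annotations: list[InsertionAnnotation] = []
    for key in sorted(groups):
        chrom, orientation = key
        counts = dict(groups[key])
        while counts:
            mode = min(
                counts, key=lambda bp: (-counts[bp], bp)
            )  # most supported, then leftmost
            window = [
                bp for bp in counts if abs(bp - mode) <= merge_window
            ]
            cluster = [c for bp in window for c in members[key][bp]]
            for bp in window:
                del counts[bp]
            lib_counts: dict[str, int] = Counter(c.library_id for c in cluster)
            n = len(cluster)
            rpm = float("nan")
            if library_totals:
                rpm = sum(
                    1e6 * cnt / library_totals[lib]
                    for lib, cnt in lib_counts.items()
                    if library_totals.get(lib)
                )
            annotations.append(
                InsertionAnnotation(
                    chrom=chrom,
                    breakpoint=mode,
                    orientation=orientation,
                    n_read_pairs=n,
                    library_counts=dict(lib_counts),
                    rpm=rpm,
                    tier="annotated" if n >= min_support else "candidate",
                )
            )
    annotations.sort(key=lambda a: (a.chrom, a.breakpoint, a.orientation))
    return annotations


def high_confidence_filter(
    annotations: list[InsertionAnnotation],
    min_reads: int = 100,
    min_primers: int = 4,
) -> list[InsertionAnnotation]:
    """Upgrade annotations meeting both support thresholds to
    ``high_confidence``; no annotation is ever removed."""
    for a in annotations:
        if a.n_read_pairs >= min_reads and a.primer_support >= min_primers:
            a.tier = "high_confidence"
    return annotations
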
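"""End-to-end orchestration of the TGS insertion-calling stages.

``run_tgs_pipeline`` takes per-library read pairs and runs
classify/trim -> align -> pair classification -> breakpoint calling ->
clustering -> tier filters, returning the annotations together with the
intermediates (library summaries, multimapping pairs for rescue).  It is the
library-level entry point used by the command-line ``run-all`` and by the
test-suite truth-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align_core import ReferenceIndex, align_pairs_to_reference, classify_pair
from .classify_trim import TEConsensus, classify_library
from .contigs import InsertionContig, build_contigs
from .insertion_caller import (
    BreakpointCall,
    InsertionAnnotation,
    call_breakpoint,
    cluster_calls,
    high_confidence_filter,
)
from .io_formats import Genome, ReadPairRecord


@dataclass
class PipelineResult:
    annotations: list[InsertionAnnotation]
    calls: list[BreakpointCall]
    library_summaries: dict[str, dict]
    library_totals: dict[str, int]
    multi_pairs: dict[str, list[ReadPairRecord]]
    pair_status_counts: dict[str, dict[str, int]]


def run_tgs_pipeline(
    libraries: dict[str, list[ReadPairRecord]],
    consensus: TEConsensus,
    genome: Genome,
    min_len: int = 20,
    max_mismatch: int = 1,
    max_gap: int = 1,
    adapters: tuple[str, ...] = (),
    qual_cutoff: int = 20,
    max_mate_dist: int = 500,
    tsd_len: int = 8,
    merge_window: int = 3,
    min_support: int = 20,
    hc_reads: int = 100,
    hc_primers: int = 4,
    max_edit_frac: float = 0.10,
) -> PipelineResult:
    """Run the full TGS calling pipeline on in-memory libraries."""
    index = ReferenceIndex(genome)
    calls: list[BreakpointCall] = []
    summaries: dict[str, dict] = {}
    totals: dict[str, int] = {}
    multi: dict[str, list[ReadPairRecord]] = {}
    status_counts: dict[str, dict[str, int]] = {}
    for lib, pairs in libraries.items():
        kept, summary = classify_library(
            pairs, consensus, min_len, max_mismatch, max_gap, adapters, qual_cutoff
        )
        summaries[lib] = summary
        totals[lib] = summary["total_pairs"]
        multi[lib] = []
        counts = {s: 0 for s in ("unique_concordant", "multi", "discordant", "unaligned")}
        aligned = align_pairs_to_reference(
            kept, genome, index=index, max_edit_frac=max_edit_frac
        )
        by_id = {p.read_id: p for p in kept}
        for read_id, (h1, h2) in aligned.items():
            status = classify_pair(h1, h2, max_mate_dist=max_mate_dist)
            counts[status] += 1
            if status == "unique_concordant":
                calls.append(call_breakpoint(h1[0], tsd_len=tsd_len, library_id=lib))
            elif status == "multi":
                multi[lib].append(by_id[read_id])
        status_counts[lib] = counts
    annotations = cluster_calls(
        calls, merge_window=merge_window, min_support=min_support,
        library_totals=totals,
    )
    high_confidence_filter(annotations, min_reads=hc_reads, min_primers=hc_primers)
    return PipelineResult(
        annotations=annotations,
        calls=calls,
        library_summaries=summaries,
        library_totals=totals,
        multi_pairs=multi,
        pair_status_counts=status_counts,
    )


def annotated(result: PipelineResult) -> list[InsertionAnnotation]:
    """Annotations meeting the per-insertion support threshold."""
    return [a for a in result.annotations if a.tier in ("annotated", "high_confidence")]


def make_contigs_for_result(
    result: PipelineResult,
    genome: Genome,
    consensus_seq: str,
    flank: int = 500,
    tsd_len: int = 8,
) -> list[InsertionContig]:
    return build_contigs(
        genome, annotated(result), consensus_seq, flank=flank, tsd_len=tsd_len
    )
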
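"""Synthetic data with known truth for every pipeline stage.

The generator emulates the hemi-specific PCR library design: a TE-specific
nested primer anchors every amplicon at the TE 3' terminus, so read-1 begins
with a fixed-length TE prefix (52 nt under the bundled primer layout)
followed by flanking genomic sequence, while read-2 enters from a degenerate
primer bound somewhere in the flank.  Planted insertions carry 8-bp
target-site duplications; substitution errors are applied at the combined
polymerase + sequencer rate.  WGS read pairs are drawn from a mixture of the
inserted and uninserted haplotypes at a chosen insertion frequency.

Every emitted read records its provenance so downstream stages can be scored
against truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import Genome, ReadPairRecord, revcomp

logger = logging.getLogger(__name__)

#: Degenerate-primer pentamers (synthetic stand-ins for a pentamer table of
#: 15 common, compositionally diverse D. melanogaster 5-mers).
DEFAULT_PENTAMERS = (
    "AATAT", "ACCTG", "AGGTC", "ATGCA", "CAATC",
    "CCGTA", "CGATT", "CTTGG", "GAACC", "GCTAA",
    "GGATG", "GTCAT", "TACGA", "TCGTT", "TGCAC",
)

CONSENSUS_LENGTH = 2907


def synthetic_consensus(length: int = CONSENSUS_LENGTH, seed: int = 20170728) -> str:
    """A synthetic stand-in for the 2907-nt P-element consensus sequence.

    Deterministic random sequence; the published consensus is not bundled, but
    every position-arithmetic property of the pipeline (primer landmarks,
    52-nt 3'-terminal prefix, contig structure) depends only on the length
    and the landmark coordinates, which match the P-element layout.
    """
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def random_genome(
    lengths: dict[str, int], seed: int = 0, gc: float = 0.42
) -> Genome:
    """A random genome with roughly Drosophila-like GC content."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return Genome(
        {
            name: "".join(bases[rng.choice(4, size=n, p=p)])
            for name, n in lengths.items()
        }
    )


@dataclass
class PlantedInsertion:
    """One planted TE insertion, in original-genome coordinates plus the
    TE block span in mutated-genome coordinates."""

    chrom: str
    tsd_start: int  # 1-based first base of the TSD (original coordinates)
    tsd_len: int
    orientation: str  # '+', '-' or 'tail_to_tail'
    te_start_mut: int  # 1-based TE block span in the mutated genome
    te_end_mut: int

    @property
    def breakpoint(self) -> int:
        """3' end of the TSD on the plus strand, original coordinates."""
        return self.tsd_start + self.tsd_len - 1

    @property
    def junction5_mut(self) -> int:
        """Last flank base before the TE block (mutated coordinates)."""
        return self.te_start_mut - 1

    @property
    def junction3_mut(self) -> int:
        """First flank base after the TE block (mutated coordinates)."""
        return self.te_end_mut + 1


@dataclass
class SimConfig:
    n_primers: int = 15
    pentamers: tuple[str, ...] = DEFAULT_PENTAMERS
    amplicon_min: int = 300
    amplicon_max: int = 500
    read_len: int = 150
    prefix_len: int = 52
    sub_rate_polymerase: float = 0.00003
    sub_rate_sequencer: float = 0.008
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.sub_rate_polymerase, self.sub_rate_sequencer):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rates must lie in [0, 1]")
        if self.prefix_len >= self.read_len:
            raise ValueError("prefix_len must be smaller than read_len")
        if any(len(p) != 5 for p in self.pentamers):
            raise ValueError("pentamers must have length 5")

    @property
    def sub_rate(self) -> float:
        return self.sub_rate_polymerase + self.sub_rate_sequencer

    @property
    def libraries(self) -> list[str]:
        return [f"R{i + 1}" for i in range(min(self.n_primers, len(self.pentamers)))]


@dataclass
class SimTruth:
    insertions: list[PlantedInsertion] = field(default_factory=list)
    #: read_id -> (insertion index or -1 for background, library_id)
    provenance: dict[str, tuple[int, str]] = field(default_factory=dict)
    library_totals: dict[str, int] = field(default_factory=dict)
    #: WGS fragments: (haplotype 'ref'|'ins', chrom, start, end) 1-based
    fragments: list[tuple[str, str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def plant_insertions(
    genome: Genome,
    consensus_seq: str,
    sites: list[tuple[str, int, str]],
    tsd_len: int = 8,
    min_flank: int = 500,
) -> tuple[Genome, SimTruth]:
    """Insert the TE at each ``(chrom, tsd_start, orientation)`` site.

    At a site with TSD starting at ``t`` the mutated chromosome is
    ``orig[1..t+tsd_len-1] + TE + orig[t..]`` — the ``tsd_len``-bp target
    sequence is duplicated on both sides of the TE.  Orientation ``'-'``
    reverse-complements the consensus; ``'tail_to_tail'`` plants two
    elements 3'-end to 3'-end (consensus followed by its reverse
    complement), the false-negative class of a 3'-only primer design.
    """
    truth = SimTruth()
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, t, orient in sites:
        if orient not in ("+", "-", "tail_to_tail"):
            raise ValueError(f"bad orientation {orient!r}")
        clen = genome.length(chrom)
        if t - 1 < min_flank or t + tsd_len - 1 + min_flank > clen:
            raise ValueError(
                f"site {chrom}:{t} too near the chromosome end "
                f"(needs {min_flank} bp of flank on both sides)"
            )
        per_chrom.setdefault(chrom, []).append((t, orient))
    mutated: dict[str, str] = {}
    for chrom, seq in genome.sequences.items():
        chosen = sorted(per_chrom.get(chrom, []))
        for (t1, _), (t2, _) in zip(chosen, chosen[1:]):
            if t2 <= t1 + tsd_len - 1:
                raise ValueError(f"overlapping insertion sites at {chrom}:{t1}/{t2}")
        parts: list[str] = []
        prev = 0  # 0-based exclusive end of what has been emitted
        offset = 0
        for t, orient in chosen:
            b = t + tsd_len - 1
            if orient == "+":
                block = consensus_seq
            elif orient == "-":
                block = revcomp(consensus_seq)
            else:
                block = consensus_seq + revcomp(consensus_seq)
            parts.append(seq[prev:b])
            te_start_mut = b + offset + 1
            parts.append(block)
            prev = t - 1  # re-emit the TSD after the TE
            truth.insertions.append(
                PlantedInsertion(
                    chrom=chrom,
                    tsd_start=t,
                    tsd_len=tsd_len,
                    orientation=orient,
                    te_start_mut=te_start_mut,
                    te_end_mut=te_start_mut + len(block) - 1,
                )
            )
            offset += len(block) + tsd_len
        parts.append(seq[prev:])
        mutated[chrom] = "".join(parts)
    return Genome(mutated), truth


def primer_site_distances(
    flank_read: str, pentamer: str, cfg: SimConfig
) -> list[int]:
    """Genomic amplicon lengths at which ``pentamer`` primes on this flank.

    ``flank_read`` is the flank in read orientation (walking away from the
    TE 3' junction).  The amplicon terminates where the reverse complement of
    the pentamer occurs, so the distance ``d`` (junction to amplicon end)
    satisfies ``amplicon_min <= prefix_len + d <= amplicon_max``.
    """
    target = revcomp(pentamer)
    lo = cfg.amplicon_min - cfg.prefix_len
    hi = cfg.amplicon_max - cfg.prefix_len
    out = []
    start = 0
    while True:
        idx = flank_read.find(target, start)
        if idx == -1:
            break
        d = idx + len(target)
        if lo <= d <= hi:
            out.append(d)
        start = idx + 1
    return out


def _junctions(ins: PlantedInsertion, consensus_len: int) -> list[tuple[int, int]]:
    """(flank_start_mut, step) for each TE 3' end of a planted element."""
    if ins.orientation == "+":
        return [(ins.te_end_mut + 1, +1)]
    if ins.orientation == "-":
        return [(ins.te_start_mut - 1, -1)]
    # tail-to-tail: both 3' termini are internal, facing the partner element
    mid = ins.te_start_mut + consensus_len
    return [(mid, +1), (mid - 1, -1)]


def _flank_read(seq: str, flank_start: int, step: int, n: int) -> str:
    """Flank sequence in read orientation (1-based ``flank_start``)."""
    if step == +1:
        return seq[flank_start - 1 : flank_start - 1 + n]
    lo = max(0, flank_start - n)
    return revcomp(seq[lo:flank_start])


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_hemi_reads(
    mut_genome: Genome,
    truth: SimTruth,
    consensus_seq: str,
    cfg: SimConfig,
    reads_per_site: int = 30,
) -> dict[str, list[ReadPairRecord]]:
    """Simulate one hemi-specific library per degenerate primer.

    For every planted TE 3' junction and every primer whose pentamer primes
    the flank within the amplicon size window, ``reads_per_site`` read pairs
    are emitted: read-1 is the ``prefix_len``-nt consensus 3' terminus
    followed by flanking sequence, read-2 reads back from the primer end;
    both truncated to ``read_len``.  Substitution errors are applied at the
    combined polymerase + sequencer rate.  Deterministic under ``cfg.seed``.

    Updates ``truth.provenance`` and ``truth.library_totals`` in place.
    """
    rng = np.random.default_rng(cfg.seed)
    suffix = consensus_seq[-cfg.prefix_len:]
    rate = cfg.sub_rate
    libs: dict[str, list[ReadPairRecord]] = {lib: [] for lib in cfg.libraries}
    max_d = cfg.amplicon_max - cfg.prefix_len
    for idx, ins in enumerate(truth.insertions):
        seq = mut_genome.sequences[ins.chrom]
        emitted = 0
        for jx, (flank_start, step) in enumerate(_junctions(ins, len(consensus_seq))):
            flank = _flank_read(seq, flank_start, step, max_d)
            for lib, pentamer in zip(cfg.libraries, cfg.pentamers):
                for d in primer_site_distances(flank, pentamer, cfg):
                    amplicon = suffix + flank[:d]
                    r1 = amplicon[: cfg.read_len]
                    r2 = revcomp(amplicon)[: cfg.read_len]
                    for i in range(reads_per_site):
                        read_id = f"{lib}|ins{idx}|j{jx}|d{d}|{i}"
                        pair = ReadPairRecord(
                            read_id=read_id,
                            seq1=_apply_errors(r1, rate, rng),
                            seq2=_apply_errors(r2, rate, rng),
                            qual1="I" * len(r1),
                            qual2="I" * len(r2),
                            library_id=lib,
                        )
                        libs[lib].append(pair)
                        truth.provenance[read_id] = (idx, lib)
                        emitted += 1
        if emitted == 0:
            logger.warning(
                "no primer matches any flank of insertion %s:%s; zero reads",
                ins.chrom, ins.tsd_start,
            )
    truth.library_totals = {lib: len(pairs) for lib, pairs in libs.items()}
    return libs


def pick_insertion_sites(
    genome: Genome,
    cfg: SimConfig,
    n_sites: int,
    seed: int = 0,
    tsd_len: int = 8,
    min_flank: int = 500,
    min_primer_sites: int = 1,
    orientations: tuple[str, ...] = ("+", "-"),
    max_tries: int = 20000,
) -> list[tuple[str, int, str]]:
    """Choose ``n_sites`` plantable sites with unambiguous TSDs.

    A site qualifies when it leaves ``min_flank`` room on both sides, the
    base preceding the TSD differs from the base following it (so the
    duplicated-sequence length is exactly ``tsd_len``), at least
    ``min_primer_sites`` primer pentamers prime the 3' flank within the
    amplicon window, and it does not collide with a previously chosen site.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    chosen: list[tuple[str, int, str]] = []
    taken: dict[str, list[int]] = {c: [] for c in chroms}
    max_d = cfg.amplicon_max - cfg.prefix_len
    spacing = 2 * (max_d + min_flank)
    for k in range(max_tries):
        if len(chosen) >= n_sites:
            break
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        seq = genome.sequences[chrom]
        clen = len(seq)
        if clen < 2 * min_flank + tsd_len + 2:
            continue
        t = int(rng.integers(min_flank + 1, clen - tsd_len - min_flank + 1))
        orient = orientations[len(chosen) % len(orientations)]
        if any(abs(t - u) < spacing for u in taken[chrom]):
            continue
        if seq[t - 2] == seq[t + tsd_len - 1]:  # base before TSD vs base after it
            continue
        b = t + tsd_len - 1
        if orient == "+":
            flank = seq[t - 1 : t - 1 + max_d]
        else:
            flank = revcomp(seq[max(0, b - max_d) : b])
        n_hits = sum(
            len(primer_site_distances(flank, p, cfg)) > 0
            for p in cfg.pentamers[: cfg.n_primers]
        )
        if n_hits < min_primer_sites:
            continue
        chosen.append((chrom, t, orient))
        taken[chrom].append(t)
    if len(chosen) < n_sites:
        raise RuntimeError(f"found only {len(chosen)}/{n_sites} usable sites")
    return chosen


# ---------------------------------------------------------------------------
# WGS simulation
# ---------------------------------------------------------------------------


def simulate_wgs_pairs(
    genome_ref: Genome,
    genome_ins: Genome,
    freq: float,
    coverage: float,
    insert_mean: float = 300.0,
    insert_sd: float = 50.0,
    read_len: int = 100,
    seed: int = 0,
    error_rate: float = 0.001,
) -> tuple[list[ReadPairRecord], SimTruth]:
    """Simulate WGS read pairs from a ref/inserted haplotype mixture.

    Each fragment comes from the inserted haplotype with probability
    ``freq``; fragment length is Normal(``insert_mean``, ``insert_sd``)
    truncated to at least ``2 * read_len``.  Fragment provenance (haplotype,
    chromosome, 1-based span in that haplotype) is recorded in the returned
    :class:`SimTruth`.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must lie in [0, 1]")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    n_frags = int(round(coverage * genome_ref.total_length / (2 * read_len)))
    truth = SimTruth()
    pairs: list[ReadPairRecord] = []
    haps = {"ref": genome_ref, "ins": genome_ins}
    for name, g in haps.items():
        chroms = list(g.sequences)
        lens = np.array([g.length(c) for c in chroms], dtype=float)
        haps[name] = (g, chroms, lens / lens.sum())
    for i in range(n_frags):
        hap = "ins" if rng.random() < freq else "ref"
        g, chroms, w = haps[hap]
        chrom = chroms[rng.choice(len(chroms), p=w)]
        clen = g.length(chrom)
        flen = int(round(rng.normal(insert_mean, insert_sd)))
        flen = max(2 * read_len, min(flen, clen))
        start = int(rng.integers(1, clen - flen + 2))
        end = start + flen - 1
        frag = g.fetch(chrom, start, end)
        r1 = _apply_errors(frag[:read_len], error_rate, rng)
        r2 = _apply_errors(revcomp(frag[-read_len:]), error_rate, rng)
        read_id = f"wgs|{i}|{hap}|{chrom}|{start}|{end}"
        pairs.append(
            ReadPairRecord(
                read_id=read_id, seq1=r1, seq2=r2,
                qual1="I" * len(r1), qual2="I" * len(r2), library_id="wgs",
            )
        )
        truth.fragments.append((hap, chrom, start, end))
        truth.provenance[read_id] = (0 if hap == "ins" else -1, "wgs")
    return pairs, truth


def _mate_covers(lo: int, hi: int, junction: int, margin: int) -> bool:
    return lo <= junction - margin + 1 and hi >= junction + margin


def truth_junction_support(
    truth: SimTruth,
    insertion: PlantedInsertion,
    read_len: int,
    margin: int = 5,
) -> tuple[int, int]:
    """Truth counts of junction-spanning WGS fragments for one insertion.

    A fragment supports the inserted allele when one of its mates covers at
    least ``margin`` bases on both sides of either TE junction (mutated
    coordinates); it supports the reference allele when a mate covers both
    sides of the breakpoint (original coordinates).  Mirrors the spanning
    rules the frequency estimator applies to alignments.
    """
    n_ins = n_ref = 0
    j5, j3 = insertion.junction5_mut, insertion.junction3_mut
    b = insertion.breakpoint
    for hap, chrom, start, end in truth.fragments:
        if chrom != insertion.chrom:
            continue
        mates = ((start, start + read_len - 1), (end - read_len + 1, end))
        if hap == "ins":
            if any(
                _mate_covers(lo, hi, j, margin)
                for lo, hi in mates
                for j in (j5, j3)
            ):
                n_ins += 1
        else:
            if any(_mate_covers(lo, hi, b, margin) for lo, hi in mates):
                n_ref += 1
    return n_ins, n_ref
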
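import numpy as np
import pytest
import scipy.stats as st
from conftest import random_seq

from hemitect.io_formats import revcomp
from hemitect.simulate import (
    SimConfig,
    pick_insertion_sites,
    plant_insertions,
    random_genome,
    simulate_hemi_reads,
    simulate_wgs_pairs,
    synthetic_consensus,
    truth_junction_support,
)


class TestPlantInsertions:
    def test_empty_site_list_is_identity(self, toy_genome, consensus_seq):
        mut, truth = plant_insertions(toy_genome, consensus_seq, [])
        assert mut.sequences == toy_genome.sequences
        assert truth.insertions == []

    def test_single_insertion_length_bookkeeping(self, toy_genome, consensus_seq):
        mut, _ = plant_insertions(toy_genome, consensus_seq, [("chrA", 5000, "+")])
        assert mut.length("chrA") == toy_genome.length("chrA") + len(consensus_seq) + 8
        assert mut.length("chrB") == toy_genome.length("chrB")

    def test_tsd_duplicated_on_both_sides(self, toy_genome, consensus_seq):
        mut, truth = plant_insertions(toy_genome, consensus_seq, [("chrA", 5000, "+")])
        ins = truth.insertions[0]
        before = mut.fetch("chrA", ins.te_start_mut - 8, ins.te_start_mut - 1)
        after = mut.fetch("chrA", ins.te_end_mut + 1, ins.te_end_mut + 8)
        assert before == after == toy_genome.fetch("chrA", 5000, 5007)

    def test_recovered_tsd_length_is_eight(self, consensus_seq):
        """The longest identical sequence ending just before the TE and
        starting just after it has exactly the planted TSD length when the
        site's flanking bases differ."""
        cfg = SimConfig(seed=0)
        genome = random_genome({"c": 30_000}, seed=9)
        (site,) = pick_insertion_sites(genome, cfg, 1, seed=10)
        mut, truth = plant_insertions(genome, consensus_seq, [site])
        ins = truth.insertions[0]
        seq = mut.sequences[ins.chrom]
        up_end = ins.te_start_mut - 1  # 0-based exclusive end of upstream flank
        down_start = ins.te_end_mut  # 0-based first base after the TE
        L = max(
            l
            for l in range(0, 30)
            if seq[up_end - l : up_end] == seq[down_start : down_start + l]
        )
        assert L == 8

    def test_oriented_te_sequence_placed_between_tsds(self, toy_genome, consensus_seq):
        mut, truth = plant_insertions(
            toy_genome, consensus_seq, [("chrA", 5000, "+"), ("chrB", 7000, "-")]
        )
        plus, minus = truth.insertions
        assert mut.fetch("chrA", plus.te_start_mut, plus.te_end_mut) == consensus_seq
        assert mut.fetch("chrB", minus.te_start_mut, minus.te_end_mut) == revcomp(
            consensus_seq
        )

    def test_downstream_coordinates_shift_with_multiple_insertions(
        self, toy_genome, consensus_seq
    ):
        sites = [("chrA", 5000, "+"), ("chrA", 20_000, "-")]
        mut, truth = plant_insertions(toy_genome, consensus_seq, sites)
        first, second = truth.insertions
        shift = len(consensus_seq) + 8
        assert second.te_start_mut == 20_000 + 8 + shift
        assert mut.fetch("chrA", second.te_start_mut, second.te_end_mut) == revcomp(
            consensus_seq
        )

    def test_overlapping_sites_rejected(self, toy_genome, consensus_seq):
        with pytest.raises(ValueError, match="overlap"):
            plant_insertions(
                toy_genome, consensus_seq, [("chrA", 5000, "+"), ("chrA", 5004, "+")]
            )

    def test_site_near_chromosome_end_rejected(self, toy_genome, consensus_seq):
        with pytest.raises(ValueError, match="near the chromosome end"):
            plant_insertions(toy_genome, consensus_seq, [("chrA", 120, "+")])


class TestHemiReads:
    def test_no_insertions_yields_no_reads(self, toy_genome, consensus_seq,
                                           errorfree_cfg):
        mut, truth = plant_insertions(toy_genome, consensus_seq, [])
        libs = simulate_hemi_reads(mut, truth, consensus_seq, errorfree_cfg)
        assert sum(len(v) for v in libs.values()) == 0

    def _simulated(self, consensus_seq, cfg, n=4, seed=21):
        genome = random_genome({"chrA": 80_000}, seed=seed)
        sites = pick_insertion_sites(genome, cfg, n, seed=seed + 1)
        mut, truth = plant_insertions(genome, consensus_seq, sites)
        libs = simulate_hemi_reads(mut, truth, consensus_seq, cfg, reads_per_site=5)
        return genome, mut, truth, libs

    def test_error_free_read1_starts_with_terminal_52mer(
        self, consensus_seq, errorfree_cfg
    ):
        *_, libs = self._simulated(consensus_seq, errorfree_cfg)
        pairs = [p for ps in libs.values() for p in ps]
        assert pairs
        assert all(p.seq1.startswith(consensus_seq[-52:]) for p in pairs)

    def test_truth_recovery_by_exact_string_search(self, consensus_seq, errorfree_cfg):
        """The genomic portion of every error-free read-1 places the planted
        breakpoint at leftmost+7 (plus) or rightmost (minus)."""
        genome, mut, truth, libs = self._simulated(consensus_seq, errorfree_cfg)
        checked = 0
        for ps in libs.values():
            for p in ps:
                ins = truth.insertions[truth.provenance[p.read_id][0]]
                genomic = p.seq1[52:]
                seq = genome.sequences[ins.chrom]
                if ins.orientation == "+":
                    pos = seq.find(genomic)
                    assert pos >= 0 and seq.find(genomic, pos + 1) == -1
                    assert (pos + 1) + 7 == ins.breakpoint
                else:
                    rc = revcomp(genomic)
                    pos = seq.find(rc)
                    assert pos >= 0 and seq.find(rc, pos + 1) == -1
                    assert pos + len(rc) == ins.breakpoint
                checked += 1
        assert checked >= 40

    def test_reads_scale_linearly_with_depth(self, consensus_seq, errorfree_cfg):
        genome = random_genome({"chrA": 80_000}, seed=21)
        sites = pick_insertion_sites(genome, errorfree_cfg, 3, seed=22)
        mut, truth = plant_insertions(genome, consensus_seq, sites)
        n10 = sum(
            len(v) for v in simulate_hemi_reads(
                mut, truth, consensus_seq, errorfree_cfg, reads_per_site=10
            ).values()
        )
        n20 = sum(
            len(v) for v in simulate_hemi_reads(
                mut, truth, consensus_seq, errorfree_cfg, reads_per_site=20
            ).values()
        )
        assert n20 == 2 * n10 > 0

    def test_bit_reproducible_under_fixed_seed(self, consensus_seq):
        cfg = SimConfig(seed=77)
        a = self._simulated(consensus_seq, cfg)[3]
        b = self._simulated(consensus_seq, cfg)[3]
        assert {k: [(p.read_id, p.seq1, p.seq2) for p in v] for k, v in a.items()} == {
            k: [(p.read_id, p.seq1, p.seq2) for p in v] for k, v in b.items()
        }

    def test_library_totals_recorded(self, consensus_seq, errorfree_cfg):
        *_, truth, libs = self._simulated(consensus_seq, errorfree_cfg)
        assert truth.library_totals == {k: len(v) for k, v in libs.items()}


class TestWgs:
    @pytest.fixture()
    def small_pair(self, consensus_seq):
        genome = random_genome({"w": 12_000}, seed=31)
        cfg = SimConfig(seed=0)
        (site,) = pick_insertion_sites(genome, cfg, 1, seed=32)
        mut, truth = plant_insertions(genome, consensus_seq, [site])
        return genome, mut, truth

    def test_freq_zero_draws_only_reference_fragments(self, small_pair):
        genome, mut, _ = small_pair
        _, truth = simulate_wgs_pairs(genome, mut, 0.0, 20, seed=1)
        assert all(f[0] == "ref" for f in truth.fragments)

    def test_freq_one_junction_pairs_carry_te_sequence(
        self, small_pair, consensus_seq
    ):
        genome, mut, ptruth = small_pair
        ins = ptruth.insertions[0]
        pairs, truth = simulate_wgs_pairs(
            genome, mut, 1.0, 30, seed=2, error_rate=0.0
        )
        n_checked = 0
        for pair, frag in zip(pairs, truth.fragments):
            hap, chrom, start, end = frag
            assert hap == "ins"
            # a mate fully inside the TE block must be pure consensus sequence
            if start >= ins.te_start_mut and start + 99 <= ins.te_end_mut:
                assert pair.seq1 in consensus_seq or revcomp(pair.seq1) in consensus_seq
                n_checked += 1
        assert n_checked > 0

    def test_truth_fraction_within_binomial_ci_at_half(self, small_pair):
        genome, mut, ptruth = small_pair
        ins = ptruth.insertions[0]
        pairs, truth = simulate_wgs_pairs(genome, mut, 0.5, 80, seed=3)
        n_ins, n_ref = truth_junction_support(truth, ins, read_len=100)
        n = n_ins + n_ref
        assert n > 20
        lo, hi = st.binom.interval(0.99, n, 0.5)
        # the *haplotype* draw is Bernoulli(0.5); junction ascertainment is
        # asymmetric, so compare the haplotype counts, not the support counts
        hap_ins = sum(f[0] == "ins" for f in truth.fragments)
        lo_h, hi_h = st.binom.interval(0.99, len(truth.fragments), 0.5)
        assert lo_h <= hap_ins <= hi_h

    def test_coverage_zero_rejected(self, small_pair):
        genome, mut, _ = small_pair
        with pytest.raises(ValueError):
            simulate_wgs_pairs(genome, mut, 0.5, 0)
        with pytest.raises(ValueError):
            simulate_wgs_pairs(genome, mut, 1.5, 10)
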
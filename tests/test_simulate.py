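"""Synthetic genome, read-pair and contig simulators."""

import numpy as np
import pytest
from scipy import stats

from asmbench.simulate import (
    INSERT_PRESETS,
    ContigEvent,
    FragmentModel,
    QualityModel,
    RepeatSpec,
    gc_fraction,
    revcomp,
    simulate_contigs,
    simulate_genome,
    simulate_read_pairs,
)
from asmbench.seqio import write_paired_fastq


class TestSimulateGenome:
    @pytest.mark.parametrize("gc", [0.354, 0.522, 0.730])
    def test_gc_within_tolerance(self, gc):
        g = simulate_genome(100_000, gc, seed=1)
        assert abs(g.gc - gc) <= 0.02
        assert g.length == 100_000

    def test_repeat_copies_are_exact_duplicates(self):
        g = simulate_genome(50_000, 0.5, [RepeatSpec(5000, 2)], seed=7)
        seq = g.replicons[0][1]
        c1, c2 = g.repeat_copies
        assert seq[c1.start : c1.end] == seq[c2.start : c2.end]
        assert c1.end - c1.start == 5000

    def test_deterministic(self):
        a = simulate_genome(20_000, 0.45, [RepeatSpec(1000, 2)], seed=3)
        b = simulate_genome(20_000, 0.45, [RepeatSpec(1000, 2)], seed=3)
        assert a.replicons == b.replicons and a.repeat_copies == b.repeat_copies

    def test_multi_replicon_lengths_sum(self):
        g = simulate_genome(30_001, 0.5, seed=1, n_replicons=3)
        assert g.length == 30_001
        assert len(g.replicons) == 3

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(length=5000, target_gc=0.5),
            dict(length=20_000, target_gc=0.1),
            dict(length=20_000, target_gc=0.9),
            dict(length=20_000, target_gc=0.5, repeat_plan=[RepeatSpec(6000, 2)]),
        ],
    )
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genome(seed=1, **kwargs)


class TestFragmentModel:
    def test_presets_carry_category_means(self):
        means = {k: fm.mean_insert for k, fm in INSERT_PRESETS.items()}
        assert means == {"TS": 641, "IS1": 686, "IS2": 990, "IS3": 1211, "IS4": 1297}
        # pairs at 2x200 never overlap for any preset
        assert all(fm.mean_insert > 2 * 200 for fm in INSERT_PRESETS.values())
        assert INSERT_PRESETS["TS"].shape == "left_tailed"

    @pytest.mark.parametrize("cat", ["TS", "IS1"])
    def test_sampled_fragments_match_specified_distribution(self, cat):
        # Kolmogorov-Smirnov distance below 0.05 at n = 1e4
        fm = INSERT_PRESETS[cat]
        rng = np.random.default_rng(11)
        draws = np.rint(fm.sample(10_000, rng))
        ks = stats.kstest(draws, fm.frozen_dist().cdf).statistic
        assert ks < 0.05

    def test_left_tailed_moments_and_skew(self):
        fm = INSERT_PRESETS["TS"]
        rng = np.random.default_rng(4)
        draws = fm.sample(50_000, rng)
        assert abs(draws.mean() - fm.mean_insert) < 1.0
        assert abs(draws.std() - fm.sd) < 1.0
        assert stats.skew(draws) < -0.5

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            FragmentModel(600, shape="bimodal").frozen_dist()


class TestSimulateReadPairs:
    def test_fr_orientation_against_truth(self, genome_low_gc, flat_quality):
        pairs = simulate_read_pairs(
            genome_low_gc, 50, 100, INSERT_PRESETS["IS1"], flat_quality, seed=3
        )
        seq = genome_low_gc.replicons[0][1]
        for p in pairs:
            t = p.truth
            assert t.length == t.end - t.start
            assert p.mate1_seq == seq[t.start : t.start + 100]
            assert p.mate2_seq == revcomp(seq[t.end - 100 : t.end])
            assert len(p.mate1_quals) == len(p.mate1_seq) == 100

    def test_empirical_mean_insert_near_preset(self, genome_low_gc, flat_quality):
        fm = INSERT_PRESETS["IS1"]
        pairs = simulate_read_pairs(genome_low_gc, 10_000, 189, fm, flat_quality, seed=3)
        inserts = np.array([p.truth.length for p in pairs])
        se = fm.sd / np.sqrt(len(pairs))
        assert abs(inserts.mean() - fm.mean_insert) < 3.5 * se

    def test_degenerate_quality_model_gives_flat_phred(self, genome_low_gc, flat_quality):
        pairs = simulate_read_pairs(
            genome_low_gc, 20, 50, INSERT_PRESETS["IS1"], flat_quality, seed=1
        )
        for p in pairs:
            assert (p.mate1_quals == 30).all() and (p.mate2_quals == 30).all()

    def test_qualities_clamped(self, genome_high_gc):
        qm = QualityModel(noise_sd=15.0)
        pairs = simulate_read_pairs(
            genome_high_gc, 200, 189, INSERT_PRESETS["IS3"], qm, seed=2
        )
        q = np.concatenate([p.mate1_quals for p in pairs])
        assert q.min() >= 2 and q.max() <= 40

    def test_same_seed_gives_identical_fastq(self, genome_low_gc, tmp_path):
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            pairs = simulate_read_pairs(
                genome_low_gc, 100, 75, INSERT_PRESETS["TS"], seed=9
            )
            write_paired_fastq(pairs, tmp_path / d / "r_1.fastq", tmp_path / d / "r_2.fastq")
        for m in ("r_1.fastq", "r_2.fastq"):
            assert (tmp_path / "a" / m).read_bytes() == (tmp_path / "b" / m).read_bytes()

    def test_expected_quality_decreases_along_read(self):
        qm = QualityModel()
        qs = [qm.expected_quality(c, gc=0.6, insert_bp=900) for c in range(189)]
        assert all(a > b for a, b in zip(qs, qs[1:]))

    def test_replicon_shorter_than_fragment_rejected(self, flat_quality):
        g = simulate_genome(10_000, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_read_pairs(g, 10, 11_000, INSERT_PRESETS["IS1"], flat_quality, seed=1)


class TestSimulateContigs:
    def test_event_free_contigs_are_exact_substrings(self, genome_low_gc):
        cs = simulate_contigs(genome_low_gc, 10, [], min_len=1000, seed=4)
        seq = genome_low_gc.replicons[0][1]
        assert len(cs.contigs) == 10 and not cs.injected_events
        for name, contig in cs.contigs:
            blocks = cs.truth_blocks[name]
            assert len(blocks) == 1 and blocks[0].strand == "+"
            assert contig in seq

    def test_inversion_yields_two_blocks_opposite_strands(self, genome_low_gc):
        cs = simulate_contigs(
            genome_low_gc, 1, [ContigEvent(0, "inversion")], min_len=1500, seed=4
        )
        blocks = cs.truth_blocks["contig_1"]
        assert len(blocks) == 2
        assert {b.strand for b in blocks} == {"+", "-"}
        assert len(cs.injected_events) == 1

    def test_two_translocations_alternate_replicons(self, genome_two_replicons):
        cs = simulate_contigs(
            genome_two_replicons,
            1,
            [ContigEvent(0, "translocation"), ContigEvent(0, "translocation")],
            min_len=1500,
            seed=4,
        )
        blocks = cs.truth_blocks["contig_1"]
        assert len(blocks) == 3
        assert blocks[0].replicon != blocks[1].replicon
        assert blocks[1].replicon != blocks[2].replicon

    def test_junction_count_matches_events(self, genome_two_replicons):
        events = [
            ContigEvent(0, "relocation_gap", gap=5000),
            ContigEvent(1, "inversion"),
            ContigEvent(1, "translocation"),
        ]
        cs = simulate_contigs(genome_two_replicons, 3, events, min_len=1200, seed=8)
        assert len(cs.injected_events) == 3
        assert len(cs.truth_blocks["contig_1"]) == 2
        assert len(cs.truth_blocks["contig_2"]) == 3
        assert len(cs.truth_blocks["contig_3"]) == 1

    def test_contig_sequence_matches_truth_blocks(self, genome_two_replicons):
        cs = simulate_contigs(
            genome_two_replicons, 2, [ContigEvent(0, "inversion")], min_len=1000, seed=3
        )
        seqs = dict(genome_two_replicons.replicons)
        for name, contig in cs.contigs:
            for b in cs.truth_blocks[name]:
                ref = seqs[b.replicon][b.r_start : b.r_end]
                if b.strand == "-":
                    ref = revcomp(ref)
                assert contig[b.c_start : b.c_end] == ref

    def test_absent_replicon_rejected(self, genome_low_gc):
        with pytest.raises(ValueError, match="replicon"):
            simulate_contigs(
                genome_low_gc, 1, [ContigEvent(0, "translocation", replicon="nope")], seed=1
            )

    def test_deterministic(self, genome_low_gc):
        a = simulate_contigs(genome_low_gc, 4, [ContigEvent(0, "inversion")], seed=6)
        b = simulate_contigs(genome_low_gc, 4, [ContigEvent(0, "inversion")], seed=6)
        assert a == b


def test_gc_fraction_and_revcomp_roundtrip():
    assert gc_fraction("GGCCAATT") == 0.5
    assert revcomp("ACGTT") == "AACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
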
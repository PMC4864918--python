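"""Factorial design bookkeeping, optimal selection, scores and orchestration."""

import random

import pytest

from asmbench.evaluate import (
    AssemblyCandidate,
    EntryKey,
    ExternalAssemblerAdapter,
    FactorDesign,
    GenomeDesign,
    GenomeSpec,
    PrecomputedContigProvider,
    StudyConfig,
    SubLibraryKey,
    ValidationEntry,
    aggregate_triplicate,
    default_design,
    default_study_config,
    design_counts,
    enumerate_design,
    relative_scores,
    run_factor_study,
    select_optimal,
    top_fraction,
)
from asmbench.metrics import AssemblyMetrics
from asmbench.simulate import RepeatSpec


def _metrics(corr, nga):
    return AssemblyMetrics(
        n_contigs=10, total_len=100_000, avg_contig=10_000.0, n50=corr,
        ng50=corr, corrected_ng50=corr, nga50=nga, n_breaks=0,
    )


def _entry(genome="G", assembler="spades", category="IS1", rl=189, depth=45.0,
           corr=100.0, nga=90.0):
    return ValidationEntry(genome, assembler, category, rl, depth, corr, nga, 3, 3, 3, False)


class TestDesign:
    def test_default_design_counts(self):
        design = default_design()
        counts = design_counts(design)
        assert counts == {"Bce": 90, "Efa": 90, "Sen": 30, "Pst": 90, "total": 300}
        keys = enumerate_design(design)
        assert len(keys) == 300
        cells = {(k.genome, k.category, k.read_length, k.depth) for k in keys}
        assert len(cells) == 100  # 100 triplicates
        assert len(cells) * 4 == 400  # validation entries over four assemblers
        assert len(keys) * 4 == 1200  # optimal assemblies

    def test_minimal_design(self):
        d = FactorDesign(
            genomes={"g": GenomeDesign(("IS1",), (45.0,))}, read_lengths=(100,), replicates=3
        )
        keys = enumerate_design(d)
        assert len(keys) == 3
        assert {k.replicate for k in keys} == {1, 2, 3}

    def test_empty_factor_sets_rejected(self):
        with pytest.raises(ValueError):
            GenomeDesign((), (45.0,))


class TestSelectOptimal:
    def test_largest_n50_wins(self):
        a = AssemblyCandidate(21, 100, 50, 4000.0)
        b = AssemblyCandidate(31, 120, 60, 3000.0)
        assert select_optimal([a, b]) is b

    def test_ties_broken_by_fewer_contigs_then_avg(self):
        a = AssemblyCandidate(21, 100, 40, 4000.0)
        b = AssemblyCandidate(31, 100, 35, 3500.0)
        assert select_optimal([a, b]) is b
        c = AssemblyCandidate(41, 100, 35, 4500.0)
        assert select_optimal([b, c]) is c

    def test_residual_tie_smallest_label(self):
        a = AssemblyCandidate(41, 100, 35, 4500.0)
        b = AssemblyCandidate(21, 100, 35, 4500.0)
        assert select_optimal([a, b]).label == 21

    def test_invariant_to_ordering(self):
        rng = random.Random(0)
        cands = [
            AssemblyCandidate(k, n50, nc, avg)
            for k, n50, nc, avg in [
                (21, 90, 40, 4000.0), (23, 100, 35, 4100.0), (25, 100, 35, 4500.0),
                (27, 100, 40, 9000.0), (29, 80, 10, 9000.0),
            ]
        ]
        winner = select_optimal(cands)
        for _ in range(20):
            rng.shuffle(cands)
            assert select_optimal(cands) is winner

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_optimal([])


class TestAggregate:
    def test_mean_of_three(self):
        key = EntryKey("G", "spades", "IS1", 189, 45.0)
        recs = [(key, _metrics(c, c - 10)) for c in (100, 200, 300)]
        e = aggregate_triplicate(recs, 3)
        assert e.mean_corrected_ng50 == 200 and e.mean_nga50 == 190
        assert not e.flagged

    def test_identical_replicates(self):
        key = EntryKey("G", "spades", "IS1", 189, 45.0)
        e = aggregate_triplicate([(key, _metrics(150, 150))] * 3, 3)
        assert e.mean_corrected_ng50 == 150

    def test_replicate_count_mismatch_rejected(self):
        key = EntryKey("G", "spades", "IS1", 189, 45.0)
        with pytest.raises(ValueError, match="replicates"):
            aggregate_triplicate([(key, _metrics(1, 1))] * 2, 3)

    def test_key_mismatch_rejected(self):
        k1 = EntryKey("G", "spades", "IS1", 189, 45.0)
        k2 = EntryKey("G", "spades", "IS1", 189, 90.0)
        with pytest.raises(ValueError, match="key mismatch"):
            aggregate_triplicate([(k1, _metrics(1, 1)), (k1, _metrics(1, 1)), (k2, _metrics(1, 1))], 3)

    def test_undefined_metric_flagged_and_excluded(self):
        key = EntryKey("G", "spades", "IS1", 189, 45.0)
        m_na = AssemblyMetrics(5, 1000, 200.0, 300, None, None, None, 0)
        e = aggregate_triplicate([(key, _metrics(100, 100)), (key, _metrics(200, 200)), (key, m_na)], 3)
        assert e.flagged and e.n_defined_corrected == 2
        assert e.mean_corrected_ng50 == 150


class TestScores:
    def test_table_ratio_mirrors_published_arithmetic(self):
        entries = [
            _entry(assembler="spades", corr=448_776.0, nga=448_776.0),
            _entry(assembler="abyss", corr=309_655.0, nga=309_655.0),
        ]
        t = relative_scores(entries, "assembler", "by_genome")
        s = dict(zip(t.data.manifestation, t.data.s_corrected))
        assert s["spades"] == pytest.approx(1.0)
        assert s["abyss"] == pytest.approx(0.69, abs=0.005)
        assert t.data.max_abs_corrected.iloc[0] == pytest.approx(448_776.0)

    def test_equal_means_all_score_one(self):
        entries = [_entry(category="TS"), _entry(category="IS1")]
        t = relative_scores(entries, "category")
        assert (t.data.s_corrected == 1.0).all() and (t.data.s_nga == 1.0).all()

    def test_scores_in_unit_interval_with_max_one(self):
        entries = [
            _entry(category=c, corr=v, nga=v / 2)
            for c, v in [("TS", 50.0), ("IS1", 80.0), ("IS2", 120.0)]
        ]
        t = relative_scores(entries, "category")
        assert ((t.data.s_corrected > 0) & (t.data.s_corrected <= 1)).all()
        assert t.data.groupby("genome").s_corrected.max().eq(1.0).all()

    def test_single_manifestation_rejected(self):
        with pytest.raises(ValueError, match="manifestations"):
            relative_scores([_entry(), _entry()], "category")

    def test_top_fraction_boundary_inclusive(self):
        entries = [
            _entry(assembler=a, rl=rl, corr=v, nga=v)
            for rl in (100, 189)
            for a, v in [("spades", 100.0), ("abyss", 94.0 if rl == 100 else 95.0)]
        ]
        t = relative_scores(entries, "read_length")
        # within each genome/assembler group there are two read lengths
        frac = top_fraction(t, threshold=0.95)
        assert set(frac.index) == {100, 189}
        assert 0.0 <= frac.frac_top_corrected_ng50.min()
        # a score of exactly 0.95 counts as top
        entries2 = [_entry(rl=100, corr=95.0), _entry(rl=189, corr=100.0)]
        t2 = relative_scores(entries2, "read_length")
        f2 = top_fraction(t2, 0.95)
        assert f2.loc[100, "frac_top_corrected_ng50"] == 1.0


@pytest.fixture()
def tiny_config():
    cfg = default_study_config(master_seed=7)
    cfg.genomes = [
        GenomeSpec(
            name="Bce", gc=0.354, length=30_000,
            categories=("TS", "IS2"), depths=(45.0,),
            repeats=(RepeatSpec(800, 3),),
        )
    ]
    cfg.read_lengths = (189,)
    cfg.assemblers = {"spades": 1.0}
    return cfg


class TestRunFactorStudy:
    def test_one_cell_design_yields_one_entry_per_assembler(self):
        cfg = default_study_config(master_seed=3)
        cfg.genomes = [cfg.genomes[0]]
        cfg.genomes[0].categories = ("IS1",)
        cfg.genomes[0].depths = (45.0,)
        cfg.read_lengths = (100,)
        report = run_factor_study(cfg)
        assert report.counts["validation_entries"] == len(cfg.assemblers)
        assert report.counts["sublibraries_total"] == 3

    def test_repeat_bridging_preset_scores_best(self, tiny_config):
        """Inserts longer than the planted repeat assemble the genome whole."""
        for seed in (1, 2, 3):
            report = run_factor_study(tiny_config, seed=seed)
            t = report.scores["category"].data
            s = dict(zip(t.manifestation, t.s_corrected))
            assert s["IS2"] == pytest.approx(1.0)  # 990 bp inserts bridge 800 bp repeats
            assert s["TS"] < 1.0  # 641 bp inserts cannot

    def test_rerun_same_seed_byte_identical_reports(self, tiny_config, tmp_path):
        for d in ("x", "y"):
            run_factor_study(tiny_config, seed=5).write(tmp_path / d)
        for name in ("validation_entries.tsv", "scores_category.tsv", "run_log.txt"):
            assert (tmp_path / "x" / name).read_bytes() == (tmp_path / "y" / name).read_bytes()

    def test_config_roundtrips_through_dict(self, tiny_config):
        clone = StudyConfig.from_dict(tiny_config.to_dict())
        assert clone.to_dict() == tiny_config.to_dict()

    def test_missing_precomputed_contigs_lists_keys(self, tiny_config):
        provider = PrecomputedContigProvider(contig_sets={})
        with pytest.raises(ValueError, match="no contig sets"):
            run_factor_study(tiny_config, provider=provider)


class TestExternalAdapter:
    def test_command_templating(self):
        ad = ExternalAssemblerAdapter(
            "{assembler} -1 {r1} -2 {r2} -o {out_dir}/{genome}_{category}_L{read_length}"
        )
        key = SubLibraryKey("Bce", "IS1", 150, 45.0, 2)
        cmd = ad.command_for(key, "spades", "a_1.fq", "a_2.fq", "out")
        assert cmd == "spades -1 a_1.fq -2 a_2.fq -o out/Bce_IS1_L150"

    def test_adapter_never_assembles_in_process(self):
        ad = ExternalAssemblerAdapter("x {r1}")
        with pytest.raises(RuntimeError):
            ad.provide(None, "spades", [], None)
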
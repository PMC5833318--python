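"""Synthetic-data generator: determinism, composition and round-trip."""

import numpy as np
import pytest

from macall import (
    SimulationConfig,
    build_catalog,
    generate_reference,
    plant_mutations,
    simulate_counts,
)
from macall.catalog import BPS, DELETION, INSERTION
from macall.fixture import STUDY_TOTALS, bps_class_counts, largest_remainder


class TestGenerateReference:
    def test_zero_coding_fraction_yields_no_genes(self):
        g = generate_reference(300, 0.5, 0.0, seed=1)
        assert g.genes == []

    def test_deterministic_for_fixed_seed(self):
        a = generate_reference(2000, 0.4, 0.5, seed=7)
        b = generate_reference(2000, 0.4, 0.5, seed=7)
        assert a.sequence == b.sequence
        assert a.genes == b.genes

    def test_gc_content_within_binomial_error(self):
        n, gc = 100_000, 0.6
        g = generate_reference(n, gc, 0.0, seed=5)
        sd = (gc * (1 - gc) / n) ** 0.5
        assert abs(g.gc_fraction() - gc) < 3 * sd

    def test_coding_fraction_approximate(self):
        g = generate_reference(50_000, 0.5, 0.7, seed=2)
        assert abs(g.coding_sites / g.length - 0.7) < 0.05

    def test_genes_do_not_overlap_and_have_codon_lengths(self):
        g = generate_reference(30_000, 0.5, 0.8, seed=3)
        for prev, cur in zip(g.genes, g.genes[1:]):
            assert cur.start > prev.end
        assert all(gene.length % 3 == 0 for gene in g.genes)

    @pytest.mark.parametrize("length,gc", [(100, 0.5), (1000, 0.0), (1000, 1.0)])
    def test_invalid_arguments_rejected(self, length, gc):
        with pytest.raises(ValueError):
            generate_reference(length, gc, 0.5, seed=1)


class TestPlantMutations:
    def test_exact_bps_count_single_line(self):
        g = generate_reference(50_000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=1, genome_length=g.length, n_bps=10, n_insertions=0,
            n_deletions=0, seed=9,
        )
        truth = plant_mutations(g, cfg)
        assert len(truth) == 10
        assert all(e.mtype == BPS for e in truth.events)

    def test_class_totals_conserved(self):
        g = generate_reference(80_000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=5, genome_length=g.length, n_bps=30, n_insertions=7,
            n_deletions=9, seed=4,
        )
        truth = plant_mutations(g, cfg)
        kinds = [e.mtype for e in truth.events]
        assert kinds.count(BPS) == 30
        assert kinds.count(INSERTION) == 7
        assert kinds.count(DELETION) == 9

    def test_clustered_pairs_within_window(self):
        g = generate_reference(100_000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=3, genome_length=g.length, n_bps=20, n_insertions=0,
            n_deletions=0, n_clustered_pairs=3, cluster_window=50, seed=8,
        )
        truth = plant_mutations(g, cfg)
        assert len(truth) == 23
        by_line = {}
        for e in truth.events:
            by_line.setdefault(e.line, []).append(e.position)
        n_close = 0
        for positions in by_line.values():
            positions.sort()
            n_close += sum(
                1 for a, b in zip(positions, positions[1:]) if b - a < 50
            )
        assert n_close == 3

    def test_request_exceeding_genome_rejected(self):
        g = generate_reference(1000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=1, genome_length=g.length, n_bps=5000, n_insertions=0,
            n_deletions=0, seed=1,
        )
        with pytest.raises(ValueError):
            plant_mutations(g, cfg)

    def test_bps_ref_matches_genome(self):
        g = generate_reference(50_000, 0.5, 0.0, seed=6)
        cfg = SimulationConfig(
            n_lines=2, genome_length=g.length, n_bps=25, n_insertions=0,
            n_deletions=0, seed=6,
        )
        truth = plant_mutations(g, cfg)
        for e in truth.events:
            assert g.base(e.position) == e.ref
            assert e.alt != e.ref


class TestSimulateCounts:
    def test_zero_error_counts_carry_only_true_allele(self):
        g = generate_reference(2000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=1, genome_length=g.length, coverage_mean=30, error_rate=0.0,
            n_bps=2, n_insertions=0, n_deletions=0, seed=2,
        )
        truth = plant_mutations(g, cfg)
        sd = simulate_counts(g, truth, cfg)
        a1, _ = sd.counts[cfg.line_ids[0]]
        counts4 = a1[:, 0::2] + a1[:, 1::2]
        nonzero_bases = (counts4 > 0).sum(axis=1)
        assert nonzero_bases.max() <= 1  # a single allele per site

    def test_error_fraction_matches_binomial_expectation(self):
        g = generate_reference(100_000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=1, genome_length=g.length, coverage_mean=20, error_rate=0.01,
            n_bps=0, n_insertions=0, n_deletions=0, seed=3,
        )
        sd = simulate_counts(g, plant_mutations(g, cfg), cfg)
        a1, _ = sd.counts[cfg.line_ids[0]]
        counts4 = a1[:, 0::2] + a1[:, 1::2]
        total = counts4.sum()
        ref_reads = np.take_along_axis(counts4, g.codes[:, None].astype(int), axis=1).sum()
        err_frac = 1 - ref_reads / total
        sd3 = 3 * (0.01 * 0.99 / total) ** 0.5
        assert abs(err_frac - 0.01) < sd3

    def test_identical_seed_reproduces_counts(self):
        g = generate_reference(3000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=2, genome_length=g.length, coverage_mean=25,
            n_bps=4, n_insertions=1, n_deletions=1, seed=17,
        )
        t = plant_mutations(g, cfg)
        s1 = simulate_counts(g, t, cfg)
        s2 = simulate_counts(g, t, cfg)
        for line in cfg.line_ids:
            assert np.array_equal(s1.counts[line][0], s2.counts[line][0])
            assert s1.evidence[line] == s2.evidence[line]

    def test_planted_indels_present_in_both_aligner_views(self, small_sim):
        for e in small_sim.truth.events:
            if e.mtype == BPS:
                continue
            ev = small_sim.evidence[e.line]
            pool = ev["paired"] if e.size >= small_sim.config.paired_evidence_min_size else ev["aligner1"]
            keys = {r.key for r in pool}
            assert (e.position, e.mtype, e.size, e.motif) in keys
            if e.size < small_sim.config.paired_evidence_min_size:
                assert (e.position, e.mtype, e.size, e.motif) in {
                    r.key for r in ev["aligner2"]
                }

    def test_full_discordance_removes_indels_from_second_aligner(self):
        g = generate_reference(20_000, 0.5, 0.0, seed=1)
        cfg = SimulationConfig(
            n_lines=2, genome_length=g.length, coverage_mean=50,
            n_bps=0, n_insertions=5, n_deletions=5, aligner_discordance=1.0, seed=5,
        )
        sd = simulate_counts(g, plant_mutations(g, cfg), cfg)
        for line in cfg.line_ids:
            assert sd.evidence[line]["aligner2"] == []


class TestFixtureCatalog:
    def test_total_event_counts(self, study_catalog):
        assert len(study_catalog.calls) == 885
        assert len(study_catalog.bps_calls()) == 779
        assert len(study_catalog.indel_calls()) == 106

    def test_single_large_deletion_in_one_line(self, study_catalog):
        big = [c for c in study_catalog.calls if c.size == 12_581]
        assert len(big) == 1
        assert big[0].mtype == "deletion"

    def test_inconsistent_marginals_rejected(self):
        bad = dict(STUDY_TOTALS, transitions=800)
        with pytest.raises(ValueError):
            build_catalog(bad)

    def test_class_split_respects_all_marginals(self):
        counts = bps_class_counts(STUDY_TOTALS)
        assert sum(counts.values()) == 779
        assert counts["G:C>A:T"] + counts["A:T>G:C"] == 558
        assert counts["G:C>A:T"] + counts["G:C>T:A"] == 533

    def test_deterministic(self):
        a, b = build_catalog(), build_catalog()
        assert a.to_frame().equals(b.to_frame())


class TestLargestRemainder:
    def test_sums_and_proportionality(self):
        alloc = largest_remainder(533, [558, 221])
        assert alloc == [382, 151]
        assert sum(largest_remainder(100, [1] * 7)) == 100

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            largest_remainder(5, [0, 0])
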
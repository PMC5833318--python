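"""Consensus caller: BPS criteria, indel criteria, progenitor filtering,
and structural properties (monotonicity, line-relabeling symmetry)."""

import numpy as np
import pytest

from macall import CallingThresholds, call_all_lines
from macall.calling import (
    call_bps,
    call_indels_consensus,
    call_indels_large,
    filter_progenitor,
)
from macall.catalog import MutationCall
from macall.pileio import IndelEvidence

T = CallingThresholds()
B = {"A": 0, "C": 1, "G": 2, "T": 3}


def counts_row(**reads):
    """8-vector from e.g. counts_row(C=48, c=50)."""
    row = np.zeros(8, dtype=np.int64)
    order = ["A", "a", "C", "c", "G", "g", "T", "t"]
    for k, v in reads.items():
        row[order.index(k)] = v
    return row


def site_matrix(rows):
    return np.vstack(rows)


class TestCallBps:
    def test_clean_substitution_called(self):
        focal = site_matrix([counts_row(C=48, c=50)])
        others = np.array([B["T"]], dtype=np.int8)
        calls, n = call_bps("L1", focal, focal.copy(), others, T)
        assert n == 1
        (c,) = calls
        assert (c.ref, c.alt, c.position) == ("T", "C", 1)

    def test_fifty_fifty_site_not_called(self):
        focal = site_matrix([counts_row(C=25, c=25, T=25, t=25)])
        others = np.array([B["T"]], dtype=np.int8)
        calls, n = call_bps("L1", focal, focal.copy(), others, T)
        assert calls == [] and n == 1

    def test_aligner_disagreement_suppresses_call(self):
        a1 = site_matrix([counts_row(C=48, c=50)])
        a2 = site_matrix([counts_row(A=48, a=50)])
        others = np.array([B["T"]], dtype=np.int8)
        calls, _ = call_bps("L1", a1, a2, others, T)
        assert calls == []

    def test_strand_support_minimum(self):
        focal = site_matrix([counts_row(C=40, c=1)])  # only one reverse read
        others = np.array([B["T"]], dtype=np.int8)
        calls, _ = call_bps("L1", focal, focal.copy(), others, T)
        assert calls == []

    def test_low_depth_site_excluded_from_analysis(self):
        focal = site_matrix([counts_row(C=3, c=3), counts_row(C=48, c=50)])
        others = np.array([B["T"], B["T"]], dtype=np.int8)
        calls, n = call_bps("L1", focal, focal.copy(), others, T)
        assert n == 1  # the depth-6 site does not count as analyzed
        assert len(calls) == 1 and calls[0].position == 2

    def test_matching_consensus_not_called(self):
        focal = site_matrix([counts_row(T=30, t=30)])
        others = np.array([B["T"]], dtype=np.int8)
        calls, _ = call_bps("L1", focal, focal.copy(), others, T)
        assert calls == []

    def test_empty_others_consensus_rejected(self):
        focal = site_matrix([counts_row(C=48, c=50)])
        others = np.array([-1], dtype=np.int8)
        with pytest.raises(ValueError):
            call_bps("L1", focal, focal.copy(), others, T)


def evidence(pos=100, kind="deletion", size=2, motif="AC", fwd=2, rev=2, spanning=10):
    return IndelEvidence(pos, kind, size, motif, fwd, rev, spanning)


class TestCallIndelsConsensus:
    def test_accepted_at_thirty_percent_with_strand_minimum(self):
        ev = evidence(fwd=2, rev=2, spanning=10)  # 40% support
        calls = call_indels_consensus("L1", [ev], [ev], T)
        assert len(calls) == 1
        assert calls[0].size == 2 and calls[0].motif == "AC"

    def test_rejected_below_strand_minimum(self):
        ev = evidence(fwd=1, rev=3, spanning=10)
        assert call_indels_consensus("L1", [ev], [ev], T) == []

    def test_rejected_when_present_in_one_aligner_only(self):
        ev = evidence()
        assert call_indels_consensus("L1", [ev], [], T) == []

    def test_rejected_below_support_fraction(self):
        ev = evidence(fwd=2, rev=2, spanning=20)  # 20% < 30%
        assert call_indels_consensus("L1", [ev], [ev], T) == []

    def test_motif_mismatch_is_a_different_event(self):
        a = evidence(motif="AC")
        b = evidence(motif="AG")
        assert call_indels_consensus("L1", [a], [b], T) == []


class TestCallIndelsLarge:
    def test_large_deletion_accepted_at_twenty_reads(self):
        ev = IndelEvidence(500, "deletion", 12_581, "", 10, 10, 30)
        calls = call_indels_large("L1", [ev], T)
        assert len(calls) == 1 and calls[0].size == 12_581

    def test_rejected_when_total_support_below_twenty(self):
        ev = IndelEvidence(500, "deletion", 100, "", 6, 6, 30)
        assert call_indels_large("L1", [ev], T) == []

    def test_rejected_when_forward_below_six(self):
        ev = IndelEvidence(500, "deletion", 100, "", 5, 15, 30)
        assert call_indels_large("L1", [ev], T) == []


class TestProgenitorFilter:
    @staticmethod
    def shared_call(line):
        return MutationCall(line, 42, "deletion", motif="A", size=1)

    def test_shared_by_majority_removed(self):
        calls = [self.shared_call(f"L{i}") for i in range(24)]
        assert filter_progenitor(calls, 47, T) == []

    def test_shared_by_minority_retained(self):
        calls = [self.shared_call(f"L{i}") for i in range(23)]
        assert len(filter_progenitor(calls, 47, T)) == 23

    def test_unique_call_retained(self):
        calls = [MutationCall("L1", 9, "bps", ref="A", alt="G")]
        assert filter_progenitor(calls, 47, T) == calls

    def test_applies_to_bps_too(self):
        calls = [MutationCall(f"L{i}", 9, "bps", ref="A", alt="G") for i in range(30)]
        assert filter_progenitor(calls, 47, T) == []


class TestCallerProperties:
    def test_raising_thresholds_never_adds_calls(self, small_sim):
        base = call_all_lines(small_sim.counts, small_sim.evidence, 200, T)
        stricter = [
            CallingThresholds(min_fwd=5, min_rev=5),
            CallingThresholds(focal_fraction=0.95),
            CallingThresholds(min_depth=40),
            CallingThresholds(indel_fraction=0.9),
            CallingThresholds(indel_min_fwd=10, indel_min_rev=10),
        ]
        for thr in stricter:
            strict = call_all_lines(small_sim.counts, small_sim.evidence, 200, thr)
            assert len(strict.calls) <= len(base.calls)

    def test_line_relabeling_is_a_symmetry(self, small_sim):
        cat = call_all_lines(small_sim.counts, small_sim.evidence, 200, T)
        mapping = {l: f"X{l}" for l in small_sim.config.line_ids}
        counts = {mapping[l]: v for l, v in small_sim.counts.items()}
        evid = {mapping[l]: v for l, v in small_sim.evidence.items()}
        cat2 = call_all_lines(counts, evid, 200, T)
        orig = {(mapping[c.line], c.position, c.mtype, c.alt, c.motif) for c in cat.calls}
        new = {(c.line, c.position, c.mtype, c.alt, c.motif) for c in cat2.calls}
        assert orig == new

    def test_fewer_than_two_lines_rejected(self, small_sim):
        line = small_sim.config.line_ids[0]
        with pytest.raises(ValueError):
            call_all_lines({line: small_sim.counts[line]}, {}, 200, T)
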
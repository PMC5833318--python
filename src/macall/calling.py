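"""Consensus mutation calling across MA lines.

Base-pair substitutions are called by comparing each focal line against
the consensus of all other lines: a site yields a call only when the
focal line's own consensus base differs from the others' consensus, is
supported by minimum forward and reverse read counts, and both aligner
views independently agree on the same alternative base.  Indels are
accepted when identical (position, type, size, motif) evidence from both
aligners each reaches the supporting-read fraction and strand minima;
very long events detected by paired-end realignment use stricter read
thresholds.  Any identical event shared by more than half of the lines is
treated as a progenitor variant (or an assembly error) and removed.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict

import numpy as np

from .catalog import BPS, LineMeta, MutationCall, MutationCatalog
from .genome import BASES
from .pileio import IndelEvidence


@dataclass(frozen=True)
class CallingThresholds:
    """All acceptance knobs of the caller.

    The indel thresholds (30% supporting fraction, 2 forward + 2 reverse
    reads, >50% progenitor sharing, 6/6/20 for paired-evidence events)
    follow standard MA-pipeline practice; the BPS-side values mirror the
    indel logic with an 80% within-line and across-line consensus
    requirement and a minimum analyzed depth of 10 reads.
    """

    focal_fraction: float = 0.80
    min_fwd: int = 2
    min_rev: int = 2
    min_depth: int = 10
    others_fraction: float = 0.80
    indel_fraction: float = 0.30
    indel_min_fwd: int = 2
    indel_min_rev: int = 2
    progenitor_fraction: float = 0.50
    large_min_fwd: int = 6
    large_min_rev: int = 6
    large_min_total: int = 20

    def __post_init__(self) -> None:
        for name in ("focal_fraction", "others_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 < self.progenitor_fraction < 1:
            raise ValueError("progenitor_fraction must be in (0, 1)")
        for name in (
            "min_fwd",
            "min_rev",
            "min_depth",
            "indel_min_fwd",
            "indel_min_rev",
            "large_min_fwd",
            "large_min_rev",
            "large_min_total",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _site_summary(counts8: np.ndarray):
    """Per-site summary of one aligner view.

    Returns (top base index with -1 for ties/zero depth, fraction of reads
    on the top base, forward and reverse support of the top base, depth).
    """
    counts8 = np.asarray(counts8)
    fwd4 = counts8[:, 0::2]
    rev4 = counts8[:, 1::2]
    counts4 = fwd4 + rev4
    depth = counts4.sum(axis=1)
    top = counts4.argmax(axis=1)
    maxc = np.take_along_axis(counts4, top[:, None], axis=1)[:, 0]
    tie = (counts4 == maxc[:, None]).sum(axis=1) > 1
    frac = np.divide(maxc, depth, out=np.zeros(len(depth)), where=depth > 0)
    top = np.where(tie | (depth == 0), -1, top).astype(np.int8)
    fwd = np.take_along_axis(fwd4, np.maximum(top, 0)[:, None].astype(int), axis=1)[:, 0]
    rev = np.take_along_axis(rev4, np.maximum(top, 0)[:, None].astype(int), axis=1)[:, 0]
    return top, frac, fwd, rev, depth


def line_consensus(counts_a1: np.ndarray, counts_a2: np.ndarray, thresholds: CallingThresholds) -> np.ndarray:
    """Per-site consensus base of one line (aligner views pooled): the
    most frequent base when it carries >= focal_fraction of reads at
    >= min_depth depth; -1 where no consensus exists."""
    top, frac, _, _, depth = _site_summary(counts_a1 + counts_a2)
    ok = (depth >= thresholds.min_depth) & (frac >= thresholds.focal_fraction)
    return np.where(ok, top, -1).astype(np.int8)


def others_consensus(base_matrix: np.ndarray, focal_index: int, thresholds: CallingThresholds) -> np.ndarray:
    """Consensus base across all lines except the focal one: the base
    carried by >= others_fraction of the other lines; -1 where no base
    reaches agreement.  Lines without their own consensus count against
    agreement (conservative)."""
    others = np.delete(base_matrix, focal_index, axis=0)
    if others.shape[0] == 0:
        raise ValueError("need at least one non-focal line for a consensus")
    n_others = others.shape[0]
    votes = np.stack([(others == b).sum(axis=0) for b in range(4)])
    top = votes.argmax(axis=0)
    maxv = np.take_along_axis(votes, top[None, :], axis=0)[0]
    ok = maxv >= thresholds.others_fraction * n_others
    return np.where(ok, top, -1).astype(np.int8)


def call_bps(
    line: str,
    counts_a1: np.ndarray,
    counts_a2: np.ndarray,
    others: np.ndarray,
    thresholds: CallingThresholds | None = None,
) -> tuple[list[MutationCall], int]:
    """BPS calls for one focal line given both aligner views and the
    others' consensus base per site (-1 where undefined).

    Returns (calls, n_analyzed): a site counts toward the analyzed-site
    denominator when both aligner views reach the depth threshold and the
    others' consensus is defined.
    """
    thresholds = thresholds or CallingThresholds()
    others = np.asarray(others)
    if others.size != np.asarray(counts_a1).shape[0]:
        raise ValueError("others-consensus and pileup cover different coordinates")
    if (others >= 0).sum() == 0:
        raise ValueError("others-consensus is empty: no site has a defined consensus")
    t1, f1, fwd1, rev1, d1 = _site_summary(counts_a1)
    t2, f2, fwd2, rev2, d2 = _site_summary(counts_a2)
    analyzed = (d1 >= thresholds.min_depth) & (d2 >= thresholds.min_depth) & (others >= 0)

    def aligner_ok(t, f, fwd, rev):
        return (
            (t >= 0)
            & (f >= thresholds.focal_fraction)
            & (fwd >= thresholds.min_fwd)
            & (rev >= thresholds.min_rev)
        )

    hit = (
        analyzed
        & aligner_ok(t1, f1, fwd1, rev1)
        & aligner_ok(t2, f2, fwd2, rev2)
        & (t1 == t2)
        & (t1 != others)
    )
    calls = [
        MutationCall(
            line=line,
            position=int(i) + 1,
            mtype=BPS,
            ref=BASES[int(others[i])],
            alt=BASES[int(t1[i])],
            fwd=int(min(fwd1[i], fwd2[i])),
            rev=int(min(rev1[i], rev2[i])),
        )
        for i in np.nonzero(hit)[0]
    ]
    return calls, int(analyzed.sum())


def call_indels_consensus(
    line: str,
    evidence_a1: list[IndelEvidence],
    evidence_a2: list[IndelEvidence],
    thresholds: CallingThresholds | None = None,
) -> list[MutationCall]:
    """Consensus indel calls: both aligners must report the identical
    (position, type, size, motif) event, each with a supporting fraction
    >= indel_fraction of spanning reads and the forward/reverse minima."""
    thresholds = thresholds or CallingThresholds()

    def passes(r: IndelEvidence) -> bool:
        return (
            r.spanning > 0
            and r.support >= thresholds.indel_fraction * r.spanning
            and r.fwd >= thresholds.indel_min_fwd
            and r.rev >= thresholds.indel_min_rev
        )

    by_key_a2 = {r.key: r for r in evidence_a2}
    calls = []
    for r1 in evidence_a1:
        r2 = by_key_a2.get(r1.key)
        if r2 is None or not passes(r1) or not passes(r2):
            continue
        calls.append(
            MutationCall(
                line=line,
                position=r1.position,
                mtype=r1.kind,
                motif=r1.motif,
                size=r1.size,
                fwd=min(r1.fwd, r2.fwd),
                rev=min(r1.rev, r2.rev),
            )
        )
    return calls


def call_indels_large(
    line: str,
    paired_evidence: list[IndelEvidence],
    thresholds: CallingThresholds | None = None,
) -> list[MutationCall]:
    """Long-indel calls from paired-end realignment evidence: at least 6
    forward and 6 reverse supporting reads and 20 supporting reads in
    total (defaults)."""
    thresholds = thresholds or CallingThresholds()
    calls = []
    for r in paired_evidence:
        if (
            r.fwd >= thresholds.large_min_fwd
            and r.rev >= thresholds.large_min_rev
            and r.support >= thresholds.large_min_total
        ):
            calls.append(
                MutationCall(
                    line=line,
                    position=r.position,
                    mtype=r.kind,
                    motif=r.motif,
                    size=r.size,
                    fwd=r.fwd,
                    rev=r.rev,
                )
            )
    return calls


def filter_progenitor(
    calls: list[MutationCall],
    n_lines: int,
    thresholds: CallingThresholds | None = None,
) -> list[MutationCall]:
    """Remove any identical event present in strictly more than
    ``progenitor_fraction`` of the lines (applied to BPSs and indels
    alike): such variants predate the MA propagation or reflect
    reference-assembly errors."""
    if n_lines < 2:
        raise ValueError("progenitor filtering needs at least 2 lines")
    thresholds = thresholds or CallingThresholds()
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for c in calls:
        carriers[c.key].add(c.line)
    cutoff = thresholds.progenitor_fraction * n_lines
    return [c for c in calls if len(carriers[c.key]) <= cutoff]


def call_all_lines(
    counts: dict[str, tuple[np.ndarray, np.ndarray]],
    evidence: dict[str, dict[str, list[IndelEvidence]]],
    generations: float | dict[str, float],
    thresholds: CallingThresholds | None = None,
) -> MutationCatalog:
    """Run the full caller over every line and assemble the catalog.

    ``counts`` maps line id to its two aligner count matrices (all shapes
    equal); ``evidence`` maps line id to its ``aligner1``/``aligner2``/
    ``paired`` evidence lists.  Per-line analyzed-site counts n_i come
    from the depth filter and feed the rate denominators.
    """
    thresholds = thresholds or CallingThresholds()
    lines = sorted(counts)
    if len(lines) < 2:
        raise ValueError("consensus calling needs at least 2 lines")
    base_matrix = np.stack(
        [line_consensus(counts[l][0], counts[l][1], thresholds) for l in lines]
    )
    all_calls: list[MutationCall] = []
    meta: dict[str, LineMeta] = {}
    for i, line in enumerate(lines):
        others = others_consensus(base_matrix, i, thresholds)
        bps_calls, n_analyzed = call_bps(
            line, counts[line][0], counts[line][1], others, thresholds
        )
        ev = evidence.get(line, {})
        indel_calls = call_indels_consensus(
            line, ev.get("aligner1", []), ev.get("aligner2", []), thresholds
        )
        large_calls = call_indels_large(line, ev.get("paired", []), thresholds)
        all_calls.extend(bps_calls + indel_calls + large_calls)
        T = generations[line] if isinstance(generations, dict) else generations
        meta[line] = LineMeta(line, float(T), max(n_analyzed, 1))
    filtered = filter_progenitor(all_calls, len(lines), thresholds)
    return MutationCatalog(calls=filtered, lines=meta)
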
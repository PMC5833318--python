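"""Deterministic catalog reconstruction from published marginal totals.

The *T. turnerae* mutation-accumulation study reports only marginal
summaries of its 885 accepted mutations: totals by event type, the
transition and A/T-ward counts, indel size-class tallies, the nucleotide
loss per generation, and the number and composition of clustered events.
This module expands such a set of marginals into a full
:class:`~macall.catalog.MutationCatalog` whose summary statistics
reproduce the configured totals exactly.

Free choices the totals do not pin down (the split of the 558 transitions
between G:C→A:T and A:T→G:C, per-line allocations, exact indel sizes,
positions) are filled by documented deterministic rules:

* class splits by largest-remainder allocation against the printed
  marginals;
* per-line counts: one line carries the reported per-line maxima, the
  remainder is spread evenly with largest-remainder rounding;
* short indels are 1 bp and long indels 4 bp, with the residual of the
  configured nucleotide totals absorbed by one long event of each type
  (besides the single explicitly-sized 12,581-bp deletion);
* clustered events occupy reserved, well-separated coordinates; all other
  events are spaced far beyond the clustering window.

Only the marginals are meaningful; the per-event detail is synthetic
plumbing that lets every downstream analysis run on a concrete catalog.
"""

from __future__ import annotations

from .catalog import BPS, DELETION, INSERTION, LineMeta, MutationCall, MutationCatalog

#: Marginal totals of the 47-line T. turnerae MA experiment (counts as
#: printed; nucleotides_deleted is the printed per-generation loss rate
#: 9.89e-2 multiplied back up by the 47 x 3,025 line-generations).
STUDY_TOTALS: dict = {
    "n_lines": 47,
    "generations": 3025.0,
    "genome_size": 5_190_000,
    "bps_total": 779,
    "transitions": 558,
    "at_ward": 533,
    "deletions": 73,
    "insertions": 33,
    "short_deletions": 47,
    "short_insertions": 25,
    "large_deletion_size": 12_581,
    "nucleotides_deleted": 14_061,
    "nucleotides_inserted": 80,
    "clustered_bps": 21,
    "clustered_indels": 16,
    "cluster_window": 50,
    "max_bps_per_line": 28,
    "max_indels_per_line": 6,
    "triple_cluster_line": "MA29",
}

# Strand-symmetric BPS classes with a deterministic ref/alt realization
# cycle (alternating the two strands of the source pair).
CLASS_VARIANTS = {
    "G:C>A:T": (("G", "A"), ("C", "T")),
    "A:T>G:C": (("A", "G"), ("T", "C")),
    "G:C>T:A": (("G", "T"), ("C", "A")),
    "A:T>T:A": (("A", "T"), ("T", "A")),
    "A:T>C:G": (("A", "C"), ("T", "G")),
    "G:C>C:G": (("G", "C"), ("C", "G")),
}

SHORT_INDEL_MAX = 3  # bp; >= 4 bp is a "long" indel
_MOTIF_CYCLE = "ACGT"


def largest_remainder(total: int, weights: list[float]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights`` by
    the largest-remainder (Hamilton) method; ties broken by list order."""
    if total < 0 or any(w < 0 for w in weights):
        raise ValueError("total and weights must be non-negative")
    wsum = float(sum(weights))
    if wsum == 0:
        raise ValueError("weights sum to zero")
    shares = [total * w / wsum for w in weights]
    alloc = [int(s) for s in shares]
    short = total - sum(alloc)
    order = sorted(range(len(weights)), key=lambda i: (alloc[i] - shares[i], i))
    for i in order[:short]:
        alloc[i] += 1
    return alloc


def proportional_sequence(counts: dict) -> list:
    """Deterministic interleaving of items: repeatedly emit the key whose
    remaining count is largest (ties by insertion order).  Spreads classes
    through the sequence instead of emitting them in blocks."""
    remaining = dict(counts)
    out = []
    for _ in range(sum(counts.values())):
        key = max(remaining, key=lambda k: (remaining[k], -list(remaining).index(k)))
        out.append(key)
        remaining[key] -= 1
        if remaining[key] == 0:
            del remaining[key]
    return out


def bps_class_counts(totals: dict) -> dict[str, int]:
    """Expand (total, transitions, A/T-ward) marginals into the six
    strand-symmetric class counts by largest-remainder allocation."""
    total = totals["bps_total"]
    ts = totals["transitions"]
    atw = totals["at_ward"]
    tv = total - ts
    if ts > total or ts < 0:
        raise ValueError(f"transitions ({ts}) inconsistent with total BPS ({total})")
    if atw > total or atw < 0:
        raise ValueError(f"A/T-ward count ({atw}) inconsistent with total BPS ({total})")
    # A/T-ward events are G:C>A:T (a transition) or G:C>T:A (a transversion);
    # split them in proportion to the overall Ts:Tv composition.
    gc_at, gc_ta = largest_remainder(atw, [ts, tv])
    at_gc = ts - gc_at
    rem_tv = tv - gc_ta
    if at_gc < 0 or rem_tv < 0:
        raise ValueError("marginals admit no non-negative class allocation")
    at_ta, at_cg, gc_cg = largest_remainder(rem_tv, [1, 1, 1])
    counts = {
        "G:C>A:T": gc_at,
        "A:T>G:C": at_gc,
        "G:C>T:A": gc_ta,
        "A:T>T:A": at_ta,
        "A:T>C:G": at_cg,
        "G:C>C:G": gc_cg,
    }
    assert sum(counts.values()) == total
    return counts


def _per_line_allocation(total: int, n_lines: int, first_line_count: int) -> list[int]:
    """First line carries the reported maximum; the rest of the total is
    spread evenly (largest remainder, earlier lines first)."""
    if first_line_count > total:
        raise ValueError("per-line maximum exceeds the total")
    rest = largest_remainder(total - first_line_count, [1] * (n_lines - 1))
    return [first_line_count] + rest


def _indel_size_lists(totals: dict) -> tuple[list[int], list[int]]:
    """Deterministic deletion / insertion size multisets consistent with
    the size-class and nucleotide-sum marginals."""
    n_del, n_ins = totals["deletions"], totals["insertions"]
    sd, si = totals["short_deletions"], totals["short_insertions"]
    if sd > n_del or si > n_ins:
        raise ValueError("short-indel counts exceed type totals")
    ld, li = n_del - sd, n_ins - si
    big = totals["large_deletion_size"]
    if ld < 1:
        raise ValueError("at least one long deletion needed for the large event")
    residual_del = totals["nucleotides_deleted"] - big - sd - 4 * (ld - 2)
    residual_ins = totals["nucleotides_inserted"] - si - 4 * (li - 1)
    if ld >= 2 and residual_del < 4:
        raise ValueError("nucleotides_deleted too small for the size-class marginals")
    if li >= 1 and residual_ins < 4:
        raise ValueError("nucleotides_inserted too small for the size-class marginals")
    del_sizes = [big]
    if ld >= 2:
        del_sizes += [residual_del] + [4] * (ld - 2)
    del_sizes += [1] * sd
    ins_sizes = ([residual_ins] + [4] * (li - 1) if li >= 1 else []) + [1] * si
    return del_sizes, ins_sizes


def _motif(size: int, offset: int) -> str:
    """Deterministic nucleotide motif; empty for very long events, where
    paired-end evidence reports only the size."""
    if size > 50:
        return ""
    s = _MOTIF_CYCLE * (size // 4 + 2)
    start = offset % 4
    return s[start : start + size]


def _cluster_plan(totals: dict, line_ids: list[str]) -> dict[str, list[str]]:
    """Assign clusters to lines.

    One triple of BPSs goes to the designated line; the remaining
    clustered events form pairs (BPS-BPS, mixed, or indel-indel) dealt to
    consecutive lines, doubling up on the earliest lines so the number of
    cluster-bearing lines matches the published ~34% of lines.
    """
    cb, ci = totals["clustered_bps"], totals["clustered_indels"]
    if cb < 3:
        raise ValueError("need at least 3 clustered BPSs for the triple")
    pair_bps = cb - 3
    if (pair_bps + ci) % 2 != 0:
        raise ValueError("clustered events beyond the triple must pair up")
    n_mixed = pair_bps % 2  # 0 or 1 mixed pair keeps everything integral
    n_bb = (pair_bps - n_mixed) // 2
    n_ii = (ci - n_mixed) // 2
    if n_mixed + 2 * n_ii != ci:
        raise ValueError("clustered indel count admits no pair decomposition")
    pairs = ["bps-bps"] * n_bb + ["bps-indel"] * n_mixed + ["indel-indel"] * n_ii

    triple_line = totals.get("triple_cluster_line") or line_ids[len(line_ids) // 2]
    plan: dict[str, list[str]] = {triple_line: ["triple"]}
    # lines after the triple line (wrapping) receive the pairs; the number
    # of distinct cluster lines is chosen so clusters sit in about a third
    # of lines: double up pairs on the earliest recipients when needed.
    start = line_ids.index(triple_line) + 1
    recipients = [line_ids[(start + k) % len(line_ids)] for k in range(len(line_ids))]
    target_lines = max(1, round(0.34 * len(line_ids)) - 1)  # minus the triple line
    target_lines = min(target_lines, len(pairs))
    doubled = len(pairs) - target_lines
    idx = 0
    for k, lid in enumerate(recipients[:target_lines]):
        take = 2 if k < doubled else 1
        plan.setdefault(lid, []).extend(pairs[idx : idx + take])
        idx += take
    assert idx == len(pairs)
    return plan


def build_catalog(totals: dict | None = None) -> MutationCatalog:
    """Expand marginal totals (default: the published study totals) into a
    full mutation catalog with per-line metadata.

    Raises ValueError on internally inconsistent marginals (e.g. more
    transitions than total BPSs).
    """
    totals = dict(STUDY_TOTALS if totals is None else totals)
    n_lines = totals["n_lines"]
    genome_size = totals["genome_size"]
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    line_ids = [f"MA{i:02d}" for i in range(1, n_lines + 1)]

    class_counts = bps_class_counts(totals)
    class_seq = proportional_sequence(class_counts)
    del_sizes, ins_sizes = _indel_size_lists(totals)
    indel_seq_types = proportional_sequence(
        {DELETION: len(del_sizes), INSERTION: len(ins_sizes)}
    )
    del_iter, ins_iter = iter(del_sizes), iter(ins_sizes)

    bps_per_line = _per_line_allocation(
        totals["bps_total"], n_lines, totals["max_bps_per_line"]
    )
    indels_per_line = _per_line_allocation(
        totals["deletions"] + totals["insertions"],
        n_lines,
        totals["max_indels_per_line"],
    )

    # deal classes and indel sizes to lines in order
    strand_cycle = {label: 0 for label in CLASS_VARIANTS}
    seq_pos = 0
    indel_pos = 0
    per_line_events: dict[str, list[dict]] = {}
    for li, lid in enumerate(line_ids):
        events = []
        for _ in range(bps_per_line[li]):
            label = class_seq[seq_pos]
            seq_pos += 1
            variants = CLASS_VARIANTS[label]
            ref, alt = variants[strand_cycle[label] % 2]
            strand_cycle[label] += 1
            events.append({"mtype": BPS, "ref": ref, "alt": alt, "size": 1})
        for _ in range(indels_per_line[li]):
            kind = indel_seq_types[indel_pos]
            indel_pos += 1
            size = next(del_iter) if kind == DELETION else next(ins_iter)
            events.append(
                {"mtype": kind, "size": size, "motif": _motif(size, indel_pos)}
            )
        per_line_events[lid] = events

    # default positions: widely spaced, line-specific lattice
    spacing = 5001
    for li, lid in enumerate(line_ids):
        for k, ev in enumerate(per_line_events[lid]):
            ev["position"] = 1 + li * 797 + k * spacing

    # clustered events occupy a reserved band; members are drawn from the
    # line's existing events so all marginals are preserved
    window = totals["cluster_window"]
    plan = _cluster_plan(totals, line_ids)
    band = int(genome_size * 0.88)
    for lid, clusters in plan.items():
        events = per_line_events[lid]
        used: set[int] = set()

        def take(mtype_bps: bool) -> dict:
            for i, ev in enumerate(events):
                if i in used:
                    continue
                if (ev["mtype"] == BPS) == mtype_bps:
                    used.add(i)
                    return ev
            raise ValueError(f"line {lid} lacks events for its assigned cluster")

        li = line_ids.index(lid)
        for j, ctype in enumerate(clusters):
            anchor = band + li * 531 + j * 20_000
            if ctype == "triple":
                members = [take(True), take(True), take(True)]
                # consecutive gaps and the total span stay below the window
                offsets = [0, (window - 1) // 2, window - 2]
            elif ctype == "bps-bps":
                members, offsets = [take(True), take(True)], [0, window - 20]
            elif ctype == "bps-indel":
                members, offsets = [take(True), take(False)], [0, window - 20]
            else:  # indel-indel
                members, offsets = [take(False), take(False)], [0, window - 20]
            for ev, off in zip(members, offsets):
                ev["position"] = anchor + off

    calls = []
    for lid in line_ids:
        for ev in per_line_events[lid]:
            calls.append(
                MutationCall(
                    line=lid,
                    position=ev["position"],
                    mtype=ev["mtype"],
                    ref=ev.get("ref", ""),
                    alt=ev.get("alt", ""),
                    motif=ev.get("motif", ""),
                    size=ev["size"],
                )
            )
    lines = {
        lid: LineMeta(lid, totals["generations"], genome_size) for lid in line_ids
    }
    return MutationCatalog(calls=calls, lines=lines)
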
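"""Mutation-spectrum summaries.

Base-pair substitutions collapse into six strand-symmetric classes
(A:T>G:C, G:C>A:T, A:T>T:A, A:T>C:G, G:C>T:A, G:C>C:G).  A change is a
transition when it exchanges purine for purine or pyrimidine for
pyrimidine, and A/T-ward when the ancestral pair is G:C and the derived
pair is A:T or T:A.  Indels split into short (1-3 bp) and long (>= 4 bp)
size classes; the nucleotide gain/loss budget is expressed per generation
per line by dividing the summed sizes by the total line-generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .catalog import BPS, DELETION, INSERTION, MutationCatalog
from .genome import Genome

PURINES = {"A", "G"}
CLASS_LABELS = ("G:C>A:T", "A:T>G:C", "G:C>T:A", "A:T>T:A", "A:T>C:G", "G:C>C:G")
SHORT_INDEL_MAX = 3  # bp


class BpsClass(NamedTuple):
    label: str
    transition: bool
    at_ward: bool


def classify_bps(ref: str, alt: str) -> BpsClass:
    """Strand-symmetric class of a substitution plus its transition and
    A/T-ward flags."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    transition = (ref in PURINES) == (alt in PURINES)
    at_ward = ref in "GC" and alt in "AT"
    source = "A:T" if ref in "AT" else "G:C"
    # destination pair written with the purine first for A/G, following
    # the conventional class names
    pair = {"A": "A:T", "T": "T:A", "G": "G:C", "C": "C:G"}
    if ref in "AT":
        dest = pair[alt] if ref == "A" else pair[alt.translate(str.maketrans("ACGT", "TGCA"))]
    else:
        dest = pair[alt] if ref == "G" else pair[alt.translate(str.maketrans("ACGT", "TGCA"))]
    label = f"{source}>{dest}"
    if label not in CLASS_LABELS:
        raise AssertionError(f"unexpected class {label}")
    return BpsClass(label, transition, at_ward)


class ChiSquareResult(NamedTuple):
    chi2: float
    df: int
    p: float


def chi_square_gof(observed, expected) -> ChiSquareResult:
    """Pearson goodness-of-fit chi-square without continuity correction:
    sum((O-E)^2 / E), df = k - 1, p from the chi-square distribution."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.size < 2:
        raise ValueError("observed and expected must have equal length >= 2")
    if np.any(e <= 0):
        raise ValueError("expected counts must all be positive")
    chi2 = float(((o - e) ** 2 / e).sum())
    df = o.size - 1
    return ChiSquareResult(chi2, df, float(stats.chi2.sf(chi2, df)))


@dataclass
class SpectrumSummary:
    class_counts: dict[str, int]
    transitions: int
    transversions: int
    at_ward: int
    bps_total: int
    deletions: int
    insertions: int
    short_deletions: int
    long_deletions: int
    short_insertions: int
    long_insertions: int
    total_events: int
    nt_lost_per_gen: float
    nt_gained_per_gen: float
    deletion_bias_fold: float | None  # None when nothing was gained
    ts_tv_pooled: float | None  # None when there are no transversions
    ts_tv_line_mean: float | None

    @property
    def indels(self) -> int:
        return self.deletions + self.insertions

    def percentages(self) -> dict[str, float]:
        """Headline shares of the spectrum, in percent."""
        out: dict[str, float] = {}
        if self.bps_total:
            out["transitions_pct"] = 100.0 * self.transitions / self.bps_total
            out["transversions_pct"] = 100.0 * self.transversions / self.bps_total
            out["at_ward_pct"] = 100.0 * self.at_ward / self.bps_total
        if self.indels:
            out["deletions_pct_of_indels"] = 100.0 * self.deletions / self.indels
        if self.deletions:
            out["short_deletions_pct"] = 100.0 * self.short_deletions / self.deletions
        if self.insertions:
            out["short_insertions_pct"] = 100.0 * self.short_insertions / self.insertions
        if self.total_events:
            out["bps_share_pct"] = 100.0 * self.bps_total / self.total_events
            out["indel_share_pct"] = 100.0 * self.indels / self.total_events
        return out


def summarize_spectrum(catalog: MutationCatalog) -> SpectrumSummary:
    """Full spectrum summary of a catalog (requires line metadata for the
    per-generation nucleotide budget)."""
    if not catalog.calls:
        raise ValueError("catalog is empty")
    class_counts = {label: 0 for label in CLASS_LABELS}
    transitions = at_ward = 0
    per_line_ts: dict[str, int] = {}
    per_line_tv: dict[str, int] = {}
    for c in catalog.bps_calls():
        k = classify_bps(c.ref, c.alt)
        class_counts[k.label] += 1
        transitions += k.transition
        at_ward += k.at_ward
        per_line_ts[c.line] = per_line_ts.get(c.line, 0) + int(k.transition)
        per_line_tv[c.line] = per_line_tv.get(c.line, 0) + int(not k.transition)
    bps_total = sum(class_counts.values())
    transversions = bps_total - transitions

    dels = [c for c in catalog.calls if c.mtype == DELETION]
    ins = [c for c in catalog.calls if c.mtype == INSERTION]
    short_d = sum(1 for c in dels if c.size <= SHORT_INDEL_MAX)
    short_i = sum(1 for c in ins if c.size <= SHORT_INDEL_MAX)

    total_T = catalog.total_generations()
    nt_lost = sum(c.size for c in dels) / total_T
    nt_gained = sum(c.size for c in ins) / total_T
    fold = (nt_lost / nt_gained) if nt_gained > 0 else None

    ts_tv_pooled = (transitions / transversions) if transversions else None
    # per-line Ts/Tv mean over lines that observed at least one
    # transversion (the ratio is undefined otherwise)
    ratios = [
        per_line_ts.get(l, 0) / per_line_tv[l]
        for l in per_line_tv
        if per_line_tv[l] > 0
    ]
    ts_tv_line_mean = float(np.mean(ratios)) if ratios else None

    return SpectrumSummary(
        class_counts=class_counts,
        transitions=transitions,
        transversions=transversions,
        at_ward=at_ward,
        bps_total=bps_total,
        deletions=len(dels),
        insertions=len(ins),
        short_deletions=short_d,
        long_deletions=len(dels) - short_d,
        short_insertions=short_i,
        long_insertions=len(ins) - short_i,
        total_events=len(catalog.calls),
        nt_lost_per_gen=nt_lost,
        nt_gained_per_gen=nt_gained,
        deletion_bias_fold=fold,
        ts_tv_pooled=ts_tv_pooled,
        ts_tv_line_mean=ts_tv_line_mean,
    )


def deletion_bias_test(summary: SpectrumSummary) -> ChiSquareResult:
    """Chi-square for excess of deletions over insertions against an
    equal-split expectation of the indel total."""
    total = summary.indels
    if total == 0:
        raise ValueError("no indels in summary")
    return chi_square_gof(
        [summary.deletions, summary.insertions], [total / 2, total / 2]
    )


def conditional_rates(
    summary: SpectrumSummary, genome: Genome, total_generations: float
) -> dict[str, float]:
    """Per-class conditional BPS rates normalized to the number of A:T or
    G:C base pairs in the genome: class count / (source-pair sites x
    total line-generations)."""
    if total_generations <= 0:
        raise ValueError("total_generations must be positive")
    if genome.at_sites == 0 or genome.gc_sites == 0:
        raise ValueError("genome must contain both A:T and G:C sites")
    out = {}
    for label, count in summary.class_counts.items():
        sites = genome.at_sites if label.startswith("A:T") else genome.gc_sites
        out[label] = count / (sites * total_generations)
    return out


def plot_spectrum(summary: SpectrumSummary, genome: Genome, total_generations: float, path) -> None:
    """Bar plot of the conditional per-class rates and indel size classes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = conditional_rates(summary, genome, total_generations)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.bar(range(len(rates)), list(rates.values()), color="steelblue")
    ax1.set_xticks(range(len(rates)), list(rates), rotation=45, ha="right")
    ax1.set_ylabel("rate / site / generation")
    ax1.set_title("conditional BPS rates")
    groups = ["del short", "del long", "ins short", "ins long"]
    values = [
        summary.short_deletions,
        summary.long_deletions,
        summary.short_insertions,
        summary.long_insertions,
    ]
    ax2.bar(groups, values, color="indianred")
    ax2.set_ylabel("events")
    ax2.set_title("indel size classes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
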
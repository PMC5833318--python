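"""Distribution of mutations with respect to genomic annotation and
chromosomal position.

Three questions: do BPSs fall in coding regions in proportion to the
coding fraction of the genome; do coding BPSs split into nonsynonymous
and synonymous changes at the ratio expected from enumerating every
possible single-nucleotide change over all coding sites (bacterial
translation table 11); and does the 50-kb bin containing the replication
terminus carry more BPSs than the rest of the chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .catalog import MutationCatalog
from .genome import BASES, Gene, Genome, reverse_complement
from .spectrum import ChiSquareResult, chi_square_gof

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _aa(codon: str) -> str:
    """Amino acid (or '*') for a codon under bacterial table 11."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def coding_distribution_test(catalog: MutationCatalog, genome: Genome) -> ChiSquareResult:
    """Observed coding/noncoding BPS counts against an expectation
    proportional to the coding/noncoding site totals."""
    coding_sites = genome.coding_sites
    noncoding_sites = genome.length - coding_sites
    if coding_sites == 0 or noncoding_sites == 0:
        raise ValueError("genome must contain both coding and noncoding sites")
    bps = catalog.bps_calls()
    if not bps:
        raise ValueError("no BPS calls in catalog")
    mask = genome.coding_mask
    observed_coding = sum(1 for c in bps if mask[c.position - 1])
    total = len(bps)
    expected = [
        total * coding_sites / genome.length,
        total * noncoding_sites / genome.length,
    ]
    return chi_square_gof([observed_coding, total - observed_coding], expected)


def enumerate_ns_fraction(genome: Genome, weights: dict | None = None) -> float:
    """Expected nonsynonymous fraction from enumerating all 3L possible
    single-nucleotide changes over all coding sites.

    ``weights`` optionally maps (ref, alt) base pairs to relative
    mutation probabilities (a spectrum-weighted expectation); the default
    weights every possible change equally.  Codons containing non-ACGT
    characters are skipped with a warning.
    """
    ns = s = 0.0
    for gene in genome.genes:
        seq = genome.slice(gene.start, gene.end)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if any(b not in BASES for b in codon):
                warnings.warn(f"skipping codon {codon!r} with non-ACGT base")
                continue
            aa0 = _aa(codon)
            for j in range(3):
                for b in BASES:
                    if b == codon[j]:
                        continue
                    w = weights.get((codon[j], b), 0.0) if weights else 1.0
                    mutant = codon[:j] + b + codon[j + 1 :]
                    if _aa(mutant) == aa0:
                        s += w
                    else:
                        ns += w
    total = ns + s
    if total == 0:
        raise ValueError("no coding changes could be enumerated")
    return ns / total


def classify_coding_call(call, genome: Genome) -> str | None:
    """'nonsynonymous', 'synonymous', or None when the site is noncoding.

    A site inside any annotated gene is classified once, using the first
    containing gene (overlaps are rare in the simulated annotations).
    """
    gene = genome.gene_at(call.position)
    if gene is None:
        return None
    seq = genome.slice(gene.start, gene.end)
    if gene.strand == "+":
        offset = call.position - gene.start
        ref_base, alt_base = call.ref, call.alt
    else:
        seq = reverse_complement(seq)
        offset = gene.end - call.position
        comp = str.maketrans("ACGT", "TGCA")
        ref_base, alt_base = call.ref.translate(comp), call.alt.translate(comp)
    ci, within = divmod(offset, 3)
    codon = seq[3 * ci : 3 * ci + 3]
    if codon[within] != ref_base:
        warnings.warn(
            f"reference mismatch at {call.position}: codon {codon} vs ref {ref_base}"
        )
    mutant = codon[:within] + alt_base + codon[within + 1 :]
    return "synonymous" if _aa(mutant) == _aa(codon) else "nonsynonymous"


def ns_s_expectation_test(
    catalog: MutationCatalog, genome: Genome, weights: dict | None = None
) -> tuple[ChiSquareResult, float, dict[str, int]]:
    """Observed NS/S split of coding BPSs against the enumerated
    expectation.  Returns (chi-square result, expected NS fraction,
    observed counts)."""
    expected_ns = enumerate_ns_fraction(genome, weights)
    observed = {"nonsynonymous": 0, "synonymous": 0}
    for c in catalog.bps_calls():
        kind = classify_coding_call(c, genome)
        if kind is not None:
            observed[kind] += 1
    total = sum(observed.values())
    if total == 0:
        raise ValueError("no coding BPS calls to test")
    result = chi_square_gof(
        [observed["nonsynonymous"], observed["synonymous"]],
        [total * expected_ns, total * (1 - expected_ns)],
    )
    return result, expected_ns, observed


@dataclass
class BinDensity:
    """Per-bin BPS counts over the circular genome in consecutive
    fixed-size bins starting at position 1 (final partial bin kept)."""

    counts: np.ndarray
    bin_size: int
    terminus_bin: int | None

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def bin_density(catalog: MutationCatalog, genome: Genome, bin_size: int = 50_000) -> BinDensity:
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = -(-genome.length // bin_size)  # ceil
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in catalog.bps_calls():
        counts[(c.position - 1) // bin_size] += 1
    terminus_bin = (
        (genome.terminus - 1) // bin_size if genome.terminus is not None else None
    )
    return BinDensity(counts=counts, bin_size=bin_size, terminus_bin=terminus_bin)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def terminus_test(bins: BinDensity, exclude_terminus: bool = False) -> TTestResult:
    """One-sample t statistic of the terminus bin's BPS count against the
    distribution of bin counts: t = (x_term - mean) / (SD / sqrt(K)),
    df = K - 1.

    By default the terminus bin itself enters the mean and SD; pass
    ``exclude_terminus=True`` for the variant where the background is the
    other bins only.  Both are reported by the pipeline since the exact
    construction behind a published value of this kind is rarely stated.
    """
    if bins.terminus_bin is None:
        raise ValueError("bin density has no terminus bin")
    counts = bins.counts.astype(float)
    if counts.size < 3:
        raise ValueError("need at least 3 bins")
    x_term = counts[bins.terminus_bin]
    sample = np.delete(counts, bins.terminus_bin) if exclude_terminus else counts
    sd = sample.std(ddof=1)
    if sd == 0:
        raise ZeroDivisionError("bin counts have zero variance")
    k = sample.size
    t = (x_term - sample.mean()) / (sd / np.sqrt(k))
    df = k - 1
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))
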
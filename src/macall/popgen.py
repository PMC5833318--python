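"""Effective population size from silent-site diversity.

For a haploid organism under neutrality, pi_S = 2 Ne mu, where pi_S is
the average pairwise nucleotide heterozygosity at silent sites among
natural isolates and mu the per-site per-generation mutation rate from
the MA assay; hence Ne = pi_S / (2 mu).

Silent sites are taken conservatively as four-fold degenerate third
codon positions whose first two codon positions are identical (and
unambiguous) across all sequences of a codon-aligned strain set; any gap
or ambiguity character at the third position excludes that site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

from Bio import SeqIO
from Bio.Data import CodonTable

from .genome import BASES

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _fourfold_prefixes() -> frozenset[str]:
    """Codon prefixes whose four third-base completions all encode the
    same amino acid (no stop codons involved)."""
    out = set()
    for p1, p2 in product(BASES, repeat=2):
        prefix = p1 + p2
        codons = [prefix + b for b in BASES]
        if any(c in _TABLE11.stop_codons for c in codons):
            continue
        aas = {_TABLE11.forward_table[c] for c in codons}
        if len(aas) == 1:
            out.add(prefix)
    return frozenset(out)


FOURFOLD_PREFIXES = _fourfold_prefixes()


@dataclass(frozen=True)
class PiEstimate:
    """Average pairwise silent-site diversity."""

    pi: float
    n_sites: int
    n_sequences: int

    def __post_init__(self) -> None:
        if not 0 <= self.pi <= 1:
            raise ValueError("pi must lie in [0, 1]")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


def silent_site_pi(sequences) -> PiEstimate:
    """pi_S over a codon-aligned set of sequences (strings or SeqRecords).

    Eligible sites are third positions of codons whose first two bases
    are identical across all sequences and form a four-fold degenerate
    prefix; the site value is the fraction of sequence pairs differing
    there, and pi_S is the mean over eligible sites.
    """
    seqs = [str(getattr(s, "seq", s)).upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length (codon alignment)")
    if length % 3 != 0:
        raise ValueError("alignment length must be divisible by 3")
    n = len(seqs)
    n_pairs = n * (n - 1) / 2
    site_pis = []
    for i in range(0, length, 3):
        prefixes = {s[i : i + 2] for s in seqs}
        if len(prefixes) != 1:
            continue
        prefix = prefixes.pop()
        if prefix not in FOURFOLD_PREFIXES:
            continue
        thirds = [s[i + 2] for s in seqs]
        if any(b not in BASES for b in thirds):
            continue  # gap or ambiguity excludes the site
        same_pairs = 0
        for b in set(thirds):
            c = thirds.count(b)
            same_pairs += c * (c - 1) / 2
        site_pis.append((n_pairs - same_pairs) / n_pairs)
    if not site_pis:
        raise ValueError("no eligible four-fold degenerate sites in alignment")
    return PiEstimate(
        pi=float(sum(site_pis) / len(site_pis)),
        n_sites=len(site_pis),
        n_sequences=n,
    )


def silent_site_pi_from_fasta(path) -> PiEstimate:
    return silent_site_pi(list(SeqIO.parse(str(path), "fasta")))


def effective_population_size(pi: float, mu: float) -> float:
    """Ne = pi_S / (2 mu) for a haploid population."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return pi / (2.0 * mu)
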
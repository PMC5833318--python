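"""Synthetic mutation-accumulation data with known ground truth.

The generator emulates the sequencing summary an MA experiment produces
after read alignment: for every line and each of two pseudo-aligners, a
per-site 8-number read-count configuration (A, a, C, c, G, g, T, t), and
a separate per-aligner indel-evidence file.  It does not simulate reads,
mapping bias or GC-coverage bias — coverage is Poisson per site, strand
is Binomial(depth, 1/2), and sequencing error substitutes a uniformly
chosen other base.

Default configuration values mirror the study conditions the pipeline was
built around: 47 haploid lines propagated ~3,025 generations on a 5.19-Mb
circular chromosome sequenced at ~100x, with mutation totals matching the
observed marginal counts.  Tests and examples pass smaller genomes and
line counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .catalog import BPS, DELETION, INSERTION
from .genome import BASES, Gene, Genome
from .pileio import (
    IndelEvidence,
    line_file_paths,
    write_fasta,
    write_gff3,
    write_indel_evidence,
    write_pileup,
)

GENE_LENGTH = 999  # bp, multiple of 3


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth mutation planted in one line (or, for progenitor
    variants, in many lines)."""

    line: str
    position: int
    mtype: str
    ref: str = ""
    alt: str = ""
    motif: str = ""
    size: int = 1
    progenitor: bool = False

    @property
    def key(self) -> tuple:
        if self.mtype == BPS:
            return (self.line, self.position, BPS, self.alt)
        return (self.line, self.position, self.mtype, self.size, self.motif)


@dataclass
class TruthCatalog:
    """All planted events; the reference answer for recovery tests."""

    events: list[PlantedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.events:
            k = (e.line, e.position)
            if k in seen:
                raise ValueError(f"two planted events at {k}")
            seen.add(k)

    def for_line(self, line: str) -> list[PlantedEvent]:
        return [e for e in self.events if e.line == line]

    def de_novo(self) -> list[PlantedEvent]:
        return [e for e in self.events if not e.progenitor]

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SimulationConfig:
    """Study-condition defaults; every knob is overridable.

    ``n_bps``, ``n_insertions`` and ``n_deletions`` are totals across all
    lines, dealt to lines uniformly at random.  ``aligner_discordance`` is
    the probability that a site's counts (or an indel's evidence record)
    differ between the two pseudo-aligner views.
    """

    n_lines: int = 47
    generations: float = 3025.0
    genome_length: int = 5_190_000
    gc_content: float = 0.51
    coding_fraction: float = 0.85
    coverage_mean: float = 100.0
    error_rate: float = 0.01
    aligner_discordance: float = 0.0
    n_bps: int = 779
    n_insertions: int = 33
    n_deletions: int = 73
    indel_sizes: tuple[int, ...] = (1, 1, 2, 3, 4, 5)
    n_clustered_pairs: int = 0
    cluster_window: int = 50
    n_progenitor_indels: int = 0
    progenitor_fraction: float = 0.6
    evidence_support_fraction: float = 0.95
    paired_evidence_min_size: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_content",):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        for name in (
            "coding_fraction",
            "error_rate",
            "aligner_discordance",
            "evidence_support_fraction",
            "progenitor_fraction",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_lines", "genome_length", "n_bps", "n_insertions", "n_deletions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i:03d}" for i in range(1, self.n_lines + 1)]


def generate_reference(
    length: int,
    gc_content: float,
    coding_fraction: float,
    seed: int,
    name: str = "chr",
) -> Genome:
    """Random circular genome with the requested approximate G+C fraction
    and non-overlapping genes covering about ``coding_fraction`` of sites.

    Deterministic for a fixed seed.  Genes are laid out on an even lattice
    with alternating strands; the replication terminus is placed at the
    antipode of position 1.
    """
    if length < 300:
        raise ValueError("genome length must be >= 300")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    if not 0 <= coding_fraction <= 1:
        raise ValueError("coding_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    codes = rng.choice(4, size=length, p=p)
    seq = "".join(BASES[c] for c in codes)
    genes: list[Gene] = []
    n_genes = int(round(length * coding_fraction / GENE_LENGTH))
    if n_genes > 0:
        stride = length / n_genes
        for i in range(n_genes):
            start = int(i * stride) + 1
            end = start + GENE_LENGTH - 1
            if end > length:
                break
            if genes and start <= genes[-1].end:
                start = genes[-1].end + 1
                end = start + GENE_LENGTH - 1
                if end > length:
                    break
            genes.append(Gene(start, end, "+-"[i % 2], f"g{i + 1:05d}"))
    return Genome(name=name, sequence=seq, genes=genes, terminus=length // 2 or 1)


def _random_motif(rng: np.random.Generator, size: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, size=size))


def plant_mutations(genome: Genome, config: SimulationConfig) -> TruthCatalog:
    """Plant mutations uniformly over the genome with the configured class
    totals (exact counts), clustered pairs closer than the window, and
    optional progenitor indels shared by more than half of the lines."""
    rng = np.random.default_rng(config.seed)
    L = genome.length
    lines = config.line_ids
    n_single = config.n_bps + config.n_insertions + config.n_deletions
    n_cluster_extra = config.n_clustered_pairs  # second member of each pair
    n_prog = config.n_progenitor_indels
    margin = max(config.indel_sizes) + 1 if config.indel_sizes else 2
    if n_single + n_cluster_extra + n_prog > L // (2 * margin + config.cluster_window):
        raise ValueError("requested mutation count too large for the genome")

    # distinct anchor positions, kept apart by more than the clustering
    # window so only deliberately planted clusters are close together
    slot = 2 * margin + config.cluster_window + 1
    n_slots = (L - margin) // slot
    chosen = rng.choice(n_slots, size=n_single + n_cluster_extra + n_prog, replace=False)
    positions = (chosen * slot + margin + 1).astype(np.int64)
    pos_iter = iter(positions.tolist())

    events: list[PlantedEvent] = []
    line_choice = rng.integers(0, len(lines), size=n_single)
    kinds = [BPS] * config.n_bps + [INSERTION] * config.n_insertions + [
        DELETION
    ] * config.n_deletions
    for kind, li in zip(kinds, line_choice):
        pos = next(pos_iter)
        line = lines[li]
        if kind == BPS:
            ref = genome.base(pos)
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            events.append(PlantedEvent(line, pos, BPS, ref=ref, alt=alt))
        elif kind == DELETION:
            size = int(config.indel_sizes[rng.integers(0, len(config.indel_sizes))])
            motif = genome.slice(pos + 1, pos + size)
            events.append(PlantedEvent(line, pos, DELETION, motif=motif, size=size))
        else:
            size = int(config.indel_sizes[rng.integers(0, len(config.indel_sizes))])
            motif = _random_motif(rng, size)
            events.append(PlantedEvent(line, pos, INSERTION, motif=motif, size=size))

    # clustered pairs: a BPS planted within the window of an existing BPS
    bps_events = [e for e in events if e.mtype == BPS]
    if config.n_clustered_pairs > len(bps_events):
        raise ValueError("more clustered pairs requested than BPS events")
    for j in range(config.n_clustered_pairs):
        partner = bps_events[j]
        next(pos_iter)  # consume a slot to keep determinism of the layout
        offset = int(rng.integers(2, config.cluster_window))
        pos = (partner.position - 1 + offset) % L + 1
        ref = genome.base(pos)
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        events.append(PlantedEvent(partner.line, pos, BPS, ref=ref, alt=alt))

    # progenitor indels: identical event in > progenitor_fraction of lines
    n_carriers = int(np.ceil(config.progenitor_fraction * len(lines)))
    for _ in range(n_prog):
        pos = next(pos_iter)
        size = int(config.indel_sizes[0]) if config.indel_sizes else 1
        motif = genome.slice(pos + 1, pos + size)
        carriers = rng.choice(len(lines), size=n_carriers, replace=False)
        for li in carriers:
            events.append(
                PlantedEvent(
                    lines[li], pos, DELETION, motif=motif, size=size, progenitor=True
                )
            )
    return TruthCatalog(events=events)


@dataclass
class SimData:
    """In-memory simulation output: per-line, per-aligner dense count
    matrices plus indel-evidence records."""

    genome: Genome
    truth: TruthCatalog
    config: SimulationConfig
    counts: dict[str, tuple[np.ndarray, np.ndarray]]
    evidence: dict[str, dict[str, list[IndelEvidence]]]


def _counts_for_allele(
    rng: np.random.Generator, allele_codes: np.ndarray, coverage: float, error: float
) -> np.ndarray:
    """One aligner view: (L, 8) counts with Poisson depth, binomial strand
    split, and uniform-substitution sequencing error."""
    L = allele_codes.size
    depth = rng.poisson(coverage, size=L)
    errors = rng.binomial(depth, error) if error > 0 else np.zeros(L, dtype=np.int64)
    correct = depth - errors
    counts4 = np.zeros((L, 4), dtype=np.int64)
    np.put_along_axis(counts4, allele_codes[:, None], correct[:, None], axis=1)
    if error > 0:
        e1 = rng.binomial(errors, 1.0 / 3.0)
        e2 = rng.binomial(errors - e1, 0.5)
        e3 = errors - e1 - e2
        # the three non-true bases in cyclic order after the true base
        for k, e in enumerate((e1, e2, e3), start=1):
            target = (allele_codes + k) % 4
            cur = np.take_along_axis(counts4, target[:, None], axis=1)[:, 0]
            np.put_along_axis(counts4, target[:, None], (cur + e)[:, None], axis=1)
    fwd = rng.binomial(counts4, 0.5)
    out = np.empty((L, 8), dtype=np.int32)
    out[:, 0::2] = fwd
    out[:, 1::2] = counts4 - fwd
    return out


def simulate_counts(
    genome: Genome, truth: TruthCatalog, config: SimulationConfig
) -> SimData:
    """Generate both pseudo-aligner count matrices and indel-evidence
    records for every line.

    BPSs replace the line's allele at their site; indels leave site counts
    untouched (reads spanning an indel still pile up on the reference
    coordinates) and instead emit evidence records.  An evidence record
    appears in both aligner views except with probability
    ``aligner_discordance``, in which case only aligner 1 reports it.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xA1])
    )
    L = genome.length
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    evidence: dict[str, dict[str, list[IndelEvidence]]] = {}
    for line in config.line_ids:
        allele = genome.codes.copy().astype(np.int64)
        for e in truth.for_line(line):
            if e.mtype == BPS:
                allele[e.position - 1] = BASES.index(e.alt)
        a1 = _counts_for_allele(rng, allele, config.coverage_mean, config.error_rate)
        if config.aligner_discordance <= 0:
            a2 = a1.copy()
        else:
            a2 = a1.copy()
            mask = rng.random(L) < config.aligner_discordance
            if mask.any():
                redraw = _counts_for_allele(
                    rng, allele[mask], config.coverage_mean, config.error_rate
                )
                a2[mask] = redraw
        counts[line] = (a1, a2)

        ev: dict[str, list[IndelEvidence]] = {"aligner1": [], "aligner2": [], "paired": []}
        for e in truth.for_line(line):
            if e.mtype == BPS:
                continue
            spanning = max(int(rng.poisson(config.coverage_mean)), 1)
            support = int(rng.binomial(spanning, config.evidence_support_fraction))
            fwd = int(rng.binomial(support, 0.5))
            rec = IndelEvidence(
                e.position, e.mtype, e.size, e.motif, fwd, support - fwd, spanning
            )
            if e.size >= config.paired_evidence_min_size:
                ev["paired"].append(rec)
            else:
                ev["aligner1"].append(rec)
                if rng.random() >= config.aligner_discordance:
                    ev["aligner2"].append(rec)
        for key in ev:
            ev[key].sort(key=lambda r: r.position)
        evidence[line] = ev
    return SimData(genome=genome, truth=truth, config=config, counts=counts, evidence=evidence)


def emit_pileups(simdata: SimData, outdir) -> Path:
    """Write the simulation to disk: per-line pileup and evidence TSVs,
    the reference FASTA/GFF3, and the truth catalog TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fa", simdata.genome)
    write_gff3(outdir / "genes.gff3", simdata.genome)
    for line, (a1, a2) in simdata.counts.items():
        paths = line_file_paths(outdir, line)
        write_pileup(paths["aligner1"], a1)
        write_pileup(paths["aligner2"], a2)
        ev = simdata.evidence[line]
        write_indel_evidence(paths["evidence1"], ev["aligner1"])
        write_indel_evidence(paths["evidence2"], ev["aligner2"])
        write_indel_evidence(paths["paired"], ev["paired"])
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("line\tposition\ttype\tref\talt\tmotif\tsize\tprogenitor\n")
        for e in simdata.truth.events:
            fh.write(
                f"{e.line}\t{e.position}\t{e.mtype}\t{e.ref}\t{e.alt}\t"
                f"{e.motif}\t{e.size}\t{int(e.progenitor)}\n"
            )
    return outdir


def simulate(config: SimulationConfig) -> SimData:
    """Convenience wrapper: reference + planted truth + count matrices."""
    genome = generate_reference(
        config.genome_length, config.gc_content, config.coding_fraction, config.seed
    )
    truth = plant_mutations(genome, config)
    return simulate_counts(genome, truth, config)


def simulate_silent_alignment(
    n_sequences: int, n_codons: int, diversity: float, seed: int
) -> list[str]:
    """Codon-aligned synthetic strain set for silent-site diversity.

    Every codon belongs to a four-fold degenerate family (prefix drawn
    from GC/GG/CT/GT...), so all third positions are eligible silent
    sites; each strain's third base mutates away from the ancestral base
    with probability ``diversity``.
    """
    if n_sequences < 2 or n_codons < 1:
        raise ValueError("need >= 2 sequences and >= 1 codon")
    rng = np.random.default_rng(seed)
    fourfold_prefixes = ["GC", "GG", "CT", "GT", "CC", "CG", "AC", "TC"]
    prefixes = [fourfold_prefixes[int(i)] for i in rng.integers(0, 8, size=n_codons)]
    anc_third = rng.integers(0, 4, size=n_codons)
    seqs = []
    for _ in range(n_sequences):
        mutate = rng.random(n_codons) < diversity
        shift = rng.integers(1, 4, size=n_codons)
        third = np.where(mutate, (anc_third + shift) % 4, anc_third)
        seqs.append("".join(p + BASES[t] for p, t in zip(prefixes, third)))
    return seqs
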
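"""Readers and writers for the on-disk formats of the pipeline.

Formats
-------
* pileup TSV: per-site read-count configuration, columns
  ``pos A a C c G g T t`` — uppercase columns are forward-strand reads,
  lowercase reverse-strand, in fixed A, C, G, T base order.  Positions are
  1-based; missing positions mean zero coverage.  Lines beginning with
  ``#`` are comments.
* indel-evidence TSV: ``pos type size motif fwd_support rev_support
  spanning_reads`` (``.`` for an empty motif, e.g. very long deletions
  reported by paired-end realignment).
* mutation-catalog TSV and per-line metadata TSV.
* FASTA reference (Biopython), GFF3 gene annotation (gffutils) and VCF 4.2
  output of accepted calls.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import BPS, DELETION, INSERTION, LineMeta, MutationCall, MutationCatalog
from .genome import Gene, Genome

PILEUP_COLUMNS = ("pos", "A", "a", "C", "c", "G", "g", "T", "t")
EVIDENCE_COLUMNS = (
    "pos",
    "type",
    "size",
    "motif",
    "fwd_support",
    "rev_support",
    "spanning_reads",
)


class PileupParseError(ValueError):
    """Malformed pileup or evidence row; message carries the line number."""


class SiteCounts:
    """The 8-number read configuration (A, a, C, c, G, g, T, t) at one
    genomic site."""

    __slots__ = ("position", "counts")

    def __init__(self, position: int, counts):
        counts = tuple(int(c) for c in counts)
        if position < 1:
            raise ValueError("position must be >= 1")
        if len(counts) != 8:
            raise ValueError("exactly 8 counts required")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        self.position = int(position)
        self.counts = counts

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SiteCounts)
            and self.position == other.position
            and self.counts == other.counts
        )

    def __repr__(self) -> str:
        return f"SiteCounts({self.position}, {self.counts})"


class IndelEvidence:
    """One aligner's (or the paired-end realigner's) evidence for an indel
    at a site: supporting forward/reverse reads out of the reads spanning
    the position."""

    __slots__ = ("position", "kind", "size", "motif", "fwd", "rev", "spanning", "source")

    def __init__(self, position, kind, size, motif, fwd, rev, spanning, source=""):
        if kind not in (INSERTION, DELETION):
            raise ValueError(f"indel type must be insertion/deletion, got {kind!r}")
        if size < 1:
            raise ValueError("indel size must be >= 1")
        if fwd < 0 or rev < 0 or spanning < 0:
            raise ValueError("read counts must be non-negative")
        if fwd + rev > spanning:
            raise ValueError("supporting reads exceed spanning reads")
        self.position = int(position)
        self.kind = kind
        self.size = int(size)
        self.motif = motif or ""
        self.fwd = int(fwd)
        self.rev = int(rev)
        self.spanning = int(spanning)
        self.source = source

    @property
    def key(self) -> tuple:
        """(position, type, size, motif): the identity two aligners must
        agree on for a consensus indel."""
        return (self.position, self.kind, self.size, self.motif)

    @property
    def support(self) -> int:
        return self.fwd + self.rev

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IndelEvidence)
            and self.key == other.key
            and (self.fwd, self.rev, self.spanning) == (other.fwd, other.rev, other.spanning)
        )

    def __repr__(self) -> str:
        return f"IndelEvidence({self.position}, {self.kind}, {self.size}, {self.motif!r})"


# ---------------------------------------------------------------------------
# pileup TSV


def read_pileup(path) -> Iterator[SiteCounts]:
    """Yield SiteCounts in ascending position order.

    Raises PileupParseError (naming the offending line number) on rows with
    the wrong column count, non-integer or negative values, or positions
    out of order.
    """
    last = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            row = raw.strip()
            if not row or row.startswith("#"):
                continue
            fields = row.split("\t") if "\t" in row else row.split()
            if len(fields) != 9:
                raise PileupParseError(
                    f"{path}:{lineno}: expected 9 columns, found {len(fields)}"
                )
            try:
                values = [int(f) for f in fields]
            except ValueError as exc:
                raise PileupParseError(f"{path}:{lineno}: non-integer field") from exc
            if any(v < 0 for v in values):
                raise PileupParseError(f"{path}:{lineno}: negative value")
            if values[0] <= last:
                raise PileupParseError(
                    f"{path}:{lineno}: positions not strictly increasing"
                )
            last = values[0]
            yield SiteCounts(values[0], values[1:])


def write_pileup(path, sites: Iterable[SiteCounts] | np.ndarray) -> None:
    """Write a pileup TSV.  ``sites`` is either SiteCounts records or a
    dense (L, 8) count matrix whose row i is position i+1 (all-zero rows
    are omitted, matching the zero-coverage-is-absent convention)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PILEUP_COLUMNS) + "\n")
        if isinstance(sites, np.ndarray):
            matrix = np.asarray(sites)
            keep = matrix.sum(axis=1) > 0
            positions = np.nonzero(keep)[0] + 1
            out = np.column_stack([positions, matrix[keep]])
            np.savetxt(fh, out, fmt="%d", delimiter="\t")
        else:
            for s in sites:
                fh.write("\t".join(map(str, (s.position, *s.counts))) + "\n")


def load_pileup_matrix(path, length: int) -> np.ndarray:
    """Read a pileup TSV into a dense (length, 8) int32 matrix (row i is
    position i+1; absent positions are zero coverage)."""
    matrix = np.zeros((length, 8), dtype=np.int32)
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None, names=PILEUP_COLUMNS, dtype=np.int64
    )
    if len(df):
        pos = df["pos"].to_numpy()
        if pos.min() < 1 or pos.max() > length:
            raise PileupParseError(f"{path}: position outside genome of {length}")
        matrix[pos - 1] = df.iloc[:, 1:].to_numpy(dtype=np.int32)
    return matrix


# ---------------------------------------------------------------------------
# indel-evidence TSV


def read_indel_evidence(path, source: str = "") -> list[IndelEvidence]:
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            row = raw.strip()
            if not row or row.startswith("#"):
                continue
            fields = row.split("\t") if "\t" in row else row.split()
            if len(fields) != 7:
                raise PileupParseError(
                    f"{path}:{lineno}: expected 7 columns, found {len(fields)}"
                )
            pos, kind, size, motif, fwd, rev, spanning = fields
            motif = "" if motif == "." else motif
            try:
                records.append(
                    IndelEvidence(
                        int(pos), kind, int(size), motif, int(fwd), int(rev),
                        int(spanning), source=source,
                    )
                )
            except ValueError as exc:
                raise PileupParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_indel_evidence(path, records: Iterable[IndelEvidence]) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(EVIDENCE_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    map(
                        str,
                        (
                            r.position,
                            r.kind,
                            r.size,
                            r.motif or ".",
                            r.fwd,
                            r.rev,
                            r.spanning,
                        ),
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# mutation catalog TSV + line metadata


def write_catalog(path, catalog: MutationCatalog) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog(path, meta_path=None) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t", dtype={"line": str}, keep_default_na=False)
    calls = [
        MutationCall(
            line=str(r.line),
            position=int(r.position),
            mtype=str(r.type),
            ref=str(r.ref),
            alt=str(r.alt),
            motif=str(r.motif),
            size=int(r.size),
            fwd=int(r.fwd),
            rev=int(r.rev),
        )
        for r in df.itertuples()
    ]
    lines = read_line_meta(meta_path) if meta_path else {}
    return MutationCatalog(calls=calls, lines=lines)


def write_line_meta(path, lines: dict[str, LineMeta]) -> None:
    with open(path, "w") as fh:
        fh.write("line\tgenerations\tsites_analyzed\n")
        for lid in sorted(lines):
            m = lines[lid]
            fh.write(f"{lid}\t{m.generations:g}\t{m.sites_analyzed}\n")


def read_line_meta(path) -> dict[str, LineMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"line": str})
    return {
        str(r.line): LineMeta(str(r.line), float(r.generations), int(r.sites_analyzed))
        for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# FASTA / GFF3


def write_fasta(path, genome: Genome) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([rec], path, "fasta")


def read_fasta(path, name: str | None = None) -> tuple[str, str]:
    """Return (name, sequence) of the first (or named) record."""
    for rec in SeqIO.parse(path, "fasta"):
        if name is None or rec.id == name:
            return rec.id, str(rec.seq).upper()
    raise ValueError(f"no record {name!r} in {path}")


def write_gff3(path, genome: Genome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for i, g in enumerate(genome.genes, start=1):
            name = g.name or f"gene{i:05d}"
            fh.write(
                f"{genome.name}\tmacall\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={name}\n"
            )


def read_gff3_genes(path) -> list[Gene]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(("gene", "CDS")):
        name = feat.id or ""
        genes.append(Gene(feat.start, feat.end, feat.strand, name))
    return sorted(genes, key=lambda g: g.start)


def read_genome(fasta_path, gff_path=None, terminus: int | None = None) -> Genome:
    name, seq = read_fasta(fasta_path)
    genes = read_gff3_genes(gff_path) if gff_path else []
    return Genome(name=name, sequence=seq, genes=genes, terminus=terminus)


# ---------------------------------------------------------------------------
# VCF output


def write_vcf(catalog: MutationCatalog, genome: Genome, path) -> None:
    """Write accepted calls as VCF 4.2.

    BPS become SNV records.  Indels are left-anchored on the base before
    the event: a deletion of sequence S whose anchor base is at POS is
    written REF=anchor+S, ALT=anchor; an insertion of motif M after POS is
    REF=anchor, ALT=anchor+M.  Per-line genotypes are haploid 0/1 sample
    columns.
    """
    samples = catalog.line_ids
    by_record: dict[tuple, tuple[str, str, set[str]]] = {}
    for c in catalog.calls:
        if c.mtype == BPS:
            if not 1 <= c.position <= genome.length:
                raise ValueError(f"call position {c.position} outside genome")
            ref, alt = c.ref or genome.base(c.position), c.alt
            pos = c.position
        elif c.mtype == DELETION:
            if not 1 <= c.position <= genome.length or c.position + c.size > genome.length:
                raise ValueError(f"deletion at {c.position} outside genome")
            anchor = genome.base(c.position)
            deleted = c.motif or genome.slice(c.position + 1, c.position + c.size)
            ref, alt, pos = anchor + deleted, anchor, c.position
        else:  # insertion
            if not 1 <= c.position <= genome.length:
                raise ValueError(f"insertion at {c.position} outside genome")
            anchor = genome.base(c.position)
            motif = c.motif or "N" * c.size
            ref, alt, pos = anchor, anchor + motif, c.position
        key = (pos, ref, alt)
        by_record.setdefault(key, (ref, alt, set()))[2].add(c.line)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.name},length={genome.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (pos, ref, alt) in sorted(by_record):
            carriers = by_record[(pos, ref, alt)][2]
            gts = ["1" if s in carriers else "0" for s in samples]
            fh.write(
                f"{genome.name}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def line_file_paths(outdir, line: str) -> dict[str, Path]:
    """Canonical per-line file names inside a simulation/calling directory."""
    outdir = Path(outdir)
    return {
        "aligner1": outdir / f"{line}.aligner1.pileup.tsv",
        "aligner2": outdir / f"{line}.aligner2.pileup.tsv",
        "evidence1": outdir / f"{line}.aligner1.indels.tsv",
        "evidence2": outdir / f"{line}.aligner2.indels.tsv",
        "paired": outdir / f"{line}.paired.indels.tsv",
    }


def discover_lines(directory) -> list[str]:
    """Line ids present in a directory of per-line pileup files."""
    lines = set()
    for fn in os.listdir(directory):
        if fn.endswith(".aligner1.pileup.tsv"):
            lines.add(fn[: -len(".aligner1.pileup.tsv")])
    return sorted(lines)
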
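"""Mutation catalog: accepted calls across MA lines plus per-line metadata.

The catalog is the central exchange object of the pipeline: the caller
produces it, and the rate, spectrum, context and clustering analyses all
consume it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

BPS = "bps"
INSERTION = "insertion"
DELETION = "deletion"
MUTATION_TYPES = (BPS, INSERTION, DELETION)


@dataclass(frozen=True)
class MutationCall:
    """One accepted mutation event in one MA line.

    ``position`` is 1-based.  For a base-pair substitution (BPS) it is the
    mutated site and ``ref``/``alt`` are single bases.  For indels it is
    the anchor base *before* the event (VCF convention); ``motif`` holds
    the inserted/deleted sequence and may be empty for long deletions
    where only the size is known.
    """

    line: str
    position: int
    mtype: str
    ref: str = ""
    alt: str = ""
    motif: str = ""
    size: int = 1
    fwd: int = 0
    rev: int = 0
    dual_aligner: bool = True

    def __post_init__(self) -> None:
        if self.mtype not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation type {self.mtype!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.mtype == BPS:
            if self.size != 1:
                raise ValueError("BPS size must be 1")
            if self.ref == self.alt:
                raise ValueError("BPS requires ref != alt")
        if self.fwd < 0 or self.rev < 0:
            raise ValueError("support counts must be non-negative")

    @property
    def key(self) -> tuple:
        """Identity of the event irrespective of line (for the shared-event
        progenitor filter)."""
        if self.mtype == BPS:
            return (self.position, BPS, self.ref, self.alt)
        return (self.position, self.mtype, self.size, self.motif)


@dataclass(frozen=True)
class LineMeta:
    """Per-line denominators for rate estimation: T generations and n
    analyzed sites."""

    line: str
    generations: float
    sites_analyzed: int

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        if self.sites_analyzed <= 0:
            raise ValueError("sites_analyzed must be > 0")


@dataclass
class MutationCatalog:
    calls: list[MutationCall] = field(default_factory=list)
    lines: dict[str, LineMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for c in self.calls:
            k = (c.line, c.position, c.mtype)
            if k in seen:
                raise ValueError(f"duplicate call at {k}")
            seen.add(k)

    @property
    def line_ids(self) -> list[str]:
        ids = set(self.lines) | {c.line for c in self.calls}
        return sorted(ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def bps_calls(self) -> list[MutationCall]:
        return [c for c in self.calls if c.mtype == BPS]

    def indel_calls(self) -> list[MutationCall]:
        return [c for c in self.calls if c.mtype != BPS]

    def calls_for_line(self, line: str) -> list[MutationCall]:
        return [c for c in self.calls if c.line == line]

    def total_generations(self) -> float:
        """Sum of per-line generation counts (the ΣT denominator for
        per-generation-per-line quantities)."""
        if not self.lines:
            raise ValueError("catalog has no line metadata")
        return float(sum(m.generations for m in self.lines.values()))

    def per_line_counts(self) -> pd.DataFrame:
        """DataFrame indexed by line with m_bps, m_indel, m_total columns;
        includes metadata lines with zero calls."""
        rows = {lid: {"m_bps": 0, "m_indel": 0} for lid in self.line_ids}
        for c in self.calls:
            col = "m_bps" if c.mtype == BPS else "m_indel"
            rows[c.line][col] += 1
        df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        df["m_total"] = df["m_bps"] + df["m_indel"]
        for lid in df.index:
            meta = self.lines.get(lid)
            df.loc[lid, "generations"] = meta.generations if meta else float("nan")
            df.loc[lid, "sites_analyzed"] = meta.sites_analyzed if meta else float("nan")
        return df

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "line": c.line,
                    "position": c.position,
                    "type": c.mtype,
                    "ref": c.ref,
                    "alt": c.alt,
                    "motif": c.motif,
                    "size": c.size,
                    "fwd": c.fwd,
                    "rev": c.rev,
                }
                for c in self.calls
            ],
            columns=[
                "line",
                "position",
                "type",
                "ref",
                "alt",
                "motif",
                "size",
                "fwd",
                "rev",
            ],
        )

    def relabel_lines(self, mapping: dict[str, str]) -> "MutationCatalog":
        """Return a copy with line ids renamed (a pure permutation of labels
        must not change any summary statistic)."""
        calls = [replace(c, line=mapping.get(c.line, c.line)) for c in self.calls]
        lines = {
            mapping.get(lid, lid): replace(m, line=mapping.get(lid, lid))
            for lid, m in self.lines.items()
        }
        return MutationCatalog(calls=calls, lines=lines)
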
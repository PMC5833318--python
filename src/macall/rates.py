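"""Mutation-rate estimation for MA lines.

For a line with m observed events over n analyzed sites and T
generations, the per-site per-generation rate is mu = m / (n T) with
standard error sqrt(mu / (n T)) (equivalently sqrt(m) / (n T), the
Poisson-counting error).  Pooling across N lines uses the mean of the
per-line rates with SE = s / sqrt(N), where s is the sample (N-1)
standard deviation of the per-line rates.  Generation totals come from
the harmonic mean of the measured cell divisions per transfer, with
divisions per transfer read off colony counts as log2(CFU).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2, sqrt

import numpy as np
import pandas as pd
from scipy.stats import hmean

from .catalog import MutationCatalog


@dataclass(frozen=True)
class RateEstimate:
    """A rate (events/site/generation) with its standard error; for
    pooled estimates ``n_lines`` and the across-line SD ``s`` are kept."""

    rate: float
    se: float
    n_lines: int = 1
    s: float | None = None

    def __post_init__(self) -> None:
        if self.rate < 0 or self.se < 0:
            raise ValueError("rate and SE must be non-negative")


def line_rate(m: int, n: float, T: float) -> RateEstimate:
    """Per-line rate m/(nT) and its SE sqrt(rate/(nT))."""
    if n <= 0 or T <= 0:
        raise ValueError("n and T must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    rate = m / (n * T)
    return RateEstimate(rate=rate, se=sqrt(rate / (n * T)))


def pooled_rate(rates) -> RateEstimate:
    """Pooled estimate across lines: mean of per-line rates, SE = s/sqrt(N).

    ``rates`` is a sequence of per-line rates (floats or RateEstimate).
    """
    values = np.array(
        [r.rate if isinstance(r, RateEstimate) else float(r) for r in rates]
    )
    if values.size < 2:
        raise ValueError("pooling needs at least 2 lines")
    s = float(values.std(ddof=1))
    return RateEstimate(
        rate=float(values.mean()),
        se=s / sqrt(values.size),
        n_lines=int(values.size),
        s=s,
    )


def per_genome_rate(rate: RateEstimate | float, n_effective: float) -> float:
    """Convert a per-site rate to events per genome replication using the
    effective (analyzed) site count as the multiplier."""
    if n_effective <= 0:
        raise ValueError("n_effective must be positive")
    r = rate.rate if isinstance(rate, RateEstimate) else float(rate)
    return r * n_effective


def divisions_from_cfu(cfu: float) -> float:
    """Cell divisions represented by a colony of ``cfu`` cells (log2)."""
    if cfu < 1:
        raise ValueError("CFU count must be >= 1")
    return log2(cfu)


def generations_harmonic(divisions_per_transfer, n_transfers: int) -> float:
    """Total generations = harmonic mean of divisions per transfer times
    the number of transfers."""
    divisions = np.asarray(list(divisions_per_transfer), dtype=float)
    if divisions.size == 0 or np.any(divisions <= 0):
        raise ValueError("all division counts must be positive")
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    return float(hmean(divisions)) * n_transfers


def catalog_rates(catalog: MutationCatalog) -> pd.DataFrame:
    """Per-line and pooled BPS/indel rates from a catalog with line
    metadata; the pooled row is labeled ``"pooled"``."""
    counts = catalog.per_line_counts()
    rows = []
    for lid, row in counts.iterrows():
        meta = catalog.lines[lid]
        rb = line_rate(int(row.m_bps), meta.sites_analyzed, meta.generations)
        ri = line_rate(int(row.m_indel), meta.sites_analyzed, meta.generations)
        rows.append(
            {
                "line": lid,
                "m_bps": int(row.m_bps),
                "m_indel": int(row.m_indel),
                "n_sites": meta.sites_analyzed,
                "generations": meta.generations,
                "bps_rate": rb.rate,
                "bps_se": rb.se,
                "indel_rate": ri.rate,
                "indel_se": ri.se,
                "bps_per_genome": per_genome_rate(rb, meta.sites_analyzed),
            }
        )
    df = pd.DataFrame(rows).set_index("line")
    if len(df) >= 2:
        pb = pooled_rate(df["bps_rate"])
        pi = pooled_rate(df["indel_rate"])
        pooled = {
            "m_bps": df["m_bps"].sum(),
            "m_indel": df["m_indel"].sum(),
            "n_sites": df["n_sites"].mean(),
            "generations": df["generations"].sum(),
            "bps_rate": pb.rate,
            "bps_se": pb.se,
            "indel_rate": pi.rate,
            "indel_se": pi.se,
            "bps_per_genome": pb.rate * df["n_sites"].mean(),
        }
        df.loc["pooled"] = pooled
    return df
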
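"""Multinucleotide mutations (MNMs): clustered events within a window.

Two constructs, documented as distinct:

* the *detector* groups a line's events by consecutive circular distance
  — a cluster is a maximal run of events whose successive gaps are all
  strictly below the window length;
* the *window model* tiles the genome into floor(genome/window)
  non-overlapping windows and asks, under a uniform Poisson placement of
  the observed per-line mutation load, for the chance that at least one
  window in one line holds two or more mutations:

      P = 1 - [P(X <= 1; Poisson lambda)] ** n_windows

  with lambda = total_bps / genome_size / n_lines * window.  The
  analytic value is cross-checked by a Monte-Carlo oracle that scatters
  events uniformly and counts replicates with a doubly-hit window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .catalog import MutationCatalog
from .genome import circular_distance


@dataclass(frozen=True)
class MnmParams:
    """Poisson-window parameters of the MNM expectation."""

    lam: float
    window: int
    n_windows: int
    total_bps: int
    genome_size: int
    n_lines: int

    def __post_init__(self) -> None:
        if min(self.lam, self.window, self.n_windows, self.genome_size, self.n_lines) <= 0:
            raise ValueError("all MNM parameters must be positive")

    @classmethod
    def from_counts(
        cls, total_bps: int, genome_size: int, n_lines: int, window: int
    ) -> "MnmParams":
        """The per-window rate: observed mutations divided by genome size
        and by the number of lines, times the window length."""
        lam = total_bps / genome_size / n_lines * window
        return cls(
            lam=lam,
            window=window,
            n_windows=genome_size // window,
            total_bps=total_bps,
            genome_size=genome_size,
            n_lines=n_lines,
        )


@dataclass(frozen=True)
class MnmCluster:
    """Two or more events of one line closer than the window."""

    line: str
    positions: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.positions)


def detect_mnm(
    catalog: MutationCatalog, window: int, genome_length: int
) -> list[MnmCluster]:
    """Maximal within-line clusters: events whose consecutive circular
    distances are all < window.  Clusters of three or more events are
    reported as a single cluster."""
    if window < 2:
        raise ValueError("window must be >= 2")
    clusters: list[MnmCluster] = []
    by_line: dict[str, list[int]] = {}
    for c in catalog.calls:
        by_line.setdefault(c.line, []).append(c.position)
    for line in sorted(by_line):
        pos = sorted(by_line[line])
        if len(pos) < 2:
            continue
        groups: list[list[int]] = [[pos[0]]]
        for p in pos[1:]:
            if p - groups[-1][-1] < window:
                groups[-1].append(p)
            else:
                groups.append([p])
        # the circle: the gap from the last event back to the first may
        # merge the first and last groups
        if len(groups) > 1 and circular_distance(pos[-1], pos[0], genome_length) < window:
            groups[0] = groups.pop() + groups[0]
        for g in groups:
            if len(g) >= 2:
                clusters.append(MnmCluster(line=line, positions=tuple(g)))
    return clusters


def clustered_event_count(clusters: list[MnmCluster]) -> int:
    return sum(c.size for c in clusters)


def mnm_expected_probability(params: MnmParams) -> float:
    """Analytic chance of at least one doubly-hit window in one line,
    evaluated in log space for numerical stability."""
    if params.lam <= 0:
        raise ValueError("lambda must be positive")
    log_cdf1 = poisson.logcdf(1, params.lam)
    return float(-np.expm1(params.n_windows * log_cdf1))


def mnm_mc_oracle(
    params: MnmParams, reps: int, seed: int
) -> tuple[float, float]:
    """Monte-Carlo estimate of the MNM probability with its binomial SE.

    Each replicate scatters a Poisson(lambda x n_windows) number of
    events uniformly over the tiled genome (one MA line's expected load)
    and succeeds when any window receives two or more events.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    mean_events = params.lam * params.n_windows
    n_events = rng.poisson(mean_events, size=reps)
    total = int(n_events.sum())
    windows = rng.integers(0, params.n_windows, size=total)
    rep_ids = np.repeat(np.arange(reps), n_events)
    keys = rep_ids.astype(np.int64) * params.n_windows + windows
    _, first_idx, counts = np.unique(keys, return_index=True, return_counts=True)
    hit_reps = np.unique(rep_ids[first_idx[counts >= 2]])
    p_hat = hit_reps.size / reps
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 1.0 / reps) / reps))
    return float(p_hat), se
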
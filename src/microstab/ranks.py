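"""Rank dynamics of the dominant taxa: RSI, RV and DV.

Taxa are ordered by accumulated relative abundance over the series (the
"overall rank"); at each timepoint the same fixed set of top taxa is
re-ranked by instantaneous abundance.  Three statistics summarize the rank
matrix:

* RSI (rank stability index), per taxon: (1 − D/((N−1)(t−1)))^p, where D is
  the cumulative absolute rank displacement along the series.  RSI is 1 for
  a taxon whose rank never changes and 0 for a taxon oscillating between
  the extreme ranks at every step.  The power p (default 4) spreads the
  stable end of the scale.
* RV (rank variability), per timepoint: mean |rank − overall rank| over the
  taxa shown.
* DV (difference variability), per timepoint: mean |rank − previous rank|.

Mid-ranked taxa that stay put while their neighbours churn form "rank
stability islands" — see :func:`stability_islands`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .abundance import AbundanceTable

__all__ = [
    "RankMatrix",
    "RankReport",
    "rank_over_time",
    "rsi",
    "rank_variability",
    "difference_variability",
    "stability_islands",
    "rank_report",
]

DEFAULT_P = 4


@dataclass(frozen=True)
class RankMatrix:
    """Per-timepoint ranks (1 = most abundant) of the top-N taxa.

    ``taxon_ids`` are listed by overall rank (descending accumulated
    abundance), so row i has overall rank i+1; every column of ``ranks`` is
    a permutation of 1..N.
    """

    taxon_ids: list[str]
    times: np.ndarray
    ranks: np.ndarray  # (N, t) integers in 1..N

    @property
    def N(self) -> int:
        return len(self.taxon_ids)

    @property
    def t(self) -> int:
        return int(self.times.size)

    def __post_init__(self) -> None:
        N, t = self.ranks.shape
        if N != len(self.taxon_ids) or t != self.times.size:
            raise ValueError("ranks shape must be (n_taxa, n_times)")
        expected = np.arange(1, N + 1)
        for k in range(t):
            if not np.array_equal(np.sort(self.ranks[:, k]), expected):
                raise ValueError(f"column {k} is not a permutation of 1..{N}")


@dataclass(frozen=True)
class RankReport:
    """RSI per taxon plus RV/DV per timepoint for one rank matrix."""

    taxon_ids: list[str]
    rsi: np.ndarray
    rv: np.ndarray
    dv: np.ndarray  # dv[0] is NaN (no previous timepoint)
    p: float = DEFAULT_P


def rank_over_time(
    table: AbundanceTable, top_n: int = 50, absent_rank_worst: bool = True
) -> RankMatrix:
    """Rank the top-N taxa (by accumulated abundance) at every timepoint.

    Ties — including taxa absent (zero) at a timepoint, which all tie at the
    bottom when ``absent_rank_worst`` — are broken by overall rank, then by
    taxon ID, so the matrix is deterministic.
    """
    if not table.is_relative:
        raise ValueError("table must be on the relative scale")
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    if top_n > table.n_taxa:
        raise ValueError(f"top_n={top_n} exceeds {table.n_taxa} taxa")
    acc = table.counts.sum(axis=1)
    # overall order: descending accumulated abundance, ID as tie-break
    order = sorted(range(table.n_taxa), key=lambda i: (-acc[i], table.taxon_ids[i]))
    keep = order[:top_n]
    ids = [table.taxon_ids[i] for i in keep]
    sub = table.counts[keep, :]

    ranks = np.empty((top_n, table.n_timepoints), dtype=int)
    for k in range(table.n_timepoints):
        col = sub[:, k]
        if not absent_rank_worst:
            col = np.where(col > 0, col, -np.inf)
        # sort by (-abundance, overall rank, id); rows are already in overall
        # order with unique ids, so row index is the full tie-break key
        idx = sorted(range(top_n), key=lambda i: (-col[i], i))
        for r, i in enumerate(idx, start=1):
            ranks[i, k] = r
    return RankMatrix(taxon_ids=ids, times=table.times.copy(), ranks=ranks)


def rsi(
    ranks: Sequence[int], N: int, t: int | None = None, p: float = DEFAULT_P
) -> float:
    """Rank stability index (1 − D/((N−1)(t−1)))^p of one taxon's rank series.

    D = Σ_k |rank_{k+1} − rank_k| is the cumulative rank displacement; the
    denominator (N−1)(t−1) is attained exactly by a series hopping between
    rank 1 and rank N at every step, making the index exactly 0 there and
    exactly 1 for a constant series.
    """
    r = np.asarray(ranks, dtype=float)
    if t is None:
        t = r.size
    if t < 2 or r.size != t:
        raise ValueError("need at least 2 timepoints with matching series length")
    if N < 2:
        raise ValueError("N must be >= 2")
    if np.any((r < 1) | (r > N)):
        raise ValueError(f"ranks must lie in 1..{N}")
    D = float(np.sum(np.abs(np.diff(r))))
    return float((1.0 - D / ((N - 1) * (t - 1))) ** p)


def rank_variability(matrix: RankMatrix) -> np.ndarray:
    """RV(k): mean |rank_i(k) − overall_rank_i| over the taxa shown."""
    overall = np.arange(1, matrix.N + 1)[:, None]
    return np.abs(matrix.ranks - overall).mean(axis=0)


def difference_variability(matrix: RankMatrix) -> np.ndarray:
    """DV(k): mean |rank_i(k) − rank_i(k−1)|; the first timepoint is NaN."""
    if matrix.t < 2:
        raise ValueError("need at least 2 timepoints")
    dv = np.empty(matrix.t)
    dv[0] = np.nan
    dv[1:] = np.abs(np.diff(matrix.ranks.astype(float), axis=1)).mean(axis=0)
    return dv


def rank_report(table: AbundanceTable, top_n: int = 50, p: float = DEFAULT_P) -> tuple[RankMatrix, RankReport]:
    """Convenience: rank matrix plus RSI/RV/DV in one call."""
    matrix = rank_over_time(table, top_n=top_n)
    vals = np.array(
        [rsi(matrix.ranks[i], N=matrix.N, t=matrix.t, p=p) for i in range(matrix.N)]
    )
    return matrix, RankReport(
        taxon_ids=matrix.taxon_ids,
        rsi=vals,
        rv=rank_variability(matrix),
        dv=difference_variability(matrix),
        p=p,
    )


def stability_islands(
    report: RankReport,
    matrix: RankMatrix,
    rsi_threshold: float = 0.70,
    rank_band: tuple[int, int] = (11, 40),
) -> list[str]:
    """Medium-ranked taxa that are anomalously rank-stable.

    A taxon is flagged when its overall rank lies within ``rank_band``
    (inclusive), its RSI is at least ``rsi_threshold``, and it beats at
    least one more-dominant taxon's RSI (stability amid instability, not
    merely riding a globally quiet community).
    """
    if not (0 <= rsi_threshold <= 1):
        raise ValueError("rsi_threshold must lie in [0, 1]")
    lo, hi = rank_band
    out: list[str] = []
    for i, tid in enumerate(report.taxon_ids):
        overall = i + 1
        if not (lo <= overall <= hi):
            continue
        if report.rsi[i] < rsi_threshold:
            continue
        if i > 0 and report.rsi[i] > report.rsi[:i].min():
            out.append(tid)
    return out
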
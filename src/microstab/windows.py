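"""Time course of the Taylor parameters via overlapping sliding windows.

The series is cut into contiguous subsets of ``window_size`` timepoints
(each next window adds the next sampling time and drops the earliest one),
each window is fitted independently, and the fitted (V, β) are plotted
against the window's mean sampling time.  A localized perturbation — an
antibiotic course, an infection — shows up as a V(t) excursion confined to
the windows overlapping it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .abundance import AbundanceTable, ValidationError, compute_stats
from .taylor import FitError, fit_taylor_xweighted

__all__ = ["WindowSeries", "sliding_taylor"]


@dataclass(frozen=True)
class WindowSeries:
    """Windowed Taylor-parameter series; failed windows hold NaN."""

    centers: np.ndarray  # mean sample time of each window
    V: np.ndarray
    err_V: np.ndarray
    beta: np.ndarray
    err_beta: np.ndarray
    window_size: int

    @property
    def n_windows(self) -> int:
        return int(self.centers.size)


def sliding_taylor(
    table: AbundanceTable,
    window_size: int = 5,
    min_nonzero: int = 2,
    n_replicates: int = 200,
    seed: int | None = None,
    mode: str = "loglog",
) -> WindowSeries:
    """Fit Taylor's law in every contiguous window of ``window_size`` points.

    Per window: per-taxon stats (taxa constant within the window drop out of
    the log-log fit, mirroring the global rules at window scale) followed by
    the stochastic x-weighted fit with a reduced replicate count.  A window
    whose fit fails is recorded as NaN rather than aborting the series.
    Returns t − window_size + 1 aligned windows.
    """
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    t = table.n_timepoints
    if t < window_size:
        raise ValidationError(
            f"{t} timepoints < window size {window_size}; nothing to window"
        )
    rng = np.random.default_rng(seed)
    n_win = t - window_size + 1
    centers = np.empty(n_win)
    V = np.full(n_win, np.nan)
    err_V = np.full(n_win, np.nan)
    beta = np.full(n_win, np.nan)
    err_beta = np.full(n_win, np.nan)
    for w in range(n_win):
        idx = range(w, w + window_size)
        centers[w] = float(table.times[list(idx)].mean())
        try:
            stats = compute_stats(table, min_nonzero=min_nonzero, timepoint_subset=idx)
            fit = fit_taylor_xweighted(
                stats,
                n_replicates=n_replicates,
                seed=int(rng.integers(2**31 - 1)),
                mode=mode,
            )
        except (FitError, ValidationError):
            continue
        V[w], err_V[w] = fit.V, fit.err_V
        beta[w], err_beta[w] = fit.beta, fit.err_beta
    return WindowSeries(
        centers=centers, V=V, err_V=err_V, beta=beta, err_beta=err_beta,
        window_size=window_size,
    )
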
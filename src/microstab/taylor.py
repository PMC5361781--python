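"""Taylor's power-law (fluctuation scaling) fits.

Across taxa, temporal dispersion scales with temporal mean as a power law,
σ_i = V · x̄_i^β.  On log-log axes V is the intercept (the fluctuation
amplitude a hypothetically dominant taxon would attain) and β the slope
(β = 1/2 is the Poisson class, β = 1 the exponential class).

The mean abundances x̄_i carry sampling error (their SEM), i.e. the error is
on the *independent* variable.  Two fitters handle this:

* :func:`fit_taylor_xweighted` — a stochastic, bootstrapping-like procedure:
  each replicate perturbs every x̄_i by a Gaussian draw with SD = SEM_i,
  refits the unweighted power law, and the replicate ensemble supplies the
  parameter estimates, their errors, and their correlation.
* :func:`fit_taylor_inversion` — the deterministic baseline: invert the
  variables, do the SEM-weighted fit of x on y, and algebraically revert.
  Adequate at high R², degrading as scatter grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .abundance import TaxonStats

__all__ = [
    "TaylorFit",
    "FitError",
    "fit_power_law_single",
    "fit_taylor_xweighted",
    "fit_taylor_inversion",
]

#: Floor applied to resampled means before the log transform.
X_FLOOR = 1e-12


class FitError(RuntimeError):
    """A power-law fit could not be performed on the given points."""


@dataclass(frozen=True)
class TaylorFit:
    """Fitted Taylor parameters for one microbiota state.

    ``V`` and ``beta`` are the power-law amplitude and exponent; ``err_V``
    and ``err_beta`` their standard-deviation uncertainties across bootstrap
    replicates (or from the weighted-regression covariance for the inversion
    baseline); ``r2`` the mean coefficient of determination (log space for
    mode "loglog"); ``param_corr`` the correlation between the V and β
    estimates.
    """

    V: float
    beta: float
    err_V: float
    err_beta: float
    r2: float
    param_corr: float
    n_replicates: int
    converged: bool
    fit_mode: str

    def __post_init__(self) -> None:
        if not (self.V > 0):
            raise FitError(f"fitted V must be positive, got {self.V}")
        if self.err_V < 0 or self.err_beta < 0:
            raise FitError("negative parameter uncertainties")

    def as_dict(self) -> dict:
        return {
            "V": self.V,
            "beta": self.beta,
            "err_V": self.err_V,
            "err_beta": self.err_beta,
            "r2": self.r2,
            "param_corr": self.param_corr,
            "n_replicates": self.n_replicates,
            "converged": self.converged,
            "fit_mode": self.fit_mode,
        }


def _usable(x: np.ndarray, y: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise FitError("non-finite input points")
    if mode == "loglog":
        keep = (x > 0) & (y > 0)
    else:
        keep = x > 0
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise FitError(f"only {x.size} usable points; at least 3 required")
    if np.ptp(x) == 0:
        raise FitError("degenerate input: all mean abundances equal")
    return x, y


def fit_power_law_single(
    x: Sequence[float], y: Sequence[float], mode: str = "loglog"
) -> tuple[float, float, float]:
    """Fit y = V·x^β to one set of (mean, SD) points; returns (V, beta, r2).

    ``mode="loglog"`` is ordinary least squares of log y on log x (r2 in log
    space); ``mode="nonlinear"`` is unweighted nonlinear least squares
    initialized from the log-log estimate (r2 in linear space).
    """
    x, y = _usable(x, y, mode)
    lx = np.log(np.clip(x, X_FLOOR, None))
    if mode == "loglog":
        ly = np.log(y)
        beta, logV = np.polyfit(lx, ly, 1)
        pred = logV + beta * lx
        ss_res = float(np.sum((ly - pred) ** 2))
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return float(np.exp(logV)), float(beta), r2
    if mode == "nonlinear":
        ypos = np.clip(y, X_FLOOR, None)
        b0, lv0 = np.polyfit(lx, np.log(ypos), 1)
        p0 = (float(np.exp(lv0)), float(b0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                popt, _ = optimize.curve_fit(
                    lambda xx, V, b: V * xx**b, x, y, p0=p0, maxfev=10000
                )
            except (RuntimeError, optimize.OptimizeWarning) as exc:
                raise FitError(f"nonlinear fit failed: {exc}") from exc
        V, beta = float(popt[0]), float(popt[1])
        pred = V * x**beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
        return V, beta, r2
    raise ValueError(f"unknown mode {mode!r}")


def _extract(stats: Sequence[TaxonStats], mode: str):
    # canonical taxon order makes the seeded fit independent of input order
    stats = sorted(stats, key=lambda s: (s.mean, s.sd, s.taxon_id))
    x = np.array([s.mean for s in stats], dtype=float)
    y = np.array([s.sd for s in stats], dtype=float)
    sem = np.array([s.sem for s in stats], dtype=float)
    if np.any(sem < 0):
        raise FitError("negative SEMs")
    if mode == "loglog":
        # constant taxa (sd = 0) have no log-scale dispersion point
        keep = y > 0
        x, y, sem = x[keep], y[keep], sem[keep]
    if x.size < 3:
        raise FitError(f"only {x.size} usable taxa; at least 3 required")
    return x, y, sem


def _loglog_batch(lx: np.ndarray, ly: np.ndarray):
    """Row-wise OLS of ly (1-D) on each row of lx; returns (logV, beta, r2)."""
    mx = lx.mean(axis=1, keepdims=True)
    my = ly.mean()
    dx = lx - mx
    dy = ly - my
    sxx = np.sum(dx * dx, axis=1)
    sxy = dx @ dy
    beta = sxy / sxx
    logV = my - beta * mx[:, 0]
    ss_tot = float(np.sum(dy * dy))
    resid = ly[None, :] - (logV[:, None] + beta[:, None] * lx)
    r2 = 1.0 - np.sum(resid * resid, axis=1) / ss_tot if ss_tot > 0 else np.ones_like(beta)
    return logV, beta, r2


def fit_taylor_xweighted(
    stats: Sequence[TaxonStats],
    n_replicates: int = 1000,
    rel_tol: float = 1e-3,
    seed: int | None = None,
    mode: str = "loglog",
    min_replicates: int = 200,
    check_every: int = 50,
    resample: str = "clamp",
) -> TaylorFit:
    """Stochastic x-weighted power-law fit of σ = V·x̄^β.

    Each replicate r resamples the mean axis, x*_i = x̄_i + v_i with
    v_i ~ Normal(0, SEM_i), then performs a full unweighted power-law fit.
    Final (V, β) are the replicate means, their errors the replicate standard
    deviations, r² the replicate mean, and ``param_corr`` the empirical
    Pearson correlation of the replicate ensemble {(V_r, β_r)}.

    Replication stops early once the running means of both parameters change
    by less than ``rel_tol`` between successive checks (every ``check_every``
    replicates, after at least ``min_replicates``); ``converged`` records
    whether the tolerance was met.

    Non-positive resampled means are clamped to a positive floor
    (``resample="clamp"``) or redrawn (``resample="redraw"``).
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    if resample not in ("clamp", "redraw"):
        raise ValueError(f"unknown resample policy {resample!r}")
    x, y, sem = _extract(stats, mode)
    rng = np.random.default_rng(seed)

    V_r: list[float] = []
    beta_r: list[float] = []
    r2_r: list[float] = []
    prev_mean: tuple[float, float] | None = None
    converged = False
    n_failed = 0

    def draw(n: int) -> np.ndarray:
        xs = x[None, :] + rng.normal(0.0, 1.0, size=(n, x.size)) * sem[None, :]
        if resample == "redraw":
            for _ in range(100):
                bad = xs <= 0
                if not bad.any():
                    break
                xs[bad] = (x[None, :] + rng.normal(0.0, 1.0, size=xs.shape) * sem[None, :])[bad]
        return np.clip(xs, X_FLOOR, None)

    done = 0
    while done < n_replicates:
        block = min(check_every, n_replicates - done)
        xs = draw(block)
        if mode == "loglog":
            logV, beta, r2 = _loglog_batch(np.log(xs), np.log(y))
            V_r.extend(np.exp(logV))
            beta_r.extend(beta)
            r2_r.extend(np.atleast_1d(r2))
        else:
            for row in xs:
                try:
                    V, b, r2v = fit_power_law_single(row, y, mode=mode)
                except FitError:
                    n_failed += 1
                    continue
                V_r.append(V)
                beta_r.append(b)
                r2_r.append(r2v)
        done += block
        if len(V_r) >= max(min_replicates, 2):
            cur = (float(np.mean(V_r)), float(np.mean(beta_r)))
            if prev_mean is not None:
                dv = abs(cur[0] - prev_mean[0]) / max(abs(prev_mean[0]), X_FLOOR)
                db = abs(cur[1] - prev_mean[1]) / max(abs(prev_mean[1]), X_FLOOR)
                if dv < rel_tol and db < rel_tol:
                    converged = True
                    break
            prev_mean = cur

    if len(V_r) < 2:
        raise FitError(f"all {n_failed + len(V_r)} replicate fits failed")
    V_arr, b_arr = np.asarray(V_r), np.asarray(beta_r)
    if np.std(V_arr) > 0 and np.std(b_arr) > 0:
        corr = float(np.corrcoef(V_arr, b_arr)[0, 1])
    else:
        corr = 0.0  # degenerate ensemble (e.g. all SEMs zero)
    return TaylorFit(
        V=float(V_arr.mean()),
        beta=float(b_arr.mean()),
        err_V=float(V_arr.std(ddof=0)),
        err_beta=float(b_arr.std(ddof=0)),
        r2=float(np.mean(r2_r)),
        param_corr=corr,
        n_replicates=len(V_r),
        converged=converged or len(V_r) >= n_replicates,
        fit_mode=mode,
    )


def fit_taylor_inversion(stats: Sequence[TaxonStats], mode: str = "loglog") -> TaylorFit:
    """Deterministic x-weighted baseline: invert, weight-fit, revert.

    With error on x only, fit the inverted relation x = (y/V)^{1/β} weighted
    by 1/SEM², then map the parameters back to (V, β).  In ``loglog`` mode
    the weighted fit is linear in log space (log-scale x-errors SEM_i/x̄_i);
    errors come from the weighted-regression covariance via the delta method.
    The approximation degrades as R² drops — use the bootstrap fitter there.
    """
    x, y, sem = _extract(stats, mode)
    sem = np.clip(sem, X_FLOOR, None)
    if mode == "loglog":
        lx, ly = np.log(x), np.log(y)
        w = 1.0 / (sem / x) ** 2  # log-scale x variance by delta method
        # weighted OLS of lx on ly: lx = a + b*ly
        W = w / w.sum()
        mby, mbx = float(W @ ly), float(W @ lx)
        dly, dlx = ly - mby, lx - mbx
        syy = float(W @ (dly * dly))
        sxy = float(W @ (dly * dlx))
        if syy == 0:
            raise FitError("degenerate inversion: all SDs equal")
        b = sxy / syy
        a = mbx - b * mby
        if b == 0:
            raise FitError("zero inverted slope; cannot revert inversion")
        beta = 1.0 / b
        logV = -a / b
        # weighted residual variance and covariance of (a, b)
        resid = lx - (a + b * ly)
        n = x.size
        s2 = float(W @ (resid * resid)) * n / max(n - 2, 1)
        neff = w.sum() ** 2 / np.sum(w**2)
        var_b = s2 / (syy * neff)
        var_a = s2 * (1.0 / neff + mby**2 / (syy * neff))
        cov_ab = -mby * var_b
        # delta method: beta = 1/b, logV = -a/b
        dbeta = np.array([0.0, -1.0 / b**2])
        dlogV = np.array([-1.0 / b, a / b**2])
        C = np.array([[var_a, cov_ab], [cov_ab, var_b]])
        err_beta = float(np.sqrt(dbeta @ C @ dbeta))
        err_logV = float(np.sqrt(dlogV @ C @ dlogV))
        V = float(np.exp(logV))
        err_V = V * err_logV
        cov_vb = float(dlogV @ C @ dbeta) * V
        denom = err_V * err_beta
        corr = cov_vb / denom if denom > 0 else 0.0
        # forward-direction r2 in log space
        pred = logV + beta * lx
        ss_tot = float(np.sum((ly - ly.mean()) ** 2))
        r2 = 1.0 - float(np.sum((ly - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    elif mode == "nonlinear":
        V0, b0, _ = fit_power_law_single(x, y, mode="loglog")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                popt, pcov = optimize.curve_fit(
                    lambda yy, V, b: (yy / V) ** (1.0 / b),
                    y,
                    x,
                    p0=(V0, b0),
                    sigma=sem,
                    absolute_sigma=False,
                    maxfev=10000,
                )
            except (RuntimeError, optimize.OptimizeWarning) as exc:
                raise FitError(f"weighted nonlinear inversion failed: {exc}") from exc
        V, beta = float(popt[0]), float(popt[1])
        err_V = float(np.sqrt(pcov[0, 0]))
        err_beta = float(np.sqrt(pcov[1, 1]))
        denom = err_V * err_beta
        corr = float(pcov[0, 1]) / denom if denom > 0 else 0.0
        pred = V * x**beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TaylorFit(
        V=V,
        beta=float(beta),
        err_V=err_V,
        err_beta=err_beta,
        r2=r2,
        param_corr=float(np.clip(corr, -1.0, 1.0)),
        n_replicates=1,
        converged=True,
        fit_mode=mode,
    )
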
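"""Langevin community dynamics and stationary Fokker-Planck diagnostics.

Taxon relative abundances are modelled by the stochastic differential
equation

    dx_i/dt = F_i x_i^α + V x_i^β ξ_i(t) − φ(t) x_i,

where F_i is the fitness of taxon i (units 1/time, roughly the inverse
relaxation time), V the noise amplitude, ξ_i Gaussian white noise, and φ(t)
the drift that keeps Σ x_i = 1 at all times.  In the stationary regime φ(t)
fluctuates around

    φ₀ = (Σ_i F_i^{1/(1−α)})^{1−α}.

The one-taxon stationary Fokker-Planck density (α < 1, β ≠ 1) is

    P₀(x) ∝ x^{−2β} exp[ (2F/V²)·x^{1+α−2β}/(1+α−2β)
                         − (φ₀/V²)·x^{2−2β}/(1−β) ]      if 2β ≠ 1 + α,
    P₀(x) ∝ x^{2F/V²−2β} exp[ −(φ₀/V²)·x^{2−2β}/(1−β) ]  if 2β = 1 + α,

with the normalization constant obtained by numerical quadrature on a
truncated domain (x_min, 1].  Whether P₀ has an interior local maximum on
(0, 1) defines the ordered (stable) phase; losing it to the boundary marks
the noise-induced (disordered) phase.  Closed-form transition lines are
F² = 4βφ₀V² for β = α ≠ 1 and F = βV² for 2β = 1 + α; with the focal taxon
dominating φ₀ (φ₀ = F) and β = 0.75 the first reduces to F = 3V².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .abundance import AbundanceTable

__all__ = [
    "LangevinParams",
    "SteadyState",
    "PhaseDiagnosis",
    "Trajectory",
    "FitnessEstimate",
    "phi0",
    "simulate",
    "steady_state_pdf",
    "has_interior_mode",
    "classify_phase",
    "find_critical_fitness",
    "infer_fitness",
    "infer_fitness_community",
    "fitness_from_autocorrelation",
]

_BRANCH_TOL = 1e-12
_X_MIN = 1e-8


@dataclass(frozen=True)
class LangevinParams:
    """Parameters of the community Langevin equation."""

    alpha: float
    beta: float
    F: np.ndarray
    V: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "F", np.atleast_1d(np.asarray(self.F, dtype=float)))
        if self.alpha >= 1:
            raise ValueError("alpha must be < 1 (systems with alpha >= 1 are unstable)")
        if self.V < 0:
            raise ValueError("noise amplitude V must be non-negative")
        if np.any(self.F <= 0):
            raise ValueError("all fitness values must be positive")


@dataclass(frozen=True)
class SteadyState:
    """Stationary Fokker-Planck density on a truncated abundance grid."""

    grid: np.ndarray
    density: np.ndarray
    norm_constant: float
    log_norm_constant: float
    x_M: float
    branch: str  # "generic" (2β ≠ 1+α) or "equal" (2β = 1+α)
    mode_is_interior: bool


@dataclass(frozen=True)
class PhaseDiagnosis:
    """Stable/unstable classification with distance to the transition."""

    phase: str  # "ordered" | "disordered"
    F_crit: float
    margin: float
    x_M: float
    method: str  # "closed_form:beta_eq_alpha" | "closed_form:equal_branch" | "bisection"


@dataclass(frozen=True)
class Trajectory:
    """Recorded compositions from a Langevin simulation."""

    times: np.ndarray
    x: np.ndarray  # (n_records, n_taxa)
    params: LangevinParams = field(repr=False, default=None)


@dataclass(frozen=True)
class FitnessEstimate:
    """Fitness inferred from fluctuations under the equilibrium assumption."""

    F: float
    loglik: float
    at_bound: bool


def phi0(F: Sequence[float] | float, alpha: float) -> float:
    """Stationary normalization drift φ₀ = (Σ_i F_i^{1/(1−α)})^{1−α}."""
    if alpha >= 1:
        raise ValueError("alpha must be < 1")
    F = np.atleast_1d(np.asarray(F, dtype=float))
    if np.any(F <= 0):
        raise ValueError("all fitness values must be positive")
    p = 1.0 / (1.0 - alpha)
    return float(np.sum(F**p) ** (1.0 - alpha))


def simulate(
    params: LangevinParams,
    x0: Sequence[float],
    dt: float | None = None,
    n_steps: int = 100_000,
    seed: int | None = None,
    record_every: int = 1,
    x_min: float = _X_MIN,
) -> Trajectory:
    """Euler–Maruyama integration of the normalized Langevin dynamics.

    Per step, with a single noise draw ξ shared between the diffusion term
    and the normalization drift,

        φ·dt = Σ F_i x_i^α dt + Σ V x_i^β ξ_i √dt,
        x_i ← x_i + (F_i x_i^α − φ x_i) dt + V x_i^β ξ_i √dt,

    which conserves Σx exactly before boundary handling; the state is then
    floored at ``x_min`` and renormalized.  Default dt = 10⁻³ / max F_i.
    """
    F, alpha, beta, V = params.F, params.alpha, params.beta, params.V
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != F.shape:
        raise ValueError(f"x0 has {x.size} taxa but params have {F.size}")
    if np.any(x <= 0) or abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("x0 must be positive and sum to 1")
    if dt is None:
        dt = 1e-3 / float(F.max())
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)

    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, x.size))
    rec_t = np.empty(n_rec)
    rec[0], rec_t[0] = x, 0.0
    j = 1
    for step in range(1, n_steps + 1):
        xa = x**alpha
        xb = x**beta
        xi = rng.standard_normal(x.size)
        drift = F * xa
        noise = V * xb * xi
        phi_dt = drift.sum() * dt + noise.sum() * sqdt
        dx = drift * dt + noise * sqdt - phi_dt * x
        if not np.all(np.isfinite(dx)):
            raise FloatingPointError(f"non-finite state update at step {step}")
        if np.any(np.abs(dx) > 0.5):
            raise ValueError(
                f"|dx| > 0.5 at step {step}: dt={dt:g} too large for these "
                "parameters; reduce dt"
            )
        x = np.clip(x + dx, x_min, None)
        x /= x.sum()
        if step % record_every == 0:
            rec[j], rec_t[j] = x, step * dt
            j += 1
    return Trajectory(times=rec_t[:j], x=rec[:j], params=params)


def _log_density_terms(alpha: float, beta: float, F: float, V: float, phi0_val: float):
    """Return (branch, unnormalized log-density, x·dlogP/dx) callables."""
    if V <= 0:
        raise ValueError("V must be positive for a stationary density")
    if abs(beta - 1.0) < _BRANCH_TOL:
        raise ValueError("beta = 1 makes the stationary exponents singular")
    v2 = V * V
    equal = abs(2 * beta - (1 + alpha)) < _BRANCH_TOL
    if equal:
        a0 = 2 * F / v2 - 2 * beta

        def logp(x: np.ndarray) -> np.ndarray:
            return a0 * np.log(x) - (phi0_val / v2) * x ** (2 - 2 * beta) / (1 - beta)

        def rfun(x: np.ndarray) -> np.ndarray:
            return a0 - (2 * phi0_val / v2) * x ** (2 - 2 * beta)

        return "equal", logp, rfun

    e1 = 1 + alpha - 2 * beta

    def logp(x: np.ndarray) -> np.ndarray:
        return (
            -2 * beta * np.log(x)
            + (2 * F / v2) * x**e1 / e1
            - (phi0_val / v2) * x ** (2 - 2 * beta) / (1 - beta)
        )

    def rfun(x: np.ndarray) -> np.ndarray:
        return -2 * beta + (2 * F / v2) * x**e1 - (2 * phi0_val / v2) * x ** (2 - 2 * beta)

    return "generic", logp, rfun


def _interior_maxima(
    rfun: Callable[[np.ndarray], np.ndarray], grid: np.ndarray
) -> list[float]:
    """Roots of x·dlogP/dx with a + → − sign change (interior local maxima)."""
    r = rfun(grid)
    out: list[float] = []
    sign = np.sign(r)
    for i in np.flatnonzero((sign[:-1] > 0) & (sign[1:] < 0)):
        out.append(float(optimize.brentq(rfun, grid[i], grid[i + 1], xtol=1e-14)))
    return out


def steady_state_pdf(
    alpha: float,
    beta: float,
    F: float,
    V: float,
    phi0_val: float,
    grid_size: int = 4000,
    x_min: float = _X_MIN,
) -> SteadyState:
    """Stationary density P₀ of one taxon on a log-spaced grid over (x_min, 1].

    The density is normalized by trapezoidal quadrature on the truncated
    domain (the x^{−2β} factor diverges at 0 when 2β ≥ 1, so x_min acts as
    the same lower cutoff the simulator uses).  ``x_M`` is the interior local
    maximum found by sign change of the closed-form log-density derivative,
    refined by root bracketing; when no interior maximum exists the grid
    argmax (a boundary) is reported and ``mode_is_interior`` is False.  When
    several interior maxima exist the one of highest density is reported.
    """
    if not (0 < x_min < 1):
        raise ValueError("x_min must lie in (0, 1)")
    branch, logp_fn, rfun = _log_density_terms(alpha, beta, F, V, phi0_val)
    grid = np.geomspace(x_min, 1.0, grid_size)
    lp = logp_fn(grid)
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError("non-finite log-density on the grid")
    m = lp.max()
    unnorm = np.exp(lp - m)
    Z = float(np.trapezoid(unnorm, grid))
    if not np.isfinite(Z) or Z <= 0:
        raise FloatingPointError("density not integrable on the truncated domain")
    log_C = -(m + np.log(Z))
    density = unnorm / Z

    maxima = _interior_maxima(rfun, grid)
    if maxima:
        best = max(maxima, key=lambda xm: float(logp_fn(np.array([xm]))[0]))
        return SteadyState(
            grid=grid,
            density=density,
            norm_constant=float(np.exp(log_C)),
            log_norm_constant=log_C,
            x_M=best,
            branch=branch,
            mode_is_interior=True,
        )
    return SteadyState(
        grid=grid,
        density=density,
        norm_constant=float(np.exp(log_C)),
        log_norm_constant=log_C,
        x_M=float(grid[int(np.argmax(density))]),
        branch=branch,
        mode_is_interior=False,
    )


def has_interior_mode(
    alpha: float,
    beta: float,
    F: float,
    V: float,
    phi0_val: float,
    grid_size: int = 4000,
    x_min: float = _X_MIN,
) -> bool:
    """Whether P₀ has a local maximum strictly inside (x_min, 1)."""
    _, _, rfun = _log_density_terms(alpha, beta, F, V, phi0_val)
    grid = np.geomspace(x_min, 1.0, grid_size)
    return len(_interior_maxima(rfun, grid)) > 0


def find_critical_fitness(
    alpha: float,
    beta: float,
    V: float,
    phi0_val: float | None = None,
    f_bracket: tuple[float, float] = (1e-6, 1e3),
    rtol: float = 1e-6,
    grid_size: int = 4000,
) -> float:
    """Critical fitness at fixed V, by bisection on the interior-mode predicate.

    ``phi0_val=None`` uses the dominant-taxon self-consistency φ₀ = F (φ₀
    tracks F during the bisection); a number fixes φ₀ independently of F.

    With a fixed φ₀ the ordered region can be bounded above as well: at very
    large F the interior maximum migrates to the x = 1 boundary and leaves
    the domain.  The bisection therefore brackets the onset (lowest ordered
    F), scanning the bracket for an ordered point when the upper end is not.
    """

    def ordered(F: float) -> bool:
        return has_interior_mode(
            alpha, beta, F, V, F if phi0_val is None else phi0_val, grid_size=grid_size
        )

    lo, hi = f_bracket
    if ordered(lo):
        raise ValueError(f"lower bracket F={lo} is already ordered")
    if not ordered(hi):
        for F in np.geomspace(lo, hi, 256):
            if ordered(F):
                hi = float(F)
                break
        else:
            raise ValueError(
                f"no ordered fitness found in bracket ({lo}, {hi})"
            )
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if ordered(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def classify_phase(
    alpha: float,
    beta: float,
    F: float,
    V: float,
    phi0_val: float | None = None,
    grid_size: int = 4000,
) -> PhaseDiagnosis:
    """Ordered/disordered diagnosis with the critical fitness at this V.

    The phase is read off the stationary density (ordered iff an interior
    local maximum exists).  F_crit uses the closed forms where they apply —
    F² = 4βφ₀V² for β = α ≠ 1 (⇒ F_crit = 4βV² under φ₀ = F) and F = βV²
    for 2β = 1 + α — and bisection on the interior-mode predicate otherwise.
    ``phi0_val=None`` applies the dominant-taxon approximation φ₀ = F.
    """
    self_consistent = phi0_val is None
    p0 = F if self_consistent else phi0_val
    ss = steady_state_pdf(alpha, beta, F, V, p0, grid_size=grid_size)
    if abs(beta - alpha) < 1e-9 and abs(beta - 1.0) > 1e-9:
        if self_consistent:
            F_crit = 4 * beta * V * V  # F² = 4βFV²  ⇒  F = 4βV²
        else:
            F_crit = float(np.sqrt(4 * beta * p0 * V * V))
        method = "closed_form:beta_eq_alpha"
    elif abs(2 * beta - (1 + alpha)) < 1e-9:
        F_crit = beta * V * V
        method = "closed_form:equal_branch"
    else:
        F_crit = find_critical_fitness(
            alpha, beta, V, None if self_consistent else p0, grid_size=grid_size
        )
        method = "bisection"
    return PhaseDiagnosis(
        phase="ordered" if ss.mode_is_interior else "disordered",
        F_crit=float(F_crit),
        margin=float(F - F_crit),
        x_M=ss.x_M,
        method=method,
    )


def _stationary_loglik(
    x: np.ndarray,
    F: float,
    alpha: float,
    beta: float,
    V: float,
    phi0_val: float,
    grid_size: int,
    x_min: float,
) -> float:
    _, logp_fn, _ = _log_density_terms(alpha, beta, F, V, phi0_val)
    grid = np.geomspace(x_min, 1.0, grid_size)
    lp = logp_fn(grid)
    m = lp.max()
    logZ = m + np.log(np.trapezoid(np.exp(lp - m), grid))
    return float(np.sum(logp_fn(x)) - x.size * logZ)


def infer_fitness(
    series: Sequence[float],
    V: float,
    alpha: float = 0.75,
    beta: float = 0.75,
    phi0_val: float | None = None,
    f_bounds: tuple[float, float] = (1e-3, 100.0),
    grid_size: int = 2000,
    x_min: float = _X_MIN,
) -> FitnessEstimate:
    """Infer a taxon's fitness from its abundance fluctuations.

    Concrete reading of the fluctuation-dissipation prescription: assuming
    the microbiota is in equilibrium (ordered phase), the observations are
    treated as independent draws from the stationary density and F maximizes
    the stationary log-likelihood Σ_t log P₀(x_t; F, V, α, β, φ₀).
    ``phi0_val=None`` uses the dominant-taxon approximation φ₀ = F; for a
    community-wide self-consistent φ₀ see :func:`infer_fitness_community`.

    A maximum pinned at either search bound (e.g. for a constant series,
    which pushes F upward without limit) is flagged via ``at_bound``.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 5:
        raise ValueError("series must have at least 5 observations")
    if V <= 0:
        raise ValueError("V must be positive")
    x = np.clip(x, x_min, 1.0)

    def nll(F: float) -> float:
        return -_stationary_loglik(
            x, F, alpha, beta, V, F if phi0_val is None else phi0_val, grid_size, x_min
        )

    res = optimize.minimize_scalar(
        nll, bounds=f_bounds, method="bounded", options={"xatol": 1e-8}
    )
    if not res.success:
        raise RuntimeError(
            f"fitness optimization failed on bracket {f_bounds}: {res.message}"
        )
    F_hat = float(res.x)
    # the search spans decades, so judge proximity to a bound on the log
    # scale: within 1% multiplicative distance of either end counts as pinned
    at_bound = F_hat < 1.01 * f_bounds[0] or F_hat > 0.99 * f_bounds[1]
    return FitnessEstimate(F=F_hat, loglik=-float(res.fun), at_bound=at_bound)


def infer_fitness_community(
    table: AbundanceTable,
    V: float,
    alpha: float = 0.75,
    beta: float = 0.75,
    n_iter: int = 5,
    f_bounds: tuple[float, float] = (1e-3, 100.0),
    grid_size: int = 2000,
) -> tuple[np.ndarray, float]:
    """Per-taxon fitness with φ₀ updated self-consistently across taxa.

    Starting from φ₀ computed with unit fitness for all taxa, alternate
    per-taxon likelihood maximization (at fixed φ₀) with recomputation of
    φ₀ from the inferred fitness vector.  Returns (F vector, final φ₀).
    """
    if not table.is_relative:
        raise ValueError("table must be on the relative scale")
    F = np.ones(table.n_taxa)
    p0 = phi0(F, alpha)
    for _ in range(n_iter):
        F = np.array(
            [
                infer_fitness(
                    table.counts[i],
                    V,
                    alpha,
                    beta,
                    phi0_val=p0,
                    f_bounds=f_bounds,
                    grid_size=grid_size,
                ).F
                for i in range(table.n_taxa)
            ]
        )
        p0 = phi0(F, alpha)
    return F, p0


def fitness_from_autocorrelation(
    series: Sequence[float], times: Sequence[float]
) -> float:
    """Alternative fitness estimator F ≈ 1/τ from the autocorrelation time.

    Fits an exponential decay to the empirical autocorrelation of the series
    (the relaxation rate toward the stable state roughly corresponds to the
    inverse half-life).  Provided as a cross-check; the likelihood estimator
    :func:`infer_fitness` is the default.
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.size != t.size or x.size < 5:
        raise ValueError("series and times must align with length >= 5")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * dt.mean():
        raise ValueError("autocorrelation estimator requires uniform sampling")
    xc = x - x.mean()
    var = float(xc @ xc)
    if var == 0:
        raise ValueError("constant series has no autocorrelation time")
    max_lag = min(x.size // 3, 50)
    acf = np.array([float(xc[: x.size - k] @ xc[k:]) / var for k in range(1, max_lag + 1)])
    pos = acf > 0.05
    n_use = int(np.argmin(pos)) if not pos.all() else max_lag
    if n_use < 2:
        raise ValueError("autocorrelation decays below noise within one lag")
    lags = np.arange(1, n_use + 1) * float(dt.mean())
    rate = -np.polyfit(lags, np.log(acf[:n_use]), 1)[0]
    if rate <= 0:
        raise ValueError("non-decaying autocorrelation; cannot estimate fitness")
    return float(rate)
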
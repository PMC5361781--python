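# Methods

This note records the models implemented in `microstab`, the estimator
choices, the numerical parameters and their rationale, and the known
limitations. Symbols: xᵢ(t) is taxon i's relative abundance at time t
(Σᵢxᵢ = 1), x̄ᵢ and σᵢ its temporal mean and standard deviation (n−1
denominator), and SEMᵢ = σᵢ/√nᵢ.

## Abundance tables and per-taxon statistics

The unit of analysis is one (subject, interval) series: a taxa × timepoint
matrix with strictly increasing sampling days and one condition label per
timepoint. Counts are converted to relative abundances per timepoint; a
series needs at least 3 timepoints. Zeros count as observations of 0 by
default; taxa nonzero at fewer than `min_nonzero = 2` timepoints are
dropped, since their dispersion reflects presence/absence rather than
fluctuation. TSV (taxa × samples plus a sidecar metadata table) and BIOM v1
JSON inputs are supported.

## Taylor's law fit

Fluctuation scaling is modelled as σᵢ = V·x̄ᵢ^β. The primary estimator,
`fit_taylor_xweighted`, propagates the uncertainty of the mean axis by a
parametric bootstrap:

1. draw replicate abscissae x*ᵢ = x̄ᵢ + N(0, SEMᵢ); values ≤ 0 are clamped
   to 10⁻¹² (a `redraw` policy is available),
2. fit log σ on log x* by unweighted least squares (or σ = V·x^β directly
   by nonlinear least squares in `nonlinear` mode),
3. report the ensemble mean and SD of (V, β) over replicates, plus their
   Pearson correlation `param_corr`.

Replication stops early when the running means of V and β change by less
than 10⁻³ (relative), checked every 50 replicates after a minimum of 200;
the cap is 1000. Input order cannot matter: taxa are sorted internally into
a canonical order before any random draw, making seeded fits bit-identical
under permutation of the input.

`fit_taylor_inversion` is a deterministic alternative: regress log x on
log σ with weights (x̄/SEM)² (the noisy variable becomes the response),
invert the line algebraically, and propagate errors by the delta method.
On exact power-law data both estimators agree with the direct fit.

**Error scope.** The bootstrap resamples only the mean axis, so the
reported errors quantify SEM propagation. The finite-sample scatter of the
SD estimates themselves (≈ 1/√(2(n−1)) in log σ per taxon) is *not*
included; at small n it dominates, so reported errors understate the total
sampling error of short series. Parameter-recovery tests therefore assert
accuracy at n = 100, where this term is small, and the sliding-window
tests assert relative accuracy rather than error coverage.

## Healthy-zone standardization

Within one study, healthy subjects' parameter values vₖ with errors εₖ get
inverse-variance weights ωₖ ∝ 1/εₖ² (normalized). The reference is the
weighted mean v̂ = Σωₖvₖ and the unbiased weighted SD
σ̂ = √[Σωₖ(vₖ−v̂)²/(1−Σωₖ²)]. Each subject maps to z = (v−v̂)/σ̂ with error
ε/σ̂. By construction the healthy z-cloud has weighted mean 0 and weighted
SD 1 exactly, so the Euclidean zone radii 1.0 (≈68%) and 2.8 (≈98%) in the
(z_V, z_β) plane are study-independent. At least two healthy subjects are
required; a degenerate group (identical values) is rejected with a warning
path for the all-equal case.

## Langevin community model

Dynamics: ẋᵢ = Fᵢxᵢ^α + Vxᵢ^β ξᵢ(t) − φ(t)xᵢ, with independent unit white
noises ξᵢ and a common drift φ(t) enforcing ΣΔxᵢ = 0 at every step. The
Euler–Maruyama update uses φ·dt = Σⱼ(Fⱼxⱼ^α dt + Vxⱼ^β ξⱼ√dt) evaluated
with the same noise draws, which conserves Σxᵢ = 1 to machine precision by
construction. Abundances are floored at x_min = 10⁻⁸ and renormalized.
Default dt = 10⁻³/max(F); a step with |Δx| > 0.5 aborts with a suggestion
to reduce dt. The stationary normalization drift is
φ₀ = (ΣᵢFᵢ^{1/(1−α)})^{1−α}, and the deterministic fixed point is
x*ᵢ = (Fᵢ/φ₀)^{1/(1−α)} (sums to 1 exactly).

## Stationary Fokker–Planck density and phase

For a single coordinate with fixed φ₀ the stationary (zero-current)
density is, up to normalization,

- generic branch (2β ≠ 1 + α):
  P₀(x) ∝ x^(−2β) exp[(2F/V²)·x^(1+α−2β)/(1+α−2β) − (2φ₀/V²)·x^(2−2β)/(2−2β)]
- equal branch (2β = 1 + α):
  P₀(x) ∝ x^(2F/V²−2β) exp[−(2φ₀/V²)·x^(2−2β)/(2−2β)]

(the minus sign in the equal branch follows from the stationary solution;
the two branches agree in the limit 2β → 1+α, which is verified by test).
β = 1 is rejected (the 2−2β exponent degenerates). The density is
evaluated on a geometric grid of 4000 points on [10⁻⁸, 1] with max-log
subtraction before exponentiation, and normalized by trapezoidal
quadrature.

Interior maxima are located from sign changes (+→−) of
r(x) = x·d log P₀/dx = −2β + (2F/V²)x^(1+α−2β) − (2φ₀/V²)x^(2−2β),
refined by `brentq`. The community is **ordered** iff P₀ has an interior
local maximum. The critical fitness has closed forms: F² = 4βφ₀V² for
β = α ≠ 1 (hence F_crit = 4βV² under the self-consistent dominant-taxon
choice φ₀ = F, i.e. F_crit/V² = 3.00 at β = 0.75) and F = βV² for
2β = 1 + α; otherwise F_crit is found by bisection on the interior-mode
predicate. With a *fixed* φ₀ the ordered region is also bounded above (at
large F the maximum migrates past x = 1), so the bisection brackets the
onset — the lowest ordered F, which is what the closed forms describe.

## Fitness inference

`infer_fitness` reads the fluctuation–dissipation idea operationally:
assuming the series is stationary in the ordered phase, observations are
treated as independent draws from P₀(x; F) and F maximizes the stationary
log-likelihood (bounded scalar optimization on F ∈ [10⁻³, 10²]). An
estimate within 1% (multiplicatively) of either bound is flagged
`at_bound` — e.g. a series saturated near x = 1 favors unbounded F.
`infer_fitness_community` alternates per-taxon maximization with
self-consistent recomputation of φ₀ from the inferred fitness vector.
`fitness_from_autocorrelation` offers the relaxation-time alternative
F ≈ 1/τ. Because successive samples are in fact autocorrelated, the
independence assumption overstates the information content; point
estimates are usable (validated to ±25% on simulated series) but no
likelihood-based error is reported.

## Rank dynamics

Taxa are ordered by accumulated abundance (ties by identifier); the top-N
(default 50) get per-timepoint ranks 1..N, ties broken by the overall
order. For a taxon's rank series, D = Σ|rank(t+1) − rank(t)| and
RSI = (1 − D/((N−1)(t−1)))^p with p = 4; RSI = 1 for a constant series and
0 for one alternating between ranks 1 and N. RV(t) is the mean absolute
deviation of ranks at t from the overall ranking; DV(t) the same relative
to the previous timepoint (undefined at the first). Stability islands are
taxa with overall rank in the band (11, 40), RSI ≥ 0.70, exceeding the
minimum RSI among better-ranked taxa — rank-stable taxa embedded below the
dominant flora.

## Sliding windows

All t−w+1 contiguous windows of w = 5 timepoints are fitted independently
(200 bootstrap replicates each, per-window seeds drawn from one root
seed); windows whose fit fails yield NaN. Window centers are the mean
sampling day. Five-point windows carry ≈35% log-σ sampling noise per
taxon, so windowed series localize changes in V (validated on injected
spikes) but individual window errors understate the total uncertainty
(see *Error scope*).

## Synthetic generators

- `gen_poisson_community` / `gen_exponential_community`: independent draws
  per timepoint at fixed per-taxon means — the two universal fluctuation
  classes (β = 1/2 and β = 1).
- `gen_exact_taylor`: truncated-normal series with exact target moments
  σᵢ = V·mᵢ^β. Designs with SD ≥ mean/2 are rejected as infeasible (the
  truncation would distort the moments).
- `gen_langevin_cohort`: full cohorts — per subject, a continuous Langevin
  trajectory (burn-in 15–20 time units by default, interval-specific V for
  perturbations, per-subject seeds via `SeedSequence`), sampled at the
  cohort spacing and observed as multinomial counts at depth 50,000,
  matching typical 16S sequencing depth. Defaults α = β = 0.75, 50 taxa,
  fitness geometrically spaced on [0.5, 3], baseline V = 0.2.

All generators are bit-reproducible under a fixed seed.

## Limitations

- Reported Taylor-fit errors cover mean-axis (SEM) propagation only; total
  error at small n is dominated by the log-σ sampling term (see *Error
  scope*). Fits on < 20 timepoints should be treated as qualitative.
- Zone classification compares z centers to the radii; it ignores the
  subject's own z errors, which for short series can exceed the zone
  radius. Two such series in the bundled demo z-score outside the 98% zone
  with z errors of ±10 or more — flagging, not diagnosis.
- The stationary-likelihood fitness estimator assumes independent draws
  from P₀ and equilibrium (ordered phase); it provides no valid confidence
  interval and degrades for strongly autocorrelated, short, or saturated
  series (the latter flagged `at_bound`).
- The Fokker–Planck analysis treats one coordinate with fixed φ₀; the full
  interacting system is explored only by simulation.
- The equal-branch density's sign follows from the stationary solution;
  its limit-consistency with the generic branch is the governing check.
- BIOM support covers the v1 (JSON) format only.
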
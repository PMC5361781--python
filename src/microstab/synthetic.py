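"""Synthetic taxa time series and cohorts with the structure the analysis assumes.

Four generators cover the testable regimes:

* :func:`gen_poisson_community` — independent Poisson counts per taxon; the
  mean–SD law is σ = x̄^{1/2}, i.e. the Taylor exponent β = 1/2 class.
* :func:`gen_exponential_community` — exponential abundances (SD = mean),
  the β = 1 class.
* :func:`gen_exact_taylor` — abundances drawn so that σ_i = V·x̄_i^β holds
  exactly in expectation, for fit validation at chosen (V, β).
* :func:`gen_langevin_cohort` — multi-subject cohorts simulated from the
  community Langevin dynamics, with interval-specific noise amplitudes
  (healthy baseline vs perturbations such as antibiotic courses) and counts
  produced by multinomial sampling at a sequencing-like depth.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats as sps

from .abundance import AbundanceTable
from .langevin import LangevinParams, simulate

__all__ = [
    "IntervalSpec",
    "SubjectSpec",
    "CohortSpec",
    "gen_poisson_community",
    "gen_exponential_community",
    "gen_exact_taylor",
    "gen_langevin_cohort",
    "cohort_from_yaml",
    "default_fitness",
]


def _table_from_counts(
    counts: np.ndarray,
    subject_id: str,
    label: str,
    times: np.ndarray | None = None,
    is_relative: bool = False,
) -> AbundanceTable:
    n_taxa, n_t = counts.shape
    width = len(str(n_taxa - 1))
    return AbundanceTable(
        subject_id=subject_id,
        taxon_ids=[f"taxon{str(i).zfill(width)}" for i in range(n_taxa)],
        times=np.arange(n_t, dtype=float) if times is None else times,
        counts=counts,
        interval_labels=[label] * n_t,
        is_relative=is_relative,
    )


def gen_poisson_community(
    means: Sequence[float],
    n_timepoints: int = 100,
    seed: int | None = None,
    subject_id: str = "poisson_sim",
    label: str = "healthy",
) -> AbundanceTable:
    """Independent Poisson counts per taxon and timepoint (β = 1/2 class).

    ``means`` should span several orders of magnitude (e.g. log-spaced
    10¹–10⁵) to give the fit leverage.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("all means must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(means[:, None], size=(means.size, n_timepoints)).astype(float)
    return _table_from_counts(counts, subject_id, label)


def gen_exponential_community(
    means: Sequence[float],
    n_timepoints: int = 100,
    seed: int | None = None,
    subject_id: str = "exponential_sim",
    label: str = "healthy",
) -> AbundanceTable:
    """Independent exponential abundances per taxon (SD = mean, β = 1 class)."""
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("all means must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.exponential(means[:, None], size=(means.size, n_timepoints))
    return _table_from_counts(counts, subject_id, label)


def gen_exact_taylor(
    V: float,
    beta: float,
    means: Sequence[float],
    n_timepoints: int = 50,
    seed: int | None = None,
    renormalize: bool = False,
    subject_id: str = "taylor_sim",
    label: str = "healthy",
) -> AbundanceTable:
    """Abundances following σ_i = V·x̄_i^β exactly (positive-truncated normal).

    Each taxon i is drawn from Normal(mean_i, V·mean_i^β) truncated at zero;
    the truncation is negligible because the SD is required to stay below
    half the mean.  Per-timepoint renormalization to Σx = 1 perturbs the
    target law and is off by default.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means <= 0):
        raise ValueError("all means must be positive")
    sds = V * means**beta
    infeasible = sds >= means / 2
    if np.any(infeasible):
        i = int(np.argmax(infeasible))
        raise ValueError(
            f"infeasible target: SD {sds[i]:.4g} >= mean/2 for mean {means[i]:.4g}; "
            "increase the means or reduce V"
        )
    rng = np.random.default_rng(seed)
    a = (0.0 - means) / sds  # lower truncation bound in SD units (<= -2 by contract)
    draws = sps.truncnorm.rvs(
        a[:, None], np.inf, loc=means[:, None], scale=sds[:, None],
        size=(means.size, n_timepoints), random_state=rng,
    )
    if renormalize:
        draws = draws / draws.sum(axis=0)
    return _table_from_counts(draws, subject_id, label, is_relative=renormalize)


@dataclass(frozen=True)
class IntervalSpec:
    """One labelled stretch of a subject's series, with its noise level."""

    label: str
    n_timepoints: int
    V: float | None = None  # None -> the cohort's baseline V

    def __post_init__(self) -> None:
        if self.n_timepoints < 1:
            raise ValueError("each interval needs at least one timepoint")


@dataclass(frozen=True)
class SubjectSpec:
    """One subject: interval schedule, health label and private seed."""

    subject_id: str
    intervals: tuple[IntervalSpec, ...]
    healthy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if sum(iv.n_timepoints for iv in self.intervals) < 3:
            raise ValueError("a subject needs at least 3 timepoints overall")


def default_fitness(n_taxa: int, low: float = 0.5, high: float = 3.0) -> np.ndarray:
    """Log-spaced fitness vector giving a realistic abundance hierarchy."""
    return np.geomspace(low, high, n_taxa)


@dataclass(frozen=True)
class CohortSpec:
    """A multi-subject study design driven by the Langevin generator.

    The default template mirrors a small longitudinal study: ~50 taxa over
    a few tens of near-daily samples, a healthy baseline noise amplitude,
    and optional perturbed intervals with elevated V.
    """

    study_id: str
    subjects: tuple[SubjectSpec, ...]
    alpha: float = 0.75
    beta: float = 0.75
    n_taxa: int = 50
    F: np.ndarray | None = None
    baseline_V: float = 0.2
    depth: int = 50_000
    sample_spacing: float = 1.0  # days between consecutive samples
    burn_in: float = 20.0  # relaxation time before the first sample
    dt: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        F = default_fitness(self.n_taxa) if self.F is None else np.asarray(self.F, float)
        if F.size != self.n_taxa:
            raise ValueError("fitness vector length must equal n_taxa")
        object.__setattr__(self, "F", F)
        if not self.subjects:
            raise ValueError("cohort needs at least one subject")
        if self.depth < 1:
            raise ValueError("sequencing depth must be positive")


def _fixed_point(F: np.ndarray, alpha: float) -> np.ndarray:
    """Deterministic composition x*_i ∝ F_i^{1/(1−α)} (sums to 1 exactly)."""
    p = F ** (1.0 / (1.0 - alpha))
    return p / p.sum()


def gen_langevin_cohort(spec: CohortSpec) -> list[AbundanceTable]:
    """Simulate every subject of a cohort and return count tables with labels.

    Each subject runs one continuous Langevin trajectory: a burn-in at the
    first interval's noise level, then the interval schedule with its
    per-interval V.  The composition is sampled every ``sample_spacing``
    time units and converted to counts by a multinomial draw at ``depth``
    reads (pure sampling noise; expectations are preserved).
    """
    tables: list[AbundanceTable] = []
    dt = spec.dt if spec.dt is not None else 1e-3 / float(spec.F.max())
    steps_per_sample = max(int(round(spec.sample_spacing / dt)), 1)
    dt = spec.sample_spacing / steps_per_sample

    for subj in spec.subjects:
        ss = np.random.SeedSequence(subj.seed)
        seeds = ss.generate_state(len(subj.intervals) + 2)
        x = _fixed_point(spec.F, spec.alpha)

        v0 = subj.intervals[0].V if subj.intervals[0].V is not None else spec.baseline_V
        burn_steps = max(int(round(spec.burn_in / dt)), 1)
        params = LangevinParams(alpha=spec.alpha, beta=spec.beta, F=spec.F, V=v0)
        traj = simulate(params, x, dt=dt, n_steps=burn_steps,
                        seed=int(seeds[0] % (2**31)), record_every=burn_steps)
        x = traj.x[-1]

        samples: list[np.ndarray] = []
        labels: list[str] = []
        for k, iv in enumerate(subj.intervals):
            V = iv.V if iv.V is not None else spec.baseline_V
            params = LangevinParams(alpha=spec.alpha, beta=spec.beta, F=spec.F, V=V)
            traj = simulate(
                params, x, dt=dt, n_steps=iv.n_timepoints * steps_per_sample,
                seed=int(seeds[k + 1] % (2**31)), record_every=steps_per_sample,
            )
            samples.extend(traj.x[1:])  # one composition per sample time
            labels.extend([iv.label] * iv.n_timepoints)
            x = traj.x[-1]

        comp = np.stack(samples, axis=1)  # taxa x time
        rng = np.random.default_rng(int(seeds[-1] % (2**31)))
        counts = np.empty_like(comp)
        for j in range(comp.shape[1]):
            pvec = comp[:, j] / comp[:, j].sum()
            counts[:, j] = rng.multinomial(spec.depth, pvec)
        n_t = comp.shape[1]
        width = len(str(spec.n_taxa - 1))
        tables.append(
            AbundanceTable(
                subject_id=subj.subject_id,
                taxon_ids=[f"taxon{str(i).zfill(width)}" for i in range(spec.n_taxa)],
                times=np.arange(n_t, dtype=float) * spec.sample_spacing,
                counts=counts,
                interval_labels=labels,
                is_relative=False,
            )
        )
    return tables


def cohort_from_yaml(path: str | Path) -> CohortSpec:
    """Load a :class:`CohortSpec` from a YAML file.

    Schema::

        study_id: studyA
        alpha: 0.75
        beta: 0.75
        n_taxa: 50
        baseline_V: 0.2
        depth: 50000
        sample_spacing: 1.0
        burn_in: 20.0
        subjects:
          - subject_id: H1
            healthy: true
            seed: 11
            intervals:
              - {label: healthy, n_timepoints: 30}
          - subject_id: P1
            healthy: false
            seed: 14
            intervals:
              - {label: antibiotic, n_timepoints: 30, V: 0.5}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    subjects = tuple(
        SubjectSpec(
            subject_id=str(s["subject_id"]),
            intervals=tuple(
                IntervalSpec(
                    label=str(iv["label"]),
                    n_timepoints=int(iv["n_timepoints"]),
                    V=float(iv["V"]) if "V" in iv and iv["V"] is not None else None,
                )
                for iv in s["intervals"]
            ),
            healthy=bool(s.get("healthy", True)),
            seed=int(s.get("seed", 0)),
        )
        for s in doc["subjects"]
    )
    kwargs = {
        k: doc[k]
        for k in ("alpha", "beta", "n_taxa", "baseline_V", "depth",
                  "sample_spacing", "burn_in", "dt")
        if k in doc
    }
    return CohortSpec(study_id=str(doc["study_id"]), subjects=subjects, **kwargs)
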
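"""Study-wise standardization of Taylor parameters against healthy subjects.

Each study carries its own systematics (primers, sequencing depth, taxonomic
pipeline), so subjects are never pooled across studies on the raw (V, β)
scale.  Instead, within each study the healthy subjects define a reference —
an inverse-variance weighted mean and a weighted standard deviation per
parameter — and every subject is mapped to standardized coordinates
z = (value − mean)/SD.  By construction the healthy group then has weighted
mean 0 and weighted SD 1, and the unit circle around the origin is the
"healthy zone" (the 68% confidence region on each axis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SubjectPoint",
    "HealthyReference",
    "StandardizedPoint",
    "weighted_mean",
    "weighted_sd",
    "normalized_weights",
    "standardize_study",
    "destandardize",
    "zone_membership",
]


@dataclass(frozen=True)
class SubjectPoint:
    """One subject's fitted Taylor parameters within a study."""

    subject_id: str
    study_id: str
    V: float
    err_V: float
    beta: float
    err_beta: float
    healthy: bool

    def __post_init__(self) -> None:
        if self.err_V <= 0 or self.err_beta <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: parameter errors must be positive "
                "(they define the standardization weights)"
            )


@dataclass(frozen=True)
class HealthyReference:
    """Weighted mean/SD of the healthy subgroup of one study."""

    study_id: str
    V_hat: float
    beta_hat: float
    sigma_V: float
    sigma_beta: float
    h: int


@dataclass(frozen=True)
class StandardizedPoint:
    """A subject in standardized (z_V, z_beta) coordinates (SD units)."""

    subject_id: str
    z_V: float
    z_V_err: float
    z_beta: float
    z_beta_err: float
    healthy: bool = True


def normalized_weights(errors: Sequence[float]) -> np.ndarray:
    """Inverse-variance weights ω_i ∝ 1/σ_i², normalized so Σω = 1."""
    err = np.asarray(errors, dtype=float)
    if err.size == 0:
        raise ValueError("at least one value required")
    if np.any(err <= 0):
        raise ValueError("all errors must be positive")
    w = 1.0 / err**2
    return w / w.sum()


def weighted_mean(values: Sequence[float], errors: Sequence[float]) -> float:
    """Inverse-variance weighted mean V̂ = Σ ω_i V_i (Σω = 1)."""
    vals = np.asarray(values, dtype=float)
    w = normalized_weights(errors)
    if vals.shape != w.shape:
        raise ValueError("values and errors must have equal length")
    return float(w @ vals)


def weighted_sd(values: Sequence[float], errors: Sequence[float]) -> float:
    """Weighted population SD, σ̂ = √[ Σ ω_i (V_i − V̂)² / (1 − Σω_i²) ].

    The 1 − W₂ denominator (W₂ = Σω_i²) is the weighted analogue of the n−1
    correction; it vanishes for a single subject, hence h ≥ 2 is required.
    Identical values give 0 with a warning (a degenerate reference).
    """
    vals = np.asarray(values, dtype=float)
    w = normalized_weights(errors)
    if vals.shape != w.shape:
        raise ValueError("values and errors must have equal length")
    if vals.size < 2:
        raise ValueError("weighted SD needs at least two subjects (1 − W2 = 0 for one)")
    W2 = float(np.sum(w**2))
    if np.isclose(W2, 1.0):
        raise ValueError("weights degenerate to a single subject (1 − W2 = 0)")
    if np.ptp(vals) == 0:
        warnings.warn("all values identical; weighted SD is 0", stacklevel=2)
        return 0.0
    vhat = float(w @ vals)
    return float(np.sqrt(np.sum(w * (vals - vhat) ** 2) / (1.0 - W2)))


def standardize_study(
    points: Sequence[SubjectPoint],
) -> tuple[HealthyReference, list[StandardizedPoint]]:
    """Standardize every subject of one study against its healthy subgroup.

    The reference is built from healthy subjects only; each subject (healthy
    or not) is mapped to z = (value − mean)/SD per parameter, with its error
    bar divided by the same SD.  Healthy subjects' standardized values then
    have weighted mean 0 and weighted SD 1 to machine precision.
    """
    if not points:
        raise ValueError("no subjects given")
    studies = {p.study_id for p in points}
    if len(studies) > 1:
        raise ValueError(
            f"subjects from multiple studies {sorted(studies)}; standardize each "
            "study in isolation"
        )
    healthy = [p for p in points if p.healthy]
    if len(healthy) < 2:
        raise ValueError(
            f"study {points[0].study_id!r} has {len(healthy)} healthy subjects; "
            "at least 2 required for a reference"
        )
    V_hat = weighted_mean([p.V for p in healthy], [p.err_V for p in healthy])
    sigma_V = weighted_sd([p.V for p in healthy], [p.err_V for p in healthy])
    beta_hat = weighted_mean([p.beta for p in healthy], [p.err_beta for p in healthy])
    sigma_beta = weighted_sd([p.beta for p in healthy], [p.err_beta for p in healthy])
    if sigma_V == 0 or sigma_beta == 0:
        raise ValueError("degenerate healthy reference (zero weighted SD)")
    ref = HealthyReference(
        study_id=points[0].study_id,
        V_hat=V_hat,
        beta_hat=beta_hat,
        sigma_V=sigma_V,
        sigma_beta=sigma_beta,
        h=len(healthy),
    )
    zpoints = [
        StandardizedPoint(
            subject_id=p.subject_id,
            z_V=(p.V - V_hat) / sigma_V,
            z_V_err=p.err_V / sigma_V,
            z_beta=(p.beta - beta_hat) / sigma_beta,
            z_beta_err=p.err_beta / sigma_beta,
            healthy=p.healthy,
        )
        for p in points
    ]
    return ref, zpoints


def destandardize(ref: HealthyReference, zpoint: StandardizedPoint) -> SubjectPoint:
    """Map a standardized point back to raw (V, β) using the stored reference."""
    return SubjectPoint(
        subject_id=zpoint.subject_id,
        study_id=ref.study_id,
        V=ref.V_hat + zpoint.z_V * ref.sigma_V,
        err_V=zpoint.z_V_err * ref.sigma_V,
        beta=ref.beta_hat + zpoint.z_beta * ref.sigma_beta,
        err_beta=zpoint.z_beta_err * ref.sigma_beta,
        healthy=zpoint.healthy,
    )


def zone_membership(
    point: StandardizedPoint, radius_68: float = 1.0, radius_98: float = 2.8
) -> str:
    """Classify a standardized point against the healthy-zone circles.

    Returns "inside_68", "inside_98" or "outside" by the Euclidean radius
    √(z_V² + z_β²).  Default radii: 1.0 for the 68% circle (unit-SD circle)
    and 2.8 for the 98% circle (2-D Gaussian quantile); both configurable.
    """
    if not (0 < radius_68 < radius_98):
        raise ValueError("radii must satisfy 0 < radius_68 < radius_98")
    r = float(np.hypot(point.z_V, point.z_beta))
    if r <= radius_68:
        return "inside_68"
    if r <= radius_98:
        return "inside_98"
    return "outside"
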
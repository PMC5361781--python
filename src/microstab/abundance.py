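"""Longitudinal taxa abundance tables and per-taxon temporal statistics.

The central container is :class:`AbundanceTable`: one subject's taxa ×
timepoint matrix with sample times (days since first sample) and per-sample
interval labels ("healthy", "antibiotic", ...).  Downstream analyses work on
relative abundances, the fraction x_i(t) of total counts carried by taxon i
at time t, and on the per-taxon temporal statistics (mean, SD, SEM) that feed
the fluctuation-scaling (Taylor's law) fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "InsufficientSeriesError",
    "AbundanceTable",
    "TaxonStats",
    "read_taxa_table",
    "to_relative",
    "compute_stats",
]

#: Minimum number of timepoints for a usable series (sample-selection rule).
MIN_TIMEPOINTS = 3


class ValidationError(ValueError):
    """An abundance table or its metadata violates a structural contract."""


class InsufficientSeriesError(ValidationError):
    """A subject has fewer timepoints than the minimum series length."""


@dataclass
class AbundanceTable:
    """Taxa × timepoint abundances for one subject.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    taxon_ids : list of str
        Taxon identifiers, optionally semicolon-delimited lineage strings.
    times : array of float
        Sample times in days since the first sample; strictly increasing.
    counts : 2-D array, shape (n_taxa, n_times)
        Non-negative counts, or relative abundances if ``is_relative``.
    interval_labels : list of str
        One condition label per timepoint (e.g. "healthy", "antibiotic").
    is_relative : bool
        If True every timepoint column sums to 1 (within 1e-9).
    """

    subject_id: str
    taxon_ids: list[str]
    times: np.ndarray
    counts: np.ndarray
    interval_labels: list[str] = field(default_factory=list)
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if not self.interval_labels:
            self.interval_labels = ["healthy"] * self.times.size
        self._validate()

    def _validate(self) -> None:
        n_taxa, n_times = len(self.taxon_ids), self.times.size
        if self.counts.shape != (n_taxa, n_times):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{n_taxa} taxa x {n_times} timepoints"
            )
        if len(self.interval_labels) != n_times:
            raise ValidationError("one interval label per timepoint required")
        if n_times and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("non-finite abundance values")
        if np.any(self.counts < 0):
            raise ValidationError("negative abundance values")
        if self.is_relative and n_times:
            sums = self.counts.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                k = int(np.argmax(np.abs(sums - 1.0)))
                raise ValidationError(
                    f"relative table column at t={self.times[k]} sums to "
                    f"{sums[k]:.12g}, not 1"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_timepoints(self) -> int:
        return int(self.times.size)

    # -- subsetting -------------------------------------------------------

    def subset_timepoints(self, index: Sequence[int]) -> "AbundanceTable":
        """Restrict to the given timepoint indices (kept in time order)."""
        idx = np.sort(np.asarray(index, dtype=int))
        return replace(
            self,
            times=self.times[idx],
            counts=self.counts[:, idx],
            interval_labels=[self.interval_labels[i] for i in idx],
        )

    def subset_interval(self, label: str) -> "AbundanceTable":
        """Restrict to timepoints carrying the given interval label.

        One (subject, interval) series is the unit of analysis: a microbiota
        state.
        """
        idx = [i for i, lab in enumerate(self.interval_labels) if lab == label]
        if not idx:
            raise ValidationError(
                f"subject {self.subject_id!r} has no timepoints labelled {label!r}"
            )
        return self.subset_timepoints(idx)

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, table_path: str | Path, metadata_path: str | Path) -> None:
        """Write the table and its sidecar metadata as TSV with headers."""
        sample_ids = [f"{self.subject_id}.t{i}" for i in range(self.n_timepoints)]
        df = pd.DataFrame(self.counts, index=self.taxon_ids, columns=sample_ids)
        df.index.name = "taxon_id"
        df.to_csv(table_path, sep="\t")
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subject_id": self.subject_id,
                "day": self.times,
                "label": self.interval_labels,
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False)


@dataclass(frozen=True)
class TaxonStats:
    """Temporal mean / dispersion of one taxon — one point of the Taylor fit.

    ``mean`` is the temporal mean abundance x̄_i (in [0, 1] on the relative
    scale), ``sd`` the temporal standard deviation σ_i (n−1 denominator),
    ``sem`` = sd/√n, and ``n`` the number of timepoints used.
    """

    taxon_id: str
    mean: float
    sd: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0 or self.n < MIN_TIMEPOINTS:
            raise ValidationError(
                f"invalid stats for {self.taxon_id}: mean={self.mean}, "
                f"sd={self.sd}, n={self.n}"
            )


def _read_biom_v1(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    """Minimal BIOM v1 (JSON) reader: returns (taxon_ids, sample_ids, data)."""
    with open(path) as fh:
        doc = json.load(fh)
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    shape = tuple(doc["shape"])
    data = np.zeros(shape, dtype=float)
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            data[int(r), int(c)] = v
    else:
        data[:] = np.asarray(doc["data"], dtype=float)
    return taxon_ids, sample_ids, data


def read_taxa_table(
    path: str | Path,
    metadata: str | Path,
    format: str = "tsv",
    subject_id: str | None = None,
) -> AbundanceTable:
    """Read a taxa × sample table plus sidecar metadata into an AbundanceTable.

    Parameters
    ----------
    path : path
        Taxa table; TSV has taxon IDs in the first column and one column per
        sample, or BIOM v1 JSON.
    metadata : path
        TSV with columns ``sample_id, subject_id, day, label``.
    format : {"tsv", "biom"}
    subject_id : str, optional
        Required when the metadata covers more than one subject.

    Raises
    ------
    InsufficientSeriesError
        Fewer than three timepoints for the subject (sample-selection rule).
    ValidationError
        Missing time stamps, duplicate days, or negative counts.
    """
    path, metadata = Path(path), Path(metadata)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxon_ids = [str(t) for t in df.index]
        sample_ids = [str(c) for c in df.columns]
        data = df.to_numpy(dtype=float)
    elif format == "biom":
        taxon_ids, sample_ids, data = _read_biom_v1(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    meta = pd.read_csv(metadata, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "subject_id", "day", "label"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    meta = meta.set_index("sample_id")

    for s in sample_ids:
        if s not in meta.index:
            raise ValidationError(f"sample {s!r} has no metadata entry (time stamp)")
    subjects = sorted(set(meta.loc[sample_ids, "subject_id"]))
    if subject_id is None:
        if len(subjects) > 1:
            raise ValidationError(
                f"metadata covers subjects {subjects}; pass subject_id"
            )
        subject_id = subjects[0]

    keep = [s for s in sample_ids if meta.loc[s, "subject_id"] == subject_id]
    if len(keep) < MIN_TIMEPOINTS:
        raise InsufficientSeriesError(
            f"subject {subject_id!r} has {len(keep)} timepoints; "
            f"at least {MIN_TIMEPOINTS} required"
        )
    days = meta.loc[keep, "day"].to_numpy(dtype=float)
    if pd.isna(days).any():
        bad = keep[int(np.argmax(pd.isna(days)))]
        raise ValidationError(f"sample {bad!r} is missing its time stamp")
    if len(np.unique(days)) != len(days):
        raise ValidationError(f"duplicate sampling days for subject {subject_id!r}")

    order = np.argsort(days)
    keep = [keep[i] for i in order]
    cols = [sample_ids.index(s) for s in keep]
    return AbundanceTable(
        subject_id=subject_id,
        taxon_ids=taxon_ids,
        times=days[order] - days[order][0],
        counts=data[:, cols],
        interval_labels=[str(meta.loc[s, "label"]) for s in keep],
        is_relative=False,
    )


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert a count table to relative abundances (columns sum to 1).

    Idempotent in effect: calling it on an already-relative table raises, as
    the flag makes re-normalization a no-op by contract.
    """
    if table.is_relative:
        raise ValidationError("table is already on the relative scale")
    totals = table.counts.sum(axis=0)
    if np.any(totals <= 0):
        k = int(np.argmax(totals <= 0))
        raise ValidationError(
            f"timepoint t={table.times[k]} has zero total count; cannot normalize"
        )
    return replace(table, counts=table.counts / totals, is_relative=True)


def compute_stats(
    table: AbundanceTable,
    min_nonzero: int = 2,
    timepoint_subset: Sequence[int] | None = None,
    drop_zeros: bool = False,
) -> list[TaxonStats]:
    """Per-taxon temporal mean, SD (n−1) and SEM over selected timepoints.

    Zeros count as observations of 0 by default; taxa nonzero at fewer than
    ``min_nonzero`` timepoints are dropped (their SD would be dominated by
    presence/absence, not fluctuation).  With ``drop_zeros`` the zero
    observations are instead excluded from each taxon's mean/SD, in which
    case a taxon needs ``max(min_nonzero, 3)`` nonzero timepoints.

    The statistics are order-free: any permutation of the timepoints yields
    identical results.
    """
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    sub = table if timepoint_subset is None else table.subset_timepoints(timepoint_subset)
    if sub.n_timepoints < MIN_TIMEPOINTS:
        raise InsufficientSeriesError(
            f"{sub.n_timepoints} timepoints selected; at least {MIN_TIMEPOINTS} required"
        )
    x = sub.counts
    out: list[TaxonStats] = []
    for i, tid in enumerate(sub.taxon_ids):
        row = x[i]
        nonzero = int(np.count_nonzero(row))
        if nonzero < min_nonzero:
            continue
        vals = row[row > 0] if drop_zeros else row
        n = vals.size
        if n < MIN_TIMEPOINTS:
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        out.append(TaxonStats(taxon_id=tid, mean=mean, sd=sd, sem=sd / np.sqrt(n), n=n))
    if not out:
        raise ValidationError("all taxa were filtered out; no statistics to report")
    if table.is_relative:
        bad = [s.taxon_id for s in out if s.mean > 1 + 1e-12]
        if bad:
            raise ValidationError(f"relative means above 1 for taxa {bad}")
    return out
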
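"""End-to-end study orchestration: stats → fits → z-space → phase → ranks → windows.

:func:`run_study` drives the full analysis for one study from a
:class:`StudyConfig` (optionally loaded from YAML), writing per-subject
Taylor fits, the standardized z-space table with zone labels, per-subject
phase diagnoses, rank reports and sliding-window series, plus a manifest
recording the seed, per-stage timing and a SHA-256 hash of every artifact.
Any stage failure aborts the run and removes partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abundance import AbundanceTable, compute_stats, read_taxa_table, to_relative
from .langevin import classify_phase, infer_fitness
from .ranks import rank_report, stability_islands
from .standardize import SubjectPoint, standardize_study, zone_membership
from .taylor import fit_taylor_xweighted
from .windows import sliding_taylor

__all__ = ["StudyConfig", "run_study"]

log = logging.getLogger("microstab")


@dataclass
class StudyConfig:
    """Configuration of one study run."""

    study_id: str
    input_tables: list[str] = field(default_factory=list)
    metadata: str | None = None
    out_dir: str = "microstab_out"
    healthy_label: str = "healthy"
    seed: int = 42
    n_replicates: int = 1000
    fit_mode: str = "loglog"
    window_size: int = 5
    window_replicates: int = 200
    top_n: int = 50
    rsi_power: float = 4.0
    rsi_threshold: float = 0.70
    radius_68: float = 1.0
    radius_98: float = 2.8
    phase_alpha: str | float = "fitted"  # "fitted" -> alpha = fitted Taylor beta
    min_nonzero: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_study(
    config: StudyConfig, tables: list[AbundanceTable] | None = None
) -> dict:
    """Run the full analysis for one study; returns the manifest dict.

    ``tables`` may supply in-memory count tables directly (e.g. synthetic
    cohorts); otherwise each path in ``config.input_tables`` is read against
    ``config.metadata``.  A subject counts as healthy when every one of its
    timepoints carries the healthy label.
    """
    out = Path(config.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    for sub in ("fits", "phase", "ranks", "windows"):
        (out / sub).mkdir(exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {"study_id": config.study_id, "seed": config.seed,
                      "stages": {}, "artifacts": {}}
    rng = np.random.SeedSequence(config.seed)
    stage = "read"
    try:
        t0 = time.perf_counter()
        if tables is None:
            if not config.input_tables or config.metadata is None:
                raise ValueError("config must list input tables and metadata")
            tables = [
                read_taxa_table(p, config.metadata) for p in config.input_tables
            ]
        rel = {tb.subject_id: to_relative(tb) if not tb.is_relative else tb
               for tb in tables}
        manifest["stages"]["read"] = time.perf_counter() - t0
        log.info("read %d subjects", len(rel))

        stage = "taylor_fit"
        t0 = time.perf_counter()
        seeds = rng.generate_state(len(rel))
        fits = {}
        for (sid, tb), s in zip(rel.items(), seeds):
            stats = compute_stats(tb, min_nonzero=config.min_nonzero)
            fits[sid] = fit_taylor_xweighted(
                stats, n_replicates=config.n_replicates,
                seed=int(s % (2**31)), mode=config.fit_mode,
            )
            doc = fits[sid].as_dict()
            doc["subject_id"] = sid
            doc["study_id"] = config.study_id
            doc["healthy"] = all(
                lab == config.healthy_label for lab in tb.interval_labels
            )
            with open(out / "fits" / f"{sid}.json", "w") as fh:
                json.dump(doc, fh, indent=1)
        manifest["stages"]["taylor_fit"] = time.perf_counter() - t0

        stage = "standardize"
        t0 = time.perf_counter()
        points = [
            SubjectPoint(
                subject_id=sid, study_id=config.study_id,
                V=f.V, err_V=f.err_V, beta=f.beta, err_beta=f.err_beta,
                healthy=all(l == config.healthy_label
                            for l in rel[sid].interval_labels),
            )
            for sid, f in fits.items()
        ]
        ref, zpoints = standardize_study(points)
        zdf = pd.DataFrame(
            {
                "study": config.study_id,
                "subject": [z.subject_id for z in zpoints],
                "healthy": [z.healthy for z in zpoints],
                "z_V": [z.z_V for z in zpoints],
                "z_V_err": [z.z_V_err for z in zpoints],
                "z_beta": [z.z_beta for z in zpoints],
                "z_beta_err": [z.z_beta_err for z in zpoints],
                "zone": [
                    zone_membership(z, config.radius_68, config.radius_98)
                    for z in zpoints
                ],
            }
        )
        zdf.to_csv(out / "zspace.tsv", sep="\t", index=False)
        manifest["stages"]["standardize"] = time.perf_counter() - t0

        stage = "phase"
        t0 = time.perf_counter()
        for sid, tb in rel.items():
            f = fits[sid]
            alpha = f.beta if config.phase_alpha == "fitted" else float(config.phase_alpha)
            dominant = int(np.argmax(tb.counts.sum(axis=1)))
            fest = infer_fitness(tb.counts[dominant], V=f.V, alpha=alpha, beta=f.beta)
            diag = classify_phase(alpha, f.beta, fest.F, f.V)
            with open(out / "phase" / f"{sid}.json", "w") as fh:
                json.dump(
                    {
                        "subject_id": sid, "alpha": alpha, "beta": f.beta,
                        "V": f.V, "F": fest.F, "F_at_bound": fest.at_bound,
                        "phase": diag.phase, "F_crit": diag.F_crit,
                        "margin": diag.margin, "x_M": diag.x_M,
                        "method": diag.method,
                    },
                    fh, indent=1,
                )
        manifest["stages"]["phase"] = time.perf_counter() - t0

        stage = "ranks"
        t0 = time.perf_counter()
        for sid, tb in rel.items():
            top_n = min(config.top_n, tb.n_taxa)
            matrix, report = rank_report(tb, top_n=top_n, p=config.rsi_power)
            pd.DataFrame(
                matrix.ranks, index=matrix.taxon_ids,
                columns=[f"d{t:g}" for t in matrix.times],
            ).rename_axis("taxon_id").to_csv(out / "ranks" / f"{sid}_ranks.tsv", sep="\t")
            islands = set(stability_islands(
                report, matrix, rsi_threshold=config.rsi_threshold,
                rank_band=(11, min(40, top_n)),
            ))
            pd.DataFrame(
                {"taxon_id": report.taxon_ids, "rsi": report.rsi,
                 "island": [t in islands for t in report.taxon_ids]}
            ).to_csv(out / "ranks" / f"{sid}_rsi.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"day": matrix.times, "rv": report.rv, "dv": report.dv}
            ).to_csv(out / "ranks" / f"{sid}_rv_dv.tsv", sep="\t", index=False)
        manifest["stages"]["ranks"] = time.perf_counter() - t0

        stage = "windows"
        t0 = time.perf_counter()
        wseeds = rng.generate_state(len(rel))
        for (sid, tb), s in zip(rel.items(), wseeds):
            if tb.n_timepoints < config.window_size:
                log.info("subject %s too short for windows; skipped", sid)
                continue
            ws = sliding_taylor(
                tb, window_size=config.window_size,
                n_replicates=config.window_replicates, seed=int(s % (2**31)),
                mode=config.fit_mode,
            )
            pd.DataFrame(
                {"center_day": ws.centers, "V": ws.V, "err_V": ws.err_V,
                 "beta": ws.beta, "err_beta": ws.err_beta}
            ).to_csv(out / "windows" / f"{sid}.tsv", sep="\t", index=False)
        manifest["stages"]["windows"] = time.perf_counter() - t0

        stage = "manifest"
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                manifest["artifacts"][str(p.relative_to(out))] = _sha256(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        log.info("run complete: %d artifacts", len(manifest["artifacts"]))
        return manifest
    except Exception as exc:
        log.exception("stage %r failed; removing partial outputs", stage)
        log.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for sub in ("fits", "phase", "ranks", "windows"):
                shutil.rmtree(out / sub, ignore_errors=True)
            for name in ("zspace.tsv", "manifest.json"):
                (out / name).unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()
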
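#!/usr/bin/env python
"""Standardize the fitted (V, beta) values against the healthy reference
group and classify each series relative to the healthy zone.

Reads results/taylor_fits.tsv, writes results/zspace.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microstab.standardize import SubjectPoint, standardize_study, zone_membership

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    fits = pd.read_csv(ROOT / "taylor_fits.tsv", sep="\t")
    points = [
        SubjectPoint(
            subject_id=f"{r.subject}:{r.interval}", study_id="synthA",
            V=r.V, err_V=r.err_V, beta=r.beta, err_beta=r.err_beta,
            healthy=bool(r.healthy) and r.interval == "healthy",
        )
        for r in fits.itertuples()
    ]
    ref, zpts = standardize_study(points)
    df = pd.DataFrame(
        dict(
            series=[z.subject_id for z in zpts],
            healthy=[z.healthy for z in zpts],
            z_V=[z.z_V for z in zpts],
            z_V_err=[z.z_V_err for z in zpts],
            z_beta=[z.z_beta for z in zpts],
            z_beta_err=[z.z_beta_err for z in zpts],
            radius=[float(np.hypot(z.z_V, z.z_beta)) for z in zpts],
            zone=[zone_membership(z) for z in zpts],
        )
    )
    df.to_csv(ROOT / "zspace.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"healthy reference: V = {ref.V_hat:.4f} +- {ref.sigma_V:.4f}, "
          f"beta = {ref.beta_hat:.4f} +- {ref.sigma_beta:.4f}")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
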
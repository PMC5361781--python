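#!/usr/bin/env python
"""Fit Taylor's law sigma = V * x^beta per (subject, interval) series.

One (subject, interval) series is the unit of analysis — a microbiota state.
Reads results/cohort/, writes results/taylor_fits.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microstab.abundance import compute_stats, read_taxa_table, to_relative
from microstab.taylor import fit_taylor_xweighted

SEED = 7041
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = ROOT / "cohort" / "metadata.tsv"
    rows = []
    seeds = np.random.SeedSequence(SEED).generate_state(100)
    k = 0
    for tpath in sorted((ROOT / "cohort").glob("[HP]*.tsv")):
        table = read_taxa_table(tpath, meta)
        for label in dict.fromkeys(table.interval_labels):
            series = to_relative(table.subset_interval(label))
            stats = compute_stats(series, min_nonzero=2)
            fit = fit_taylor_xweighted(stats, n_replicates=1000,
                                       seed=int(seeds[k] % 2**31))
            k += 1
            rows.append(dict(
                subject=table.subject_id, interval=label,
                healthy=table.subject_id.startswith("H"),
                n_timepoints=series.n_timepoints, n_taxa=len(stats),
                V=fit.V, err_V=fit.err_V, beta=fit.beta,
                err_beta=fit.err_beta, r2=fit.r2, param_corr=fit.param_corr,
            ))
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "taylor_fits.tsv", sep="\t", index=False,
              float_format="%.6g")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
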
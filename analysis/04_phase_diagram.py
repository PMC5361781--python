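#!/usr/bin/env python
"""Locate each series on the ordered/disordered phase diagram.

For every (subject, interval) series: infer the dominant taxon's fitness F
from its abundance series by stationary-likelihood MLE, then compare F to
the critical fitness at the fitted (V, beta).  Also tabulates the phase
line F_crit(V) for alpha = beta = 0.75 with self-consistent phi0 = F.

Reads results/cohort/ and results/taylor_fits.tsv, writes results/phase.tsv
and results/phase_line.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microstab.abundance import read_taxa_table, to_relative
from microstab.langevin import classify_phase, infer_fitness

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    line = pd.DataFrame({"V": np.round(np.arange(0.05, 0.65, 0.05), 2)})
    line["F_crit"] = 3 * line["V"] ** 2
    line.to_csv(ROOT / "phase_line.tsv", sep="\t", index=False)

    fits = pd.read_csv(ROOT / "taylor_fits.tsv", sep="\t")
    meta = ROOT / "cohort" / "metadata.tsv"
    rows = []
    for r in fits.itertuples():
        table = read_taxa_table(ROOT / "cohort" / f"{r.subject}.tsv", meta)
        series = to_relative(table.subset_interval(r.interval))
        dominant = int(np.argmax(series.counts.sum(axis=1)))
        est = infer_fitness(series.counts[dominant], V=r.V,
                            alpha=r.beta, beta=r.beta)
        diag = classify_phase(r.beta, r.beta, est.F, r.V)
        rows.append(dict(
            subject=r.subject, interval=r.interval, V=r.V, beta=r.beta,
            F=est.F, F_at_bound=est.at_bound, F_crit=diag.F_crit,
            margin=diag.margin, phase=diag.phase, x_M=diag.x_M,
            method=diag.method,
        ))
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "phase.tsv", sep="\t", index=False, float_format="%.6g")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
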
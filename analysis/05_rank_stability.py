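#!/usr/bin/env python
"""Rank-dynamics analysis per subject: RSI, rank/difference variability and
stability islands.

Reads results/cohort/, writes results/rsi.tsv and results/rv_dv.tsv.
"""

from pathlib import Path

import pandas as pd

from microstab.abundance import read_taxa_table, to_relative
from microstab.ranks import rank_report, stability_islands

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    meta = ROOT / "cohort" / "metadata.tsv"
    rsi_rows, rv_rows = [], []
    for tpath in sorted((ROOT / "cohort").glob("[HP]*.tsv")):
        table = to_relative(read_taxa_table(tpath, meta))
        top_n = min(30, table.n_taxa)
        matrix, report = rank_report(table, top_n=top_n, p=4.0)
        islands = set(stability_islands(report, matrix,
                                        rank_band=(11, min(40, top_n))))
        for tid, val in zip(report.taxon_ids, report.rsi):
            rsi_rows.append(dict(subject=table.subject_id, taxon_id=tid,
                                 rsi=val, island=tid in islands))
        for day, rv, dv in zip(matrix.times, report.rv, report.dv):
            rv_rows.append(dict(subject=table.subject_id, day=day,
                                rv=rv, dv=dv))
    rsi_df = pd.DataFrame(rsi_rows)
    rsi_df.to_csv(ROOT / "rsi.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame(rv_rows).to_csv(ROOT / "rv_dv.tsv", sep="\t", index=False,
                                 float_format="%.6g")
    summary = rsi_df.groupby("subject").agg(
        mean_rsi=("rsi", "mean"), median_rsi=("rsi", "median"),
        max_rsi=("rsi", "max"), n_islands=("island", "sum"),
    )
    print(summary.to_string())


if __name__ == "__main__":
    main()
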
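#!/usr/bin/env python
"""Generate the demonstration cohort: four healthy subjects plus one subject
whose second half is an antibiotic interval with elevated noise amplitude.

Healthy subjects carry slightly different baseline noise amplitudes
(V = 0.19 ... 0.22) so the healthy reference group has a realistic
between-subject spread; the perturbed interval doubles the amplitude.

Writes per-subject count tables and a combined metadata TSV under
results/cohort/.
"""

from pathlib import Path

import pandas as pd

from microstab.synthetic import (
    CohortSpec,
    IntervalSpec,
    SubjectSpec,
    gen_langevin_cohort,
)

SEED = 20240915
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def cohort_spec() -> CohortSpec:
    healthy_V = {"H1": 0.19, "H2": 0.20, "H3": 0.21, "H4": 0.22}
    subjects = tuple(
        SubjectSpec(sid, (IntervalSpec("healthy", 30, V=V),), True, SEED + i)
        for i, (sid, V) in enumerate(healthy_V.items(), start=1)
    ) + (
        SubjectSpec(
            "P1",
            (IntervalSpec("healthy", 15, V=0.21),
             IntervalSpec("antibiotic", 15, V=0.42)),
            False,
            SEED + 9,
        ),
    )
    return CohortSpec(study_id="synthA", subjects=subjects, n_taxa=30,
                      baseline_V=0.2, burn_in=15.0, dt=1e-3)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metas = []
    for table in gen_langevin_cohort(cohort_spec()):
        tpath = OUT / f"{table.subject_id}.tsv"
        mpath = OUT / f"{table.subject_id}.meta.tsv"
        table.to_tsv(tpath, mpath)
        metas.append(pd.read_csv(mpath, sep="\t"))
        mpath.unlink()
    pd.concat(metas).to_csv(OUT / "metadata.tsv", sep="\t", index=False)
    print(f"wrote {len(metas)} subjects to {OUT}")


if __name__ == "__main__":
    main()
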
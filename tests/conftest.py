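import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microstab.abundance import AbundanceTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 taxa x 4 timepoints of counts."""
    counts = np.array(
        [
            [20.0, 18.0, 25.0, 22.0],
            [5.0, 8.0, 4.0, 6.0],
            [75.0, 74.0, 71.0, 72.0],
        ]
    )
    return AbundanceTable(
        subject_id="S1",
        taxon_ids=["g__A", "g__B", "g__C"],
        times=np.array([0.0, 3.0, 7.0, 10.0]),
        counts=counts,
        interval_labels=["healthy"] * 4,
    )


@pytest.fixture
def tsv_pair(tmp_path, small_table):
    """The small table written as TSV + sidecar metadata; returns the paths."""
    table_path = tmp_path / "table.tsv"
    meta_path = tmp_path / "meta.tsv"
    small_table.to_tsv(table_path, meta_path)
    return table_path, meta_path
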
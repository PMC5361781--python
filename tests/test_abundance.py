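import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microstab.abundance import (
    AbundanceTable,
    InsufficientSeriesError,
    ValidationError,
    compute_stats,
    read_taxa_table,
    to_relative,
)


class TestReadTaxaTable:
    def test_tsv_roundtrip(self, tsv_pair, small_table):
        table = read_taxa_table(*tsv_pair)
        assert table.subject_id == "S1"
        assert table.taxon_ids == small_table.taxon_ids
        np.testing.assert_allclose(table.times, [0, 3, 7, 10])
        np.testing.assert_allclose(table.counts, small_table.counts)

    def test_samples_sorted_by_time(self, tmp_path, small_table):
        table_path, meta_path = tmp_path / "t.tsv", tmp_path / "m.tsv"
        small_table.to_tsv(table_path, meta_path)
        # scramble the metadata day order
        lines = meta_path.read_text().splitlines()
        meta_path.write_text("\n".join([lines[0]] + lines[1:][::-1]) + "\n")
        table = read_taxa_table(table_path, meta_path)
        assert np.all(np.diff(table.times) > 0)

    def test_two_samples_is_insufficient(self, tmp_path):
        (tmp_path / "t.tsv").write_text("taxon_id\ts1\ts2\nA\t1\t2\nB\t3\t4\n")
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\tday\tlabel\ns1\tS\t0\thealthy\ns2\tS\t1\thealthy\n"
        )
        with pytest.raises(InsufficientSeriesError, match="3"):
            read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_negative_count_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "taxon_id\ts1\ts2\ts3\nA\t1\t-2\t3\nB\t3\t4\t5\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\tday\tlabel\n"
            "s1\tS\t0\th\ns2\tS\t1\th\ns3\tS\t2\th\n"
        )
        with pytest.raises(ValidationError, match="negative"):
            read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_missing_metadata_names_sample(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "taxon_id\ts1\ts2\ts3\nA\t1\t2\t3\nB\t3\t4\t5\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\tday\tlabel\ns1\tS\t0\th\ns2\tS\t1\th\n"
        )
        with pytest.raises(ValidationError, match="s3"):
            read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_duplicate_days_rejected(self, tmp_path):
        (tmp_path / "t.tsv").write_text(
            "taxon_id\ts1\ts2\ts3\nA\t1\t2\t3\nB\t3\t4\t5\n"
        )
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\tday\tlabel\n"
            "s1\tS\t0\th\ns2\tS\t1\th\ns3\tS\t1\th\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_taxa_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_biom_v1_sparse(self, tmp_path):
        doc = {
            "id": "x", "format": "1.0", "type": "OTU table",
            "matrix_type": "sparse", "shape": [2, 3],
            "rows": [{"id": "A"}, {"id": "B"}],
            "columns": [{"id": "s1"}, {"id": "s2"}, {"id": "s3"}],
            "data": [[0, 0, 5], [0, 2, 1], [1, 1, 7]],
        }
        (tmp_path / "t.biom").write_text(json.dumps(doc))
        (tmp_path / "m.tsv").write_text(
            "sample_id\tsubject_id\tday\tlabel\n"
            "s1\tS\t0\th\ns2\tS\t1\th\ns3\tS\t2\th\n"
        )
        table = read_taxa_table(tmp_path / "t.biom", tmp_path / "m.tsv", format="biom")
        np.testing.assert_allclose(table.counts, [[5, 0, 1], [0, 7, 0]])


class TestToRelative:
    def test_proportions(self):
        tb = AbundanceTable("s", ["A", "B", "C"], [0, 1, 2],
                            np.array([[2, 2, 2], [3, 3, 3], [5, 5, 5]], float))
        rel = to_relative(tb)
        np.testing.assert_allclose(rel.counts[:, 0], [0.2, 0.3, 0.5])
        assert rel.is_relative
        np.testing.assert_allclose(rel.counts.sum(axis=0), 1.0)

    def test_already_relative_rejected(self, small_table):
        rel = to_relative(small_table)
        with pytest.raises(ValidationError, match="already"):
            to_relative(rel)

    def test_zero_total_column_names_timepoint(self):
        tb = AbundanceTable("s", ["A", "B"], [0, 1, 2],
                            np.array([[1, 0, 1], [1, 0, 1]], float))
        with pytest.raises(ValidationError, match="t=1"):
            to_relative(tb)


class TestComputeStats:
    def _table(self, rows, times=None):
        rows = np.atleast_2d(np.asarray(rows, float))
        t = np.arange(rows.shape[1]) if times is None else times
        # pad with a filler taxon so columns sum to 1
        filler = 1.0 - rows.sum(axis=0)
        assert np.all(filler >= 0)
        return AbundanceTable("s", [f"T{i}" for i in range(rows.shape[0])] + ["fill"],
                              t, np.vstack([rows, filler]), is_relative=True)

    def test_constant_series(self):
        stats = compute_stats(self._table([[0.1, 0.1, 0.1]]))
        s = next(s for s in stats if s.taxon_id == "T0")
        assert s.mean == pytest.approx(0.1, abs=1e-15)
        assert s.sd == pytest.approx(0.0, abs=1e-15)
        assert s.sem == pytest.approx(0.0, abs=1e-15)
        assert s.n == 3

    def test_hand_computed_sd(self):
        stats = compute_stats(self._table([[0.1, 0.2, 0.3]]))
        s = next(s for s in stats if s.taxon_id == "T0")
        assert s.mean == pytest.approx(0.2)
        assert s.sd == pytest.approx(0.1)
        assert s.sem == pytest.approx(0.1 / np.sqrt(3))

    def test_rare_taxon_dropped(self):
        rows = np.zeros((1, 10))
        rows[0, 3] = 0.5
        stats = compute_stats(self._table(rows), min_nonzero=2)
        assert all(s.taxon_id != "T0" for s in stats)

    def test_all_filtered_is_error(self):
        tb = self._table(np.zeros((1, 5)))
        # the filler taxon is constant-1, nonzero everywhere; exclude it by
        # demanding more nonzero points than exist for T0 and allowing filler
        with pytest.raises(ValidationError):
            compute_stats(tb.subset_timepoints(range(5)), min_nonzero=6)

    @given(st.permutations(list(range(6))))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(0)
        rows = rng.dirichlet(np.ones(4), size=6).T  # 4 taxa x 6 times
        tb = AbundanceTable("s", list("ABCD"), np.arange(6.0), rows, is_relative=True)
        base = compute_stats(tb)
        permuted = AbundanceTable("s", list("ABCD"), np.arange(6.0),
                                  rows[:, perm], is_relative=True)
        for a, b in zip(base, compute_stats(permuted)):
            assert a.taxon_id == b.taxon_id
            assert a.mean == pytest.approx(b.mean)
            assert a.sd == pytest.approx(b.sd)

    def test_sem_never_exceeds_sd(self):
        rng = np.random.default_rng(1)
        rows = rng.dirichlet(np.ones(10), size=8).T
        tb = AbundanceTable("s", [f"T{i}" for i in range(10)], np.arange(8.0),
                            rows, is_relative=True)
        for s in compute_stats(tb):
            assert s.sem <= s.sd


class TestTableInvariants:
    def test_times_must_increase(self):
        with pytest.raises(ValidationError, match="increasing"):
            AbundanceTable("s", ["A"], [0, 0, 1], np.ones((1, 3)))

    def test_relative_columns_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sums"):
            AbundanceTable("s", ["A", "B"], [0, 1, 2],
                           np.full((2, 3), 0.4), is_relative=True)

    def test_interval_subsetting(self, small_table):
        small_table.interval_labels = ["healthy", "healthy", "antibiotic", "antibiotic"]
        sub = small_table.subset_interval("antibiotic")
        np.testing.assert_allclose(sub.times, [7, 10])
        with pytest.raises(ValidationError):
            small_table.subset_interval("trip")
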
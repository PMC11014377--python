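import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agingtx import (
    CountMatrix,
    Transcript,
    TranscriptCatalog,
    count_isoforms_detected,
    filter_low_counts,
    quantile_normalize,
    read_counts,
    read_gtf,
    row_median_center,
    write_counts,
    write_gtf,
)
from agingtx.core_io import ParseError, read_sample_sheet, write_sample_sheet

from conftest import make_matrix, make_sheet


class TestCountsIO:
    def test_round_trip_preserves_values_and_order(self, tmp_path):
        m = make_matrix([[1.5, 2.25, 0, 3], [4, 0, 0, 7]], features=["gA", "gB"])
        write_counts(m, tmp_path / "c.tsv")
        write_sample_sheet(m.samples, tmp_path / "s.tsv")
        back = read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
        assert list(back.samples["age_group"]) == list(m.samples["age_group"])

    def test_duplicate_feature_id_is_named(self, tmp_path):
        (tmp_path / "c.tsv").write_text("feature_id\ty1\ta1\ngX\t1\t2\ngX\t3\t4\n")
        (tmp_path / "s.tsv").write_text("sample_id\tage_group\ny1\t6m\na1\t24m\n")
        with pytest.raises(ParseError, match="gX"):
            read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")

    def test_non_numeric_cell_is_located(self, tmp_path):
        (tmp_path / "c.tsv").write_text("feature_id\ty1\ta1\ngX\t1\toops\n")
        (tmp_path / "s.tsv").write_text("sample_id\tage_group\ny1\t6m\na1\t24m\n")
        with pytest.raises(ParseError, match="a1"):
            read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")

    def test_empty_matrix_is_valid(self, tmp_path):
        (tmp_path / "c.tsv").write_text("feature_id\ty1\ta1\n")
        (tmp_path / "s.tsv").write_text("sample_id\tage_group\ny1\t6m\na1\t24m\n")
        m = read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert m.values.shape == (0, 2)

    def test_sample_missing_from_sheet_rejected(self):
        sheet = make_sheet(1, 1)
        with pytest.raises(ParseError, match="absent"):
            CountMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["zz"]), sheet)


class TestLowCountFilter:
    def test_mean_at_threshold_removed_inclusive(self):
        m = make_matrix([[5, 5, 5, 5], [6, 6, 6, 6]])
        out, n_removed = filter_low_counts(m, threshold=5)
        assert list(out.feature_ids) == ["f1"]
        assert n_removed == 1

    def test_single_spike_retained_by_mean_rule(self):
        m = make_matrix([[100, 0, 0, 0, 0, 0, 0, 0]], n_young=4, n_aged=4)
        out, _ = filter_low_counts(m, threshold=5)
        assert len(out.feature_ids) == 1  # mean 12.5 > 5

    def test_all_zero_matrix_empties_without_error(self):
        m = make_matrix(np.zeros((3, 4)))
        out, n_removed = filter_low_counts(m, threshold=5)
        assert out.values.empty and n_removed == 3

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_low_counts(make_matrix([[1, 1]]), threshold=-1)


class TestQuantileNormalize:
    def test_worked_two_by_two_example(self):
        m = make_matrix([[1, 4], [3, 2]])
        out = quantile_normalize(m).values.to_numpy()
        assert np.allclose(out, [[1.5, 3.5], [3.5, 1.5]])

    def test_identical_columns_are_a_fixed_point(self):
        m = make_matrix(np.tile([[3.0], [1.0], [2.0]], (1, 4)))
        out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.lists(st.floats(0, 1e6), min_size=3, max_size=3,
                             unique=True),
                    min_size=2, max_size=30))
    def test_sorted_columns_identical_and_idempotent(self, rows):
        from hypothesis import assume

        arr_in = np.asarray(rows)
        # the exact-equality property is defined for tie-free samples
        assume(all(len(np.unique(arr_in[:, j])) == arr_in.shape[0]
                   for j in range(arr_in.shape[1])))
        m = make_matrix(rows)
        out = quantile_normalize(m)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            assert np.allclose(np.sort(arr[:, j]), ref)
        twice = quantile_normalize(out).values.to_numpy()
        assert np.allclose(twice, arr, atol=1e-12)

    def test_tied_values_get_mean_of_rank_means(self):
        m = make_matrix([[1, 1], [1, 3]])
        out = quantile_normalize(m).values.to_numpy()
        # rank means (1, 2); the tied first column spans both ranks
        assert np.allclose(out[:, 0], [1.5, 1.5])
        assert np.allclose(out[:, 1], [1.0, 2.0])

    def test_single_sample_warns_and_returns_input(self):
        m = make_matrix([[1.0], [2.0]], n_young=1, n_aged=0)
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        assert np.allclose(out.values, m.values)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.poisson(40.0, size=(30, 6)).astype(float)
        m = make_matrix(vals)
        perm = rng.permutation(30)
        m_perm = make_matrix(vals[perm])
        a = quantile_normalize(filter_low_counts(m)[0]).values.to_numpy()
        b = quantile_normalize(filter_low_counts(m_perm)[0]).values.to_numpy()
        # permuting input rows permutes output rows identically
        order_a = np.lexsort(a.T)
        order_b = np.lexsort(b.T)
        assert np.allclose(a[order_a], b[order_b])


class TestRowMedianCenter:
    def test_divides_by_row_median(self):
        out, flagged = row_median_center(make_matrix([[2, 4, 8]], n_young=2, n_aged=1))
        assert np.allclose(out.values.to_numpy(), [[0.5, 1, 2]])
        assert flagged == []

    def test_constant_positive_row_becomes_ones(self):
        out, _ = row_median_center(make_matrix([[3, 3, 3]], n_young=2, n_aged=1))
        assert np.allclose(out.values.to_numpy(), 1.0)

    def test_zero_median_falls_back_to_smallest_positive(self):
        out, flagged = row_median_center(make_matrix([[0, 0, 4]], n_young=2, n_aged=1))
        assert np.allclose(out.values.to_numpy(), [[0, 0, 1]])
        assert flagged == ["f0"]


class TestIsoformDetection:
    def test_group_mean_exactly_at_cutoff_not_detected(self):
        m = make_matrix([[2, 2, 10, 10]], n_young=2, n_aged=2)
        res = count_isoforms_detected(m, cutoff=2)
        assert res["n_young"] == 0 and res["n_aged"] == 1

    def test_percent_difference_arithmetic(self):
        young = np.full((103, 2), 1.0)
        young[:100] = 5.0
        aged = np.full((103, 2), 5.0)
        m = make_matrix(np.hstack([young, aged]), n_young=2, n_aged=2)
        res = count_isoforms_detected(m, cutoff=2)
        assert res["n_young"] == 100 and res["n_aged"] == 103
        assert res["percent_difference"] == pytest.approx(3.0)

    def test_identical_groups_give_zero_difference(self):
        m = make_matrix([[5, 6, 5, 6], [1, 1, 1, 1]], n_young=2, n_aged=2)
        assert count_isoforms_detected(m)["percent_difference"] == 0.0


class TestGtf:
    def test_catalog_round_trip(self, tmp_path, small_bundle):
        catalog = small_bundle["catalog"]
        write_gtf(catalog, tmp_path / "cat.gtf")
        back = read_gtf(tmp_path / "cat.gtf")
        assert len(back) == len(catalog)
        for tx in catalog:
            other = back[tx.transcript_id]
            assert other.exons == tx.exons
            assert other.cds == tx.cds
            assert other.strand == tx.strand
            assert other.gene_id == tx.gene_id

    def test_transcript_geometry_validation(self):
        with pytest.raises(ValueError, match="overlapping"):
            Transcript("t", "g", "+", [(0, 100), (50, 150)])
        with pytest.raises(ValueError, match="CDS"):
            Transcript("t", "g", "+", [(0, 100)], cds=(50, 200))

    def test_region_lengths_sum_to_cdna(self, small_bundle):
        for tx in small_bundle["catalog"]:
            r = tx.region_tx_intervals()
            if "CDS" in r:
                total = (r["5UTR"][1] - r["5UTR"][0]) + (r["CDS"][1] - r["CDS"][0]) \
                    + (r["3UTR"][1] - r["3UTR"][0])
                assert total == tx.cdna_length
                assert (r["CDS"][1] - r["CDS"][0]) % 3 == 0
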
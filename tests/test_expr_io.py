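"""Expression I/O, quantile normalization, transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from splicestress import expr_io
from splicestress.expr_io import (
    ExpressionDataset,
    collapse_probes,
    log2_transform,
    quantile_normalize,
    read_expression,
    write_expression,
    zscore_rows,
)


def quantile_normalize_oracle(arr: np.ndarray) -> np.ndarray:
    """Brute-force mean-of-sorted reference with tie averaging."""
    n, m = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(m):
        col = arr[:, j]
        for i in range(n):
            # ranks occupied by the tied span of col[i] (0-based)
            tied = np.flatnonzero(np.sort(col) == col[i])
            out[i, j] = reference[tied].mean()
    return out


class TestReadWrite:
    def test_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "expr.tsv"
        write_expression(small_dataset, path)
        back = read_expression(path, small_dataset.group_of, dataset_id="toy")
        assert back.genes == small_dataset.genes
        assert back.samples == small_dataset.samples
        np.testing.assert_allclose(back.values, small_dataset.values)
        assert back.values.shape == (3, 4)

    def test_missing_group_label_names_sample(self, small_dataset, tmp_path):
        path = tmp_path / "expr.tsv"
        write_expression(small_dataset, path)
        groups = dict(small_dataset.group_of)
        del groups["s3"]
        with pytest.raises(ValueError, match="s3"):
            read_expression(path, groups)

    def test_non_numeric_cell_cites_row_and_column(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\ts1\ts2\ngA\t1.0\tNA\ngB\t2.0\t3.0\n")
        with pytest.raises(ValueError, match="gA.*s2"):
            read_expression(path, {"s1": "control", "s2": "treated"})

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("gene_id\ts1\ts1\ngA\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_expression(path, {"s1": "control"})

    def test_group_spec_round_trip(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("s1\tcontrol\t0\ns2\ttreated\t24\n")
        group_of, time_of = expr_io.read_group_spec(path)
        assert group_of == {"s1": "control", "s2": "treated"}
        assert time_of == {"s1": 0.0, "s2": 24.0}

    def test_invalid_group_label_rejected(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("s1\tcontrol\ns2\tdosed\n")
        with pytest.raises(ValueError, match="dosed"):
            expr_io.read_group_spec(path)


class TestDetectionFilterAndIdMap:
    def test_detection_filter_drops_undetected_rows(self):
        values = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                              columns=["s1", "s2"])
        det = pd.DataFrame([[0.01, 0.2], [0.5, 0.9]], index=["a", "b"],
                           columns=["s1", "s2"])
        out = expr_io.detection_filter(values, det, threshold=0.05)
        assert list(out.index) == ["a"]  # b undetected in every sample

    def test_gene_id_map_reader(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("p1\tNM_0001\np2\tNM_0002\n")
        assert expr_io.read_gene_id_map(path) == {"p1": "NM_0001",
                                                  "p2": "NM_0002"}
        bad = tmp_path / "bad.tsv"
        bad.write_text("p1\t\n")
        with pytest.raises(ValueError, match="empty target"):
            expr_io.read_gene_id_map(bad)


class TestQuantileNormalize:
    def test_two_column_example(self):
        arr = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        out = quantile_normalize(arr)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_fixed_point(self):
        arr = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 3))
        np.testing.assert_allclose(quantile_normalize(arr), arr)

    def test_tie_averaging(self):
        arr = np.array([[1.0, 3.0], [1.0, 4.0], [2.0, 5.0]])
        out = quantile_normalize(arr)
        # reference = mean of sorted columns = [2, 2.5, 3.5]
        # tied entries of column 0 share mean(2, 2.5) = 2.25
        np.testing.assert_allclose(out[:, 0], [2.25, 2.25, 3.5])
        np.testing.assert_allclose(out[:, 1], [2.0, 2.5, 3.5])
        np.testing.assert_allclose(out, quantile_normalize_oracle(arr))

    def test_matches_oracle_on_random_matrices_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            arr = rng.integers(0, 6, size=(12, 4)).astype(float)
            np.testing.assert_allclose(
                quantile_normalize(arr), quantile_normalize_oracle(arr),
                atol=1e-12,
            )

    def test_column_means_equal(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(50, 5))
        out = quantile_normalize(arr)
        means = out.mean(axis=0)
        assert np.ptp(means) < 1e-9

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent_and_rank_preserving(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(20, 3))
        once = quantile_normalize(arr)
        np.testing.assert_allclose(quantile_normalize(once), once, atol=1e-9)
        for j in range(arr.shape[1]):
            assert (np.argsort(once[:, j]) == np.argsort(arr[:, j])).all()

    def test_single_column_warns_unchanged(self):
        arr = np.array([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(arr)
        np.testing.assert_allclose(out, arr)


class TestLog2Transform:
    def test_basic(self):
        np.testing.assert_allclose(
            log2_transform(np.array([[1.0, 2.0, 4.0]])), [[0.0, 1.0, 2.0]]
        )

    def test_offset(self):
        np.testing.assert_allclose(log2_transform(np.array([[0.0]]), 1.0), [[0.0]])

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            log2_transform(np.array([[0.0]]), 0.0)


class TestCollapseProbes:
    @pytest.fixture
    def probe_dataset(self):
        data = pd.DataFrame(
            [[5.0, 5.0], [7.0, 7.0], [1.0, 3.0]],
            index=["p1", "p2", "p3"],
            columns=["s1", "s2"],
        )
        groups = {"s1": "control", "s2": "treated"}
        return ExpressionDataset("d", data, groups)

    def test_max_mean_probe(self, probe_dataset):
        out = collapse_probes(probe_dataset, {"p1": "G", "p2": "G"},
                              method="max-mean-probe")
        assert out.genes == ["G"]
        np.testing.assert_allclose(out.values, [[7.0, 7.0]])

    def test_mean(self, probe_dataset):
        out = collapse_probes(probe_dataset, {"p1": "G", "p2": "G"},
                              method="mean")
        np.testing.assert_allclose(out.values, [[6.0, 6.0]])

    def test_unmapped_probe_dropped(self, probe_dataset, caplog):
        import logging
        with caplog.at_level(logging.INFO, logger="splicestress.expr_io"):
            out = collapse_probes(
                probe_dataset, {"p1": "G1", "p2": "G2"}, method="mean")
        assert out.genes == ["G1", "G2"]
        assert "1 unmapped" in caplog.text

    def test_gene_count_equals_distinct_mapped_ids(self, probe_dataset):
        idmap = {"p1": "G1", "p2": "G2", "p3": "G1"}
        out = collapse_probes(probe_dataset, idmap, method="mean")
        assert sorted(out.genes) == sorted(set(idmap.values()))

    def test_empty_after_mapping_error(self, probe_dataset):
        with pytest.raises(ValueError):
            collapse_probes(probe_dataset, {"px": "G"})


class TestZscoreRows:
    def test_example(self):
        np.testing.assert_allclose(
            zscore_rows(np.array([[2.0, 4.0, 6.0]])), [[-1.0, 0.0, 1.0]]
        )

    def test_constant_row_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = zscore_rows(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], [0.0, 0.0, 0.0])
        assert np.isfinite(out).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_zero_sd_one_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.normal(size=(5, 6)) * 3 + 2
        out = zscore_rows(arr)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-9)
        np.testing.assert_allclose(zscore_rows(out), out, atol=1e-9)
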
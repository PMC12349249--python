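"""Ingestion and preprocessing: reductions, normalization, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relnose.signal_io import (DatasetBundle, DialectConfig, DiscardRecording,
                               RawRecording, Sample, channel_shuffle,
                               equal_interval_extract, load_bundle, normalize,
                               per_second_average, preprocess_recording,
                               read_raw_table, save_bundle, window_truncate,
                               write_raw_table)


class TestReadRawTable:
    def test_well_formed_file(self, tmp_path):
        data = np.arange(80.0).reshape(10, 8)
        path = tmp_path / "rec.csv"
        np.savetxt(path, data, delimiter=",")
        rec = read_raw_table(path, label="x")
        assert rec.n_points == 10 and rec.n_sensors == 8
        np.testing.assert_allclose(rec.channels, data)

    def test_blank_cell_discards_recording(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2,3\n4,,6\n7,8,9\n")
        with pytest.raises(DiscardRecording):
            read_raw_table(path)

    def test_non_numeric_cell_discards_recording(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2\n3,oops\n")
        with pytest.raises(DiscardRecording):
            read_raw_table(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raw_table(tmp_path / "absent.csv")

    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        rec = RawRecording(rng.normal(size=(50, 8)), 0.01, label="g", source="meta_test")
        path = tmp_path / "rt.csv"
        write_raw_table(rec, path)
        back = read_raw_table(path, label="g", source="meta_test")
        assert np.array_equal(back.channels, rec.channels)

    def test_dialect_drops_time_column_and_reorders(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("t\ta\tb\n0\t10\t20\n1\t30\t40\n")
        dialect = DialectConfig(delimiter="\t", header_rows=1, time_column=0,
                                channel_columns=(1, 0))
        rec = read_raw_table(path, dialect)
        np.testing.assert_allclose(rec.channels, [[20, 10], [40, 30]])


class TestPerSecondAverage:
    def test_constant_channel(self):
        rec = RawRecording(np.full((300, 2), 2.5), 0.01, "c")
        out = per_second_average(rec, 100)
        assert out.shape == (3, 2)
        np.testing.assert_allclose(out, 2.5)

    def test_forty_thousand_points_become_four_hundred_rows(self):
        rec = RawRecording(np.zeros((40_000, 8)), 0.01, "c")
        assert per_second_average(rec, 100).shape == (400, 8)

    def test_ramp_means(self):
        ramp = np.arange(200.0).reshape(200, 1)
        np.testing.assert_allclose(per_second_average(ramp, 100).ravel(),
                                   [49.5, 149.5])

    def test_trailing_remainder_dropped(self):
        out = per_second_average(np.ones((250, 1)), 100)
        assert out.shape == (2, 1)

    def test_invalid_points_per_second(self):
        with pytest.raises(ValueError):
            per_second_average(np.ones((10, 1)), 0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_commutes_with_channel_permutation(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.normal(size=(300, 5))
        perm = rng.permutation(5)
        np.testing.assert_allclose(per_second_average(matrix, 100)[:, perm],
                                   per_second_average(matrix[:, perm], 100))


class TestWindowTruncate:
    def test_default_window_gives_240_rows(self):
        out = window_truncate(np.arange(400 * 8.0).reshape(400, 8))
        assert out.shape == (240, 8)

    def test_full_window_is_identity(self):
        m = np.arange(20.0).reshape(10, 2)
        np.testing.assert_array_equal(window_truncate(m, 0, 10), m)

    def test_row_alignment(self):
        m = np.arange(400.0).reshape(400, 1)
        out = window_truncate(m)
        for i in (0, 100, 239):
            assert out[i, 0] == m[17 + i, 0]

    def test_out_of_bounds_window(self):
        with pytest.raises(ValueError):
            window_truncate(np.zeros((100, 2)), 17, 257)


class TestEqualIntervalExtract:
    def test_four_thousand_to_240(self):
        assert equal_interval_extract(np.zeros((4000, 8)), 240).shape == (240, 8)

    def test_target_equals_rows_is_identity(self):
        m = np.arange(12.0).reshape(6, 2)
        np.testing.assert_array_equal(equal_interval_extract(m, 6), m)

    def test_index_rule(self):
        m = np.arange(10.0).reshape(10, 1)
        np.testing.assert_array_equal(equal_interval_extract(m, 4).ravel(),
                                      [0, 3, 6, 9])

    def test_endpoints_always_kept(self):
        m = np.arange(101.0).reshape(101, 1)
        out = equal_interval_extract(m, 7)
        assert out[0, 0] == 0 and out[-1, 0] == 100

    def test_target_larger_than_rows(self):
        with pytest.raises(ValueError):
            equal_interval_extract(np.zeros((5, 1)), 10)


class TestNormalize:
    def test_affine_map(self):
        s = Sample(np.array([[1.0], [3.0], [5.0]]), "a")
        np.testing.assert_allclose(normalize(s).matrix.ravel(), [0, 0.5, 1])

    def test_constant_channel_maps_to_zero(self):
        s = Sample(np.array([[4.0, 1.0], [4.0, 2.0]]), "a")
        out = normalize(s).matrix
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_range_and_idempotence(self, rng):
        s = Sample(rng.normal(size=(50, 4)), "a")
        once = normalize(s)
        assert once.matrix.min(axis=0) == pytest.approx(np.zeros(4))
        assert once.matrix.max(axis=0) == pytest.approx(np.ones(4))
        np.testing.assert_array_equal(normalize(once).matrix, once.matrix)


class TestChannelShuffle:
    def test_identity_permutation(self, rng):
        batch = [Sample(rng.normal(size=(6, 4)), "a") for _ in range(3)]
        out = channel_shuffle(batch, permutation=[0, 1, 2, 3])
        for orig, new in zip(batch, out):
            np.testing.assert_array_equal(orig.matrix, new.matrix)

    def test_permutation_then_inverse_restores(self, rng):
        batch = [Sample(rng.normal(size=(6, 4)), "a")]
        perm = np.array([2, 0, 3, 1])
        inv = np.argsort(perm)
        out = channel_shuffle(channel_shuffle(batch, perm), inv)
        np.testing.assert_array_equal(out[0].matrix, batch[0].matrix)

    def test_same_seed_same_permutation(self, rng):
        batch = [Sample(rng.normal(size=(6, 4)), "a")]
        a = channel_shuffle(batch, rng=np.random.default_rng(5))
        b = channel_shuffle(batch, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].matrix, b[0].matrix)

    def test_single_permutation_across_batch(self, rng):
        batch = [Sample(np.tile(np.arange(4.0), (6, 1)), "a") for _ in range(4)]
        out = channel_shuffle(batch, rng=np.random.default_rng(8))
        first = out[0].matrix[0]
        for s in out:
            np.testing.assert_array_equal(s.matrix[0], first)

    def test_rejects_non_bijection(self, rng):
        batch = [Sample(rng.normal(size=(6, 4)), "a")]
        with pytest.raises(ValueError):
            channel_shuffle(batch, permutation=[0, 0, 1, 2])


class TestPreprocessing:
    def test_meta_train_path_shape(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(40_000, 8)),
                           0.01, "g", source="meta_train")
        assert preprocess_recording(rec).matrix.shape == (240, 8)

    def test_meta_test_path_shape(self):
        rec = RawRecording(np.random.default_rng(0).normal(size=(4_000, 8)),
                           0.002, "g", source="meta_test")
        assert preprocess_recording(rec).matrix.shape == (240, 8)


class TestBundlePersistence:
    def test_save_load_round_trip(self, tmp_path, small_bundle):
        save_bundle(small_bundle, tmp_path / "b")
        back = load_bundle(tmp_path / "b")
        assert len(back) == len(small_bundle)
        assert back.classes == small_bundle.classes
        for a, b in zip(small_bundle.samples, back.samples):
            assert a.label == b.label
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_bundle_rejects_mixed_shapes(self):
        with pytest.raises(ValueError):
            DatasetBundle([Sample(np.zeros((4, 2)), "a"),
                           Sample(np.zeros((5, 2)), "a")])
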
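from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_window, toy_table
from m5cpred import (
    InputError,
    PseDncEncoder,
    auto_covariance,
    cross_covariance,
    encode,
    encode_dataset,
    kmer_composition,
    load_property_table,
    standardize,
)
from m5cpred.encoding import feature_dim
from m5cpred.properties import DINUCLEOTIDES, PropertyTable, save_property_table
from m5cpred.simulate import SimConfig, simulate_benchmark

windows_st = st.text(alphabet="ACGU", min_size=3, max_size=30)


def loop_auto_covariance(window, m, g, table):
    """Independent brute-force oracle for AC(m, g)."""
    dinucs = [window[i : i + 2] for i in range(len(window) - 1)]
    vals = [table.value(m, d) for d in dinucs]
    mean = sum(vals) / len(vals)
    n = len(vals) - g
    return sum((vals[i] - mean) * (vals[i + g] - mean) for i in range(n)) / n


def loop_cross_covariance(window, m1, m2, g, table):
    """Independent brute-force oracle for CC(m1, m2, g)."""
    dinucs = [window[i : i + 2] for i in range(len(window) - 1)]
    v1 = [table.value(m1, d) for d in dinucs]
    v2 = [table.value(m2, d) for d in dinucs]
    mean1, mean2 = sum(v1) / len(v1), sum(v2) / len(v2)
    n = len(v1) - g
    return sum((v1[i] - mean1) * (v2[i + g] - mean2) for i in range(n)) / n


class TestPropertyTable:
    def test_default_table_shape(self):
        table = load_property_table()
        assert table.n_properties == 10
        assert table.values.shape == (10, 16)
        assert not table.standardized

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        cols = list(DINUCLEOTIDES[:-1])
        path.write_text("property\t" + "\t".join(cols) + "\nrow\t" + "\t".join(["1"] * 15) + "\n")
        with pytest.raises(InputError, match="UU"):
            load_property_table(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        row = ["x"] + ["1"] * 15
        path.write_text(
            "property\t" + "\t".join(DINUCLEOTIDES) + "\nrow\t" + "\t".join(row) + "\n"
        )
        with pytest.raises(InputError):
            load_property_table(path)

    def test_duplicate_property_name_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        line = "row\t" + "\t".join(["1"] * 16) + "\n"
        path.write_text("property\t" + "\t".join(DINUCLEOTIDES) + "\n" + line + line)
        with pytest.raises(InputError, match="duplicate"):
            load_property_table(path)

    def test_save_load_roundtrip(self, tmp_path):
        table = load_property_table()
        path = tmp_path / "table.tsv"
        save_property_table(table, path)
        back = load_property_table(path)
        assert back.property_names == table.property_names
        np.testing.assert_allclose(back.values, table.values)
        assert back.checksum() == table.checksum()


class TestStandardize:
    def test_rows_become_mean0_sd1(self):
        table = standardize(load_property_table())
        np.testing.assert_allclose(table.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(table.values.std(axis=1), 1.0, atol=1e-9)
        assert table.standardized

    def test_idempotent(self):
        once = standardize(load_property_table())
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_constant_row_rejected(self):
        table = PropertyTable(("flat",), np.ones((1, 16)))
        with pytest.raises(InputError, match="[Zz]ero-variance"):
            standardize(table)


class TestKmerComposition:
    def test_mononucleotide_degenerate_case(self):
        np.testing.assert_allclose(kmer_composition("AAAA", 1), [1, 0, 0, 0])

    def test_dinucleotide_hand_count(self):
        vec = kmer_composition("ACGU", 2)
        expected = np.zeros(16)
        idx = {d: i for i, d in enumerate(DINUCLEOTIDES)}
        for d in ("AC", "CG", "GU"):
            expected[idx[d]] = 1 / 3
        np.testing.assert_allclose(vec, expected)

    @given(windows_st, st.integers(min_value=1, max_value=3))
    def test_nonnegative_and_sums_to_one(self, window, k):
        vec = kmer_composition(window, k)
        assert len(vec) == 4**k
        assert np.all(vec >= 0)
        assert np.isclose(vec.sum(), 1.0)

    def test_k_out_of_range(self):
        with pytest.raises(InputError):
            kmer_composition("ACGU", 0)
        with pytest.raises(InputError):
            kmer_composition("ACGU", 5)


class TestCovarianceHandValues:
    table = toy_table(dict(AC=1, CG=3, GA=2), dict(AC=0, CG=1, GA=2))

    def test_auto_covariance_hand_value(self):
        assert auto_covariance("ACGA", 0, 1, self.table) == pytest.approx(-0.5)

    def test_cross_covariance_hand_value_and_asymmetry(self):
        assert cross_covariance("ACGA", 0, 1, 1, self.table) == pytest.approx(0.5)
        assert cross_covariance("ACGA", 1, 0, 1, self.table) == pytest.approx(-0.5)

    def test_constant_profile_gives_zero(self):
        table = toy_table(dict.fromkeys(DINUCLEOTIDES, 7.0))
        for g in (1, 2, 3):
            assert auto_covariance("ACGUA", 0, g, table) == 0.0

    def test_lag_without_summand_rejected(self):
        with pytest.raises(InputError, match="lag"):
            auto_covariance("ACGA", 0, 3, self.table)

    def test_equal_property_indices_rejected(self):
        with pytest.raises(InputError, match="distinct"):
            cross_covariance("ACGA", 1, 1, 1, self.table)

    def test_unstandardized_table_rejected(self, rng):
        raw = load_property_table()
        with pytest.raises(InputError, match="standardized"):
            auto_covariance(random_window(rng, 11), 0, 1, raw)


class TestCovarianceOracle:
    def test_matches_loop_oracle_on_random_windows(self, default_table, rng):
        """Closed-form AC/CC equal a naive double loop on >=100 random cases."""
        checked = 0
        for _ in range(120):
            window = random_window(rng, int(rng.integers(8, 30)))
            g = int(rng.integers(1, len(window) - 2))
            m1, m2 = rng.choice(10, size=2, replace=False)
            assert auto_covariance(window, m1, g, default_table) == pytest.approx(
                loop_auto_covariance(window, m1, g, default_table), abs=1e-12
            )
            assert cross_covariance(window, m1, m2, g, default_table) == pytest.approx(
                loop_cross_covariance(window, m1, m2, g, default_table), abs=1e-12
            )
            checked += 1
        assert checked >= 100

    def test_cc_depends_only_on_its_two_properties(self, default_table, rng):
        window = random_window(rng, 15)
        scrambled = PropertyTable(
            default_table.property_names,
            np.vstack([default_table.values[:2], default_table.values[2:][::-1]]),
            standardized=True,
        )
        assert cross_covariance(window, 0, 1, 2, scrambled) == pytest.approx(
            cross_covariance(window, 0, 1, 2, default_table), abs=1e-12
        )


class TestEncode:
    def test_vector_length_100_lam(self, default_table, rng):
        window = random_window(rng, 41)
        assert len(encode(window, default_table, lam=5)) == 500
        assert len(encode(window, default_table, lam=1)) == 100
        assert feature_dim(5) == 500

    def test_layout_matches_scalar_operations(self, default_table, rng):
        window = random_window(rng, 21)
        lam = 3
        vec = encode(window, default_table, lam=lam)
        pairs = list(permutations(range(10), 2))
        for g in range(1, lam + 1):
            for m in range(10):
                assert vec[(g - 1) * 10 + m] == pytest.approx(
                    auto_covariance(window, m, g, default_table), abs=1e-12
                )
            for p, (m1, m2) in enumerate(pairs):
                assert vec[10 * lam + (g - 1) * 90 + p] == pytest.approx(
                    cross_covariance(window, m1, m2, g, default_table), abs=1e-12
                )

    def test_single_letter_window_encodes_to_zero(self, default_table):
        vec = encode("A" * 12, default_table, lam=3)
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_deterministic(self, default_table, rng):
        window = random_window(rng, 41)
        np.testing.assert_array_equal(
            encode(window, default_table), encode(window, default_table)
        )

    def test_kmer_block_appended(self, default_table, rng):
        window = random_window(rng, 41)
        vec = encode(window, default_table, lam=2, include_kmer=True, k=2)
        assert len(vec) == 200 + 16
        np.testing.assert_allclose(vec[200:], kmer_composition(window, 2))

    def test_lam_too_large_rejected(self, default_table):
        with pytest.raises(InputError, match="lam"):
            encode("ACGAC", default_table, lam=4)


class TestEncoderTransformer:
    def test_sklearn_params_roundtrip(self):
        enc = PseDncEncoder(lam=3, include_kmer=True)
        params = enc.get_params()
        assert params["lam"] == 3
        enc2 = PseDncEncoder().set_params(**params)
        assert enc2.get_params() == params

    def test_fit_exposes_table_and_dims(self):
        enc = PseDncEncoder(lam=5).fit()
        assert enc.n_features_out_ == 500
        assert enc.table_.standardized
        assert len(enc.property_checksum_) == 64

    def test_transform_rejects_mixed_lengths(self):
        enc = PseDncEncoder().fit()
        with pytest.raises(InputError, match="mixed"):
            enc.transform(["ACGUA" * 5, "ACG"])

    def test_encode_dataset_row_order_and_shape(self):
        ds = simulate_benchmark(SimConfig(n_pos=4, n_neg=8, xi=8, seed=7))
        X, y, enc = encode_dataset(ds, lam=2)
        assert X.shape == (12, 200)
        assert y.tolist() == [1] * 4 + [0] * 8
        # row i is exactly the encoding of window i
        np.testing.assert_array_equal(
            X[5], encode(ds.windows[5].window, enc.table_, lam=2)
        )

    def test_encode_dataset_empty_rejected(self):
        from m5cpred.windows import BenchmarkDataset

        with pytest.raises(InputError, match="empty"):
            encode_dataset(BenchmarkDataset(positives=[], negatives=[], xi=3), lam=1)
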
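"""Array container, standardization, wide views, pattern generation, I/O."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metimpute import (
    METArray,
    apply_pattern,
    back_transform,
    generate_missing,
    read_long_csv,
    read_pattern,
    read_slices,
    standardize,
    to_wide,
    write_long_csv,
    write_pattern,
    write_slices,
)


class TestMETArray:
    def test_mask_derived_from_nan(self):
        vals = np.arange(12, dtype=float).reshape(2, 3, 2)
        vals[0, 1, 0] = np.nan
        arr = METArray(vals)
        assert arr.mask.sum() == 11
        assert not arr.mask[0, 1, 0]

    def test_rejects_bad_shapes_and_labels(self):
        with pytest.raises(ValueError):
            METArray(np.zeros((1, 3, 2)))  # I < 2
        with pytest.raises(ValueError, match="unique"):
            METArray(np.zeros((2, 2, 2)), genotype_ids=["a", "a"])
        with pytest.raises(ValueError, match="labels"):
            METArray(np.zeros((2, 2, 2)), environment_ids=["e1"])


class TestStandardize:
    def test_symmetric_column(self):
        vals = np.zeros((3, 2, 1))
        vals[:, 0, 0] = [1.0, 2.0, 3.0]
        vals[:, 1, 0] = [5.0, 0.0, 1.0]
        std = standardize(METArray(vals))
        np.testing.assert_allclose(std.values[:, 0, 0], [-1, 0, 1])
        assert std.col_mean[0, 0] == pytest.approx(2.0)
        assert std.col_sd[0, 0] == pytest.approx(1.0)

    def test_columns_centered_unit_sd(self, tiny_array):
        std = standardize(tiny_array)
        np.testing.assert_allclose(std.values.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(std.values.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_attribute_correlations_preserved(self, small_sim):
        std = standardize(small_sim)
        j = 2
        raw_r = np.corrcoef(small_sim.values[:, j, 0], small_sim.values[:, j, 1])[0, 1]
        std_r = np.corrcoef(std.values[:, j, 0], std.values[:, j, 1])[0, 1]
        assert std_r == pytest.approx(raw_r, abs=1e-12)

    def test_back_transform_round_trip(self, small_sim):
        std = standardize(small_sim)
        np.testing.assert_allclose(back_transform(std), small_sim.values, atol=1e-10)

    def test_observed_only_statistics_and_wholly_missing(self, tiny_array):
        vals = tiny_array.values.copy()
        vals[0, 1, 0] = np.nan  # partial column
        vals[:, 2, 1] = np.nan  # wholly missing column
        std = standardize(METArray(vals))
        obs = vals[1:, 1, 0]
        assert std.col_mean[1, 0] == pytest.approx(obs.mean())
        assert std.col_sd[1, 0] == pytest.approx(obs.std(ddof=1))
        assert np.isnan(std.col_mean[2, 1]) and np.isnan(std.col_sd[2, 1])

    def test_degenerate_columns_error(self):
        vals = np.random.default_rng(0).normal(size=(4, 2, 1))
        vals[1:, 0, 0] = np.nan  # single observed value
        with pytest.raises(ValueError, match=r"environment=0"):
            standardize(METArray(vals))
        vals2 = np.random.default_rng(0).normal(size=(4, 2, 1))
        vals2[:, 1, 0] = 7.0  # zero variance
        with pytest.raises(ValueError, match=r"environment=1"):
            standardize(METArray(vals2))


class TestWideViews:
    def test_bijection_2x2x2(self):
        vals = np.arange(8, dtype=float).reshape(2, 2, 2)
        std = standardize(METArray(np.random.default_rng(1).normal(size=(2, 2, 2))))
        std.values[:] = vals  # exercise the mapping on distinct values
        w = to_wide(std, "genotypes_by_env_attr")
        assert w.matrix.shape == (2, 4)
        seen = set()
        for r in range(2):
            for c in range(4):
                i, j, k = w.triple(r, c)
                assert w.matrix[r, c] == vals[i, j, k]
                seen.add((i, j, k))
        assert len(seen) == 8

    @pytest.mark.parametrize("orientation", ["genotypes_by_env_attr", "env_by_geno_attr"])
    def test_round_trip(self, small_sim, orientation):
        std = standardize(small_sim)
        w = to_wide(std, orientation)
        np.testing.assert_array_equal(w.to_array(), std.values)

    def test_missing_column_visibility(self, small_sim):
        std = standardize(small_sim)
        std.values[:, 1, 2] = np.nan
        std.mask[:, 1, 2] = False
        wide_ig = to_wide(std, "genotypes_by_env_attr").matrix
        wide_jg = to_wide(std, "env_by_geno_attr").matrix
        assert np.isnan(wide_ig).all(axis=0).sum() == 1
        assert not np.isnan(wide_jg).all(axis=0).any()

    def test_column_order_attribute_major(self, small_sim):
        std = standardize(small_sim)
        J = std.shape[1]
        w = to_wide(std, "genotypes_by_env_attr")
        # column k*J + j must carry (i, j, k)
        np.testing.assert_array_equal(w.matrix[:, 2 * J + 3], std.values[:, 3, 2])


class TestGenerateMissing:
    def test_counts_match_percent(self):
        arr = METArray(np.random.default_rng(0).normal(size=(58, 8, 6)))
        pat = generate_missing(arr, 0.05, n_columns=1, seed=1)
        assert pat.n_missing(58) == 139  # round(0.05 * 2784)
        assert len(pat.columns) == 1
        assert len(pat.cells) == 139 - 58
        assert pat.cells.isdisjoint(pat.column_cells(58))

    def test_deterministic_given_seed(self, small_sim):
        a = generate_missing(small_sim, 0.1, n_columns=1, seed=9)
        b = generate_missing(small_sim, 0.1, n_columns=1, seed=9)
        assert a.cells == b.cells and a.columns == b.columns

    def test_boundary_exact_column_budget(self):
        # percent such that the total equals exactly I * n_columns
        arr = METArray(np.random.default_rng(0).normal(size=(10, 5, 2)))
        pat = generate_missing(arr, 0.1, n_columns=1, seed=0)  # round(10) = I
        assert pat.cells == set()

    def test_rejects_bad_percent_and_budget(self, small_sim):
        with pytest.raises(ValueError, match="percent"):
            generate_missing(small_sim, 1.5, seed=0)
        with pytest.raises(ValueError, match="fewer"):
            generate_missing(small_sim, 0.01, n_columns=3, seed=0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), pct=st.sampled_from([0.10, 0.15, 0.25]))
    def test_never_empties_genotype_row(self, seed, pct):
        arr = METArray(np.sin(np.arange(20 * 5 * 3)).reshape(20, 5, 3) + 2.0)
        pat = generate_missing(arr, pct, n_columns=1, seed=seed)
        masked = apply_pattern(arr, pat)
        assert not np.any((~masked.mask).all(axis=1))
        assert masked.mask.sum() == arr.mask.size - pat.n_missing(20)


class TestIO:
    def test_long_csv_round_trip(self, tmp_path, small_sim):
        arr = apply_pattern(small_sim, generate_missing(small_sim, 0.1, seed=4))
        p = tmp_path / "long.csv"
        write_long_csv(arr, p)
        back = read_long_csv(p)
        np.testing.assert_allclose(back.values, arr.values, equal_nan=True)
        assert back.genotype_ids == arr.genotype_ids
        assert back.attribute_ids == arr.attribute_ids

    def test_slices_round_trip(self, tmp_path, small_sim):
        write_slices(small_sim, tmp_path)
        paths = [tmp_path / f"{a}.csv" for a in small_sim.attribute_ids]
        back = read_slices(paths)
        np.testing.assert_allclose(back.values, small_sim.values)

    def test_pattern_json_round_trip(self, tmp_path, small_sim):
        pat = generate_missing(small_sim, 0.1, n_columns=1, seed=5)
        p = tmp_path / "pattern.json"
        write_pattern(pat, p)
        with open(p) as fh:
            d = json.load(fh)
        assert set(d) == {"cells", "columns", "seed", "percent"}
        back = read_pattern(p)
        assert back.cells == pat.cells and back.columns == pat.columns
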
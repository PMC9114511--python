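"""Loading, selection, aggregation, rescaling and imputation of raw tables."""

import numpy as np
import pandas as pd
import pytest

from mcrn import prep


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadWideCsv:
    def test_parses_rows_and_variables(self, tmp_path):
        p = _write(tmp_path, "timestamp,a,b\n2021-01-01,1,2\n2021-01-02,3,4\n2021-01-03,5,6\n")
        raw = prep.load_wide_csv(p, "timestamp")
        assert raw.n_rows == 3
        assert raw.variable_names == ["a", "b"]

    def test_missing_codes_become_nan(self, tmp_path):
        p = _write(tmp_path, "timestamp,a\n2021-01-01,NA\n2021-01-02,2\n")
        raw = prep.load_wide_csv(p, "timestamp")
        assert raw.frame["a"].isna().tolist() == [True, False]

    def test_rows_sorted_by_timestamp(self, tmp_path):
        p = _write(
            tmp_path,
            "timestamp,a\n2021-01-03,3\n2021-01-01,1\n2021-01-02,2\n",
        )
        raw = prep.load_wide_csv(p, "timestamp")
        assert raw.frame["a"].tolist() == [1.0, 2.0, 3.0]

    def test_missing_timestamp_column_errors(self, tmp_path):
        p = _write(tmp_path, "time,a\n2021-01-01,1\n")
        with pytest.raises(ValueError, match="timestamp"):
            prep.load_wide_csv(p, "timestamp")

    def test_non_numeric_cell_reports_row(self, tmp_path):
        p = _write(tmp_path, "timestamp,a\n2021-01-01,1\n2021-01-02,oops\n")
        with pytest.raises(ValueError, match=r"rows \[3\]"):
            prep.load_wide_csv(p, "timestamp")


class TestSelectVariables:
    def _table(self, **cols):
        idx = pd.date_range("2021-01-01", periods=100, freq="D")
        return prep.RawTable(frame=pd.DataFrame(cols, index=idx))

    def test_missingness_threshold_is_strict(self):
        a = np.arange(100.0)
        a[:6] = np.nan  # 6% missing
        b = np.arange(100.0) + np.sin(np.arange(100))
        table = self._table(a=a, b=b)
        sel, report = prep.select_variables(table)
        assert sel.variable_names == ["b"]
        assert "missing fraction" in report.set_index("variable").loc["a", "reason"]

    def test_flat_differenced_series_excluded(self):
        rng = np.random.default_rng(0)
        a = np.repeat(np.arange(50.0), 2)  # diff is 0 half the time
        b = rng.normal(size=100)
        sel, report = prep.select_variables(self._table(a=a, b=b))
        assert sel.variable_names == ["b"]
        assert "zero fraction" in report.set_index("variable").loc["a", "reason"]

    def test_exempt_variable_retained(self):
        a = np.arange(100.0)
        a[:10] = np.nan
        sel, _ = prep.select_variables(self._table(a=a, b=np.random.default_rng(1).normal(size=100)),
                                       exempt={"a"})
        assert "a" in sel.variable_names

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        table = self._table(a=rng.normal(size=100), b=np.repeat(np.arange(50.0), 2))
        once, _ = prep.select_variables(table)
        twice, _ = prep.select_variables(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError, match="every variable"):
            prep.select_variables(self._table(a=np.ones(100)))


class TestAggregateDaily:
    def test_mean_of_day_observations(self):
        idx = pd.DatetimeIndex(["2021-01-01 08:00", "2021-01-01 20:00", "2021-01-02 09:00"])
        raw = prep.RawTable(frame=pd.DataFrame({"a": [2.0, 4.0, 5.0]}, index=idx))
        daily = prep.aggregate_daily(raw)
        assert daily.frame["a"].tolist() == [3.0, 5.0]

    def test_single_observation_per_day_is_identity(self):
        idx = pd.date_range("2021-01-01", periods=4, freq="D")
        raw = prep.RawTable(frame=pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]}, index=idx))
        assert prep.aggregate_daily(raw).frame["a"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_all_missing_day_propagates(self):
        idx = pd.DatetimeIndex(["2021-01-01", "2021-01-02", "2021-01-03"])
        raw = prep.RawTable(frame=pd.DataFrame({"a": [1.0, np.nan, 3.0]}, index=idx))
        out = prep.aggregate_daily(raw).frame["a"]
        assert out.isna().tolist() == [False, True, False]

    def test_grand_mean_preserved_with_balanced_days(self):
        # two observations on each of three days
        idx = pd.DatetimeIndex(
            ["2021-01-01 08:00", "2021-01-01 20:00"] * 1
            + ["2021-01-02 08:00", "2021-01-02 20:00"]
            + ["2021-01-03 08:00", "2021-01-03 20:00"]
        )
        vals = np.array([1.0, 3.0, 2.0, 6.0, 4.0, 8.0])
        raw = prep.RawTable(frame=pd.DataFrame({"a": vals}, index=idx))
        daily = prep.aggregate_daily(raw)
        assert daily.frame["a"].mean() == pytest.approx(vals.mean())


class TestRescaleAndRecode:
    def _table(self, values, reverse=()):
        idx = pd.date_range("2021-01-01", periods=len(values), freq="D")
        return prep.RawTable(
            frame=pd.DataFrame({"a": values}, index=idx), reverse_coded=frozenset(reverse)
        )

    def test_midpoint_maps_to_midpoint(self):
        out = prep.rescale_and_recode(self._table([0.0, 5.0, 10.0]), 1, 7)
        assert out.frame["a"].tolist() == [1.0, 4.0, 7.0]

    def test_reverse_coding_reflects(self):
        out = prep.rescale_and_recode(self._table([1.0, 7.0], reverse=("a",)), 1, 7)
        assert out.frame["a"].tolist() == [7.0, 1.0]

    def test_affine_map_hand_case(self):
        out = prep.rescale_and_recode(self._table([1.0, 3.0, 5.0]), 1, 7)
        assert out.frame["a"].tolist() == [1.0, 4.0, 7.0]

    def test_constant_variable_maps_to_midpoint(self):
        out = prep.rescale_and_recode(self._table([2.0, 2.0, 2.0]), 1, 7)
        assert out.frame["a"].tolist() == [4.0, 4.0, 4.0]

    def test_output_range_equals_target(self):
        rng = np.random.default_rng(3)
        out = prep.rescale_and_recode(self._table(rng.normal(size=50)), 1, 7)
        assert out.frame["a"].min() == pytest.approx(1.0)
        assert out.frame["a"].max() == pytest.approx(7.0)
        assert out.scale_range == (1, 7)


class TestImputeMissing:
    def test_no_missing_is_identity(self, raw_table):
        table = prep.RawTable(
            frame=raw_table.frame.fillna(4.0),
            subsystem_map=raw_table.subsystem_map,
            scale_range=raw_table.scale_range,
        )
        series = prep.impute_missing(table, seed=0)
        np.testing.assert_array_equal(series.values.to_numpy(), table.frame.to_numpy())

    def test_imputed_value_within_scale(self, raw_table):
        series = prep.impute_missing(raw_table, seed=0)
        assert not series.values.isna().any().any()
        lo, hi = raw_table.scale_range
        assert series.values.to_numpy().min() >= lo
        assert series.values.to_numpy().max() <= hi

    def test_deterministic_under_fixed_seed(self, raw_table):
        a = prep.impute_missing(raw_table, seed=7)
        b = prep.impute_missing(raw_table, seed=7)
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_starved_variable_named_in_error(self, raw_table):
        frame = raw_table.frame.copy()
        frame["b"] = np.nan
        table = prep.RawTable(frame=frame, subsystem_map=raw_table.subsystem_map)
        with pytest.raises(ValueError, match="'b'"):
            prep.impute_missing(table)
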
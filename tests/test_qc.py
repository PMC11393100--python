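"""QC rule behaviour, count accounting and rainfall pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doflux import apply_qc_filters, pair_rainfall
from doflux.qc import CANONICAL_COLUMNS, WaterQualitySeries


def _raw(rows):
    base = {
        "timestamp": [],
        "do_mgl": [],
        "temp_c": [],
        "cond_uscm": [],
        "ph": [],
        "ammonium_mgl": [],
        "turbidity_ntu": [],
    }
    for i, row in enumerate(rows):
        base["timestamp"].append(pd.Timestamp("2021-06-01") + i * pd.Timedelta(minutes=15))
        base["do_mgl"].append(row.get("do", 10.0))
        base["temp_c"].append(row.get("temp", 15.0))
        base["cond_uscm"].append(row.get("cond", 500.0))
        base["ph"].append(row.get("ph", 7.8))
        base["ammonium_mgl"].append(row.get("amm", 0.1))
        base["turbidity_ntu"].append(row.get("turb", 10.0))
    return pd.DataFrame(base)


def test_do_above_ceiling_removed_and_counted():
    raw = _raw([{"do": 26.0}, {"do": 10.0}, {"do": 25.0}])
    series, report = apply_qc_filters(raw)
    assert len(series) == 2  # 25.0 is not "> 25"
    assert report.rows_removed_by_rule == {"do_gt_25": 1}
    assert report.reconciles()


def test_clean_row_retained_unchanged():
    raw = _raw([{"do": 10.0}])
    series, report = apply_qc_filters(raw)
    assert len(series) == 1
    assert series.do_mgl.iloc[0] == 10.0
    assert report.rows_removed_by_rule == {}


def test_conductivity_ms_per_cm_converted():
    raw = _raw([{"cond": 0.5}])
    series, report = apply_qc_filters(raw, cond_unit="mS/cm")
    assert series.data["cond_uscm"].iloc[0] == pytest.approx(500.0)
    assert report.unit_conversions == 1


def test_unknown_unit_declaration_is_hard_error():
    with pytest.raises(ValueError, match="unknown conductivity unit"):
        apply_qc_filters(_raw([{}]), cond_unit="S/m")


@pytest.mark.parametrize(
    "fault", [{"ph": -0.1}, {"cond": 0.0}, {"amm": -1.0}, {"turb": -2.0}, {"do": -0.5}]
)
def test_nonpositive_indicator_removed(fault):
    raw = _raw([fault, {}])
    series, report = apply_qc_filters(raw)
    assert len(series) == 1
    assert report.rows_removed_by_rule == {"nonpositive_value": 1}


def test_missing_values_pass_but_are_nan():
    raw = _raw([{}, {}])
    raw.loc[0, "turbidity_ntu"] = np.nan
    series, report = apply_qc_filters(raw)
    assert len(series) == 2
    assert np.isnan(series.data["turbidity_ntu"].iloc[0])


def test_exclusion_interval_rows_removed():
    raw = _raw([{} for _ in range(8)])
    iv = (raw["timestamp"].iloc[2], raw["timestamp"].iloc[4], "oxygen injection")
    series, report = apply_qc_filters(raw, exclusion_intervals=[iv])
    assert len(series) == 5
    assert report.rows_removed_by_rule["excluded_interval"] == 3
    assert report.excluded_intervals[0][2] == "oxygen injection"


def test_salinity_column_dropped_not_rows():
    raw = _raw([{}, {}])
    raw["salinity"] = [0.3, 0.3]
    series, report = apply_qc_filters(raw)
    assert "salinity" not in series.data.columns
    assert report.dropped_columns == ["salinity"]
    assert len(series) == 2


def test_duplicate_timestamps_keep_first():
    raw = _raw([{"do": 10.0}, {"do": 11.0}])
    raw.loc[1, "timestamp"] = raw.loc[0, "timestamp"]
    series, report = apply_qc_filters(raw)
    assert len(series) == 1
    assert series.do_mgl.iloc[0] == 10.0
    assert report.rows_removed_by_rule == {"duplicate_timestamp": 1}


def test_missing_timestamp_column_is_hard_error():
    raw = _raw([{}]).drop(columns=["timestamp"])
    with pytest.raises(ValueError, match="timestamp"):
        apply_qc_filters(raw)


def test_column_map_renames_raw_headers():
    raw = _raw([{}]).rename(columns={"do_mgl": "DOO-MGL", "cond_uscm": "COND"})
    series, _ = apply_qc_filters(
        raw, column_map={"DOO-MGL": "do_mgl", "COND": "cond_uscm"}
    )
    assert series.do_mgl.iloc[0] == 10.0


def test_idempotence():
    raw = _raw([{"do": 26.0}, {}, {"ph": -1.0}, {}])
    series1, report1 = apply_qc_filters(raw)
    series2, report2 = apply_qc_filters(series1.data)
    assert report2.rows_removed_by_rule == {}
    pd.testing.assert_frame_equal(series1.data, series2.data)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    do=st.lists(st.floats(-5, 40, allow_nan=False), min_size=1, max_size=40),
    ph=st.floats(-2, 14, allow_nan=False),
)
def test_qc_conservation_and_bounds_property(do, ph):
    """Counts always reconcile; surviving values never violate QC bounds;
    timestamps are never altered, only dropped."""
    n = len(do)
    ts = pd.date_range("2021-01-01", periods=n, freq="15min")
    raw = pd.DataFrame(
        {"timestamp": ts, "do_mgl": do, "cond_uscm": 500.0, "ph": ph,
         "ammonium_mgl": 0.1, "turbidity_ntu": 5.0, "temp_c": 12.0}
    )
    series, report = apply_qc_filters(raw)
    assert report.reconciles()
    assert report.rows_in == n
    if len(series):
        assert (series.do_mgl > 0).all() and (series.do_mgl <= 25).all()
        assert (series.data["ph"] > 0).all()
        assert set(series.timestamps).issubset(set(ts))


def test_pair_rainfall_broadcasts_by_date():
    ts = pd.date_range("2020-01-01", periods=96 * 2, freq="15min")
    data = pd.DataFrame(
        {c: 1.0 for c in CANONICAL_COLUMNS}, index=ts.rename("timestamp")
    )
    series = WaterQualitySeries("s", data)
    rain = pd.Series([3.2], index=[pd.Timestamp("2020-01-01")])
    out = pair_rainfall(series, rain)
    day1 = out.data.loc["2020-01-01", "rainfall_mm"]
    day2 = out.data.loc["2020-01-02", "rainfall_mm"]
    assert (day1 == 3.2).all() and len(day1) == 96
    assert day2.isna().all()  # absent date -> missing, never silent zero


def test_pair_rainfall_duplicate_dates_error():
    ts = pd.date_range("2020-01-01", periods=4, freq="15min")
    data = pd.DataFrame({c: 1.0 for c in CANONICAL_COLUMNS}, index=ts.rename("timestamp"))
    series = WaterQualitySeries("s", data)
    rain = pd.Series([1.0, 2.0], index=pd.to_datetime(["2020-01-01", "2020-01-01"]))
    with pytest.raises(ValueError, match="duplicate"):
        pair_rainfall(series, rain)
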
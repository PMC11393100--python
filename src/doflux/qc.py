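"""Quality control and ingest for multi-indicator water-quality sensor series.

Raw telemetry records (15-minute nominal spacing) are cleaned by a fixed
rule set before any analysis:

* duplicate timestamps dropped (keep first);
* rows inside caller-supplied exclusion intervals removed (e.g. episodes of
  artificial oxygen injection);
* dissolved oxygen above 25 mg/L discarded as sensor-faulty;
* non-positive DO, conductivity, pH, ammonium or turbidity discarded;
* conductivity declared in mS/cm converted to uS/cm;
* salinity columns dropped (duplicates of conductivity).

Gaps are kept as gaps — the series stays irregular, nothing is imputed —
and missing values are NaN, distinct from removed-by-rule rows.  Every
removal is tallied in a :class:`QCReport` that reconciles exactly:
rows_in == rows_out + sum(removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["WaterQualitySeries", "QCReport", "apply_qc_filters", "pair_rainfall"]

CANONICAL_COLUMNS = [
    "do_mgl",
    "temp_c",
    "cond_uscm",
    "ph",
    "ammonium_mgl",
    "turbidity_ntu",
    "rainfall_mm",
]

# columns screened for non-positive values (temperature may legitimately be <= 0)
_POSITIVE_COLUMNS = ["do_mgl", "cond_uscm", "ph", "ammonium_mgl", "turbidity_ntu"]

DO_CEILING_MGL = 25.0


@dataclass
class WaterQualitySeries:
    """Per-site timestamped multi-indicator series with site metadata."""

    site_id: str
    data: pd.DataFrame  # DatetimeIndex, canonical columns
    dist_to_sea_km: float = 0.0

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise ValueError("WaterQualitySeries.data must have a DatetimeIndex")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if self.dist_to_sea_km < 0:
            raise ValueError("dist_to_sea_km must be non-negative")

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def do_mgl(self) -> pd.Series:
        return self.data["do_mgl"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class QCReport:
    """Row-count accounting for one QC run."""

    rows_in: int
    rows_out: int
    rows_removed_by_rule: dict = field(default_factory=dict)
    unit_conversions: int = 0
    excluded_intervals: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.rows_in == self.rows_out + sum(self.rows_removed_by_rule.values())

    def to_json(self, path=None) -> str:
        payload = {
            "rows_in": self.rows_in,
            "rows_out": self.rows_out,
            "rows_removed_by_rule": self.rows_removed_by_rule,
            "unit_conversions": self.unit_conversions,
            "excluded_intervals": [
                [str(a), str(b), reason] for a, b, reason in self.excluded_intervals
            ],
            "dropped_columns": self.dropped_columns,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _tally(report_counts: dict, rule: str, n: int) -> None:
    if n:
        report_counts[rule] = report_counts.get(rule, 0) + int(n)


def apply_qc_filters(
    raw: pd.DataFrame,
    exclusion_intervals: Sequence[Tuple] = (),
    *,
    site_id: str = "site",
    dist_to_sea_km: float = 0.0,
    column_map: Optional[Mapping[str, str]] = None,
    cond_unit: str = "uS/cm",
    timestamp_column: str = "timestamp",
) -> Tuple[WaterQualitySeries, QCReport]:
    """Clean raw sensor records into a :class:`WaterQualitySeries`.

    Parameters
    ----------
    raw
        Table with a timestamp column (or DatetimeIndex) and at least a DO
        column; indicator columns may be named via ``column_map``
        (raw name -> canonical name).
    exclusion_intervals
        Date ranges ``(start, end[, reason])`` whose rows are removed.
    cond_unit
        Declared unit of the conductivity column, 'uS/cm' or 'mS/cm'
        (the latter is multiplied by 1000).  Unknown declarations are a
        hard error — unit detection is never guessed from magnitudes.
    """
    df = raw.copy()
    if column_map:
        df = df.rename(columns=dict(column_map))

    if isinstance(df.index, pd.DatetimeIndex):
        df = df.reset_index(names=timestamp_column)
    if timestamp_column not in df.columns:
        raise ValueError(
            f"missing timestamp column {timestamp_column!r}; found {list(df.columns)}"
        )
    if "do_mgl" not in df.columns:
        raise ValueError("raw table must contain a DO column mapped to 'do_mgl'")

    counts: dict = {}
    rows_in = len(df)

    ts = pd.to_datetime(df[timestamp_column])
    df = df.drop(columns=[timestamp_column]).set_index(ts.rename("timestamp"))
    df = df.sort_index(kind="stable")

    # salinity duplicates conductivity: drop the column, not rows
    dropped_cols = [c for c in df.columns if c.lower().startswith("salinity")]
    df = df.drop(columns=dropped_cols)

    dup = df.index.duplicated(keep="first")
    _tally(counts, "duplicate_timestamp", dup.sum())
    df = df[~dup]

    intervals = []
    for iv in exclusion_intervals:
        start, end = pd.Timestamp(iv[0]), pd.Timestamp(iv[1])
        reason = iv[2] if len(iv) > 2 else "excluded_interval"
        intervals.append((start, end, reason))
        mask = (df.index >= start) & (df.index <= end)
        _tally(counts, "excluded_interval", mask.sum())
        df = df[~mask]

    if cond_unit not in ("uS/cm", "mS/cm"):
        raise ValueError(
            f"unknown conductivity unit declaration {cond_unit!r}; "
            "expected 'uS/cm' or 'mS/cm'"
        )
    n_conversions = 0
    if cond_unit == "mS/cm" and "cond_uscm" in df.columns:
        valid = df["cond_uscm"].notna()
        df.loc[valid, "cond_uscm"] = df.loc[valid, "cond_uscm"] * 1000.0
        n_conversions = int(valid.sum())

    over = df["do_mgl"] > DO_CEILING_MGL
    _tally(counts, "do_gt_25", over.sum())
    df = df[~over]

    nonpos = pd.Series(False, index=df.index)
    for col in _POSITIVE_COLUMNS:
        if col in df.columns:
            nonpos |= df[col] <= 0  # NaN compares False: missing is not removal
    _tally(counts, "nonpositive_value", nonpos.sum())
    df = df[~nonpos]

    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]

    series = WaterQualitySeries(site_id=site_id, data=df, dist_to_sea_km=dist_to_sea_km)
    report = QCReport(
        rows_in=rows_in,
        rows_out=len(df),
        rows_removed_by_rule=counts,
        unit_conversions=n_conversions,
        excluded_intervals=intervals,
        dropped_columns=dropped_cols,
    )
    assert report.reconciles()
    return series, report


def pair_rainfall(series: WaterQualitySeries, rain: pd.Series) -> WaterQualitySeries:
    """Broadcast a daily rainfall table onto every 15-min row by calendar date.

    ``rain`` is indexed by date (one value per day); duplicate dates are a
    hard error.  Dates absent from ``rain`` yield NaN rainfall, never a
    silent zero.
    """
    if isinstance(rain, pd.DataFrame):
        if rain.shape[1] != 1:
            raise ValueError("rain table must have exactly one value column")
        rain = rain.iloc[:, 0]
    idx = pd.to_datetime(rain.index).normalize()
    if idx.duplicated().any():
        dups = idx[idx.duplicated()].unique()
        raise ValueError(f"overlapping duplicate dates in rainfall table: {list(dups)}")
    lookup = pd.Series(rain.values, index=idx)
    dates = series.data.index.normalize()
    data = series.data.copy()
    data["rainfall_mm"] = lookup.reindex(dates).to_numpy()
    return WaterQualitySeries(
        site_id=series.site_id, data=data, dist_to_sea_km=series.dist_to_sea_km
    )
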
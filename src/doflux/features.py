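"""Covariate engineering for dissolved-oxygen forecasting.

Fourteen covariates per time step: the seven measured channels plus seven
calendar/periodic encodings — hour-of-day, day-of-week and month-of-year
each mapped affinely into [-0.5, 0.5], and sine/cosine of the half-day
phase and of the year phase.  The two trigonometric pairs encode the two
dominant spectral lines of tidal-river DO (half-day tide, annual season),
which :func:`fft_dominant_frequencies` recovers from data.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .qc import WaterQualitySeries

__all__ = ["COVARIATE_COLUMNS", "TARGET_COLUMN", "build_features", "fft_dominant_frequencies"]

MEASURED_CHANNELS = [
    "do_mgl", "temp_c", "cond_uscm", "ph", "ammonium_mgl", "turbidity_ntu", "rainfall_mm",
]
CALENDAR_COLUMNS = [
    "hour_enc", "dow_enc", "month_enc",
    "halfday_sin", "halfday_cos", "year_sin", "year_cos",
]
COVARIATE_COLUMNS = MEASURED_CHANNELS + CALENDAR_COLUMNS
TARGET_COLUMN = "do_mgl"

_HALF_DAY_MINUTES = 720.0


def _year_fraction(index: pd.DatetimeIndex) -> np.ndarray:
    """Elapsed fraction of each timestamp's own calendar year (leap-aware)."""
    year_start = pd.to_datetime({"year": index.year, "month": 1, "day": 1})
    next_start = pd.to_datetime({"year": index.year + 1, "month": 1, "day": 1})
    elapsed = (index.to_numpy() - year_start.to_numpy()).astype("timedelta64[s]").astype(float)
    span = (next_start.to_numpy() - year_start.to_numpy()).astype("timedelta64[s]").astype(float)
    return elapsed / span


def build_features(series: WaterQualitySeries) -> pd.DataFrame:
    """Build the 14-covariate matrix (plus target) from a cleaned series.

    Encodings: hour/23 - 0.5, weekday/6 - 0.5, (month-1)/11 - 0.5;
    half-day phase = 2 pi (minutes since the last 00:00 or 12:00) / 720;
    year phase = 2 pi (elapsed fraction of the calendar year).
    """
    df = series.data.copy()
    idx = df.index
    out = pd.DataFrame(index=idx)
    for col in MEASURED_CHANNELS:
        out[col] = df[col] if col in df.columns else np.nan

    out["hour_enc"] = idx.hour / 23.0 - 0.5
    out["dow_enc"] = idx.dayofweek / 6.0 - 0.5
    out["month_enc"] = (idx.month - 1) / 11.0 - 0.5

    minute_of_day = idx.hour * 60.0 + idx.minute + idx.second / 60.0
    halfday_phase = 2.0 * np.pi * np.mod(minute_of_day, _HALF_DAY_MINUTES) / _HALF_DAY_MINUTES
    out["halfday_sin"] = np.sin(halfday_phase)
    out["halfday_cos"] = np.cos(halfday_phase)

    year_phase = 2.0 * np.pi * _year_fraction(idx)
    out["year_sin"] = np.sin(year_phase)
    out["year_cos"] = np.cos(year_phase)

    assert len(COVARIATE_COLUMNS) == 14
    return out[COVARIATE_COLUMNS]


def fft_dominant_frequencies(
    y,
    k: int = 2,
    nperseg: Optional[int] = None,
) -> List[Tuple[float, float]]:
    """Top-``k`` spectral peaks (frequency in cycles/sample, power), zero excluded.

    ``y`` may be a plain array (assumed regularly sampled) or a pandas
    Series with a DatetimeIndex, in which case irregular sampling is a hard
    error.  With ``nperseg`` set, a Welch average over segments is used
    (coarser bins, lower variance) instead of the full-length periodogram.
    Peaks are local maxima of the spectrum ranked by power.
    """
    if isinstance(y, pd.Series) and isinstance(y.index, pd.DatetimeIndex):
        deltas = np.diff(y.index.to_numpy().astype("datetime64[s]").astype(float))
        if deltas.size and np.ptp(deltas) != 0:
            raise ValueError("irregular sampling: resample before spectral analysis")
        y = y.to_numpy()
    y = np.asarray(y, dtype=float)
    if y.size < 2 * k:
        raise ValueError(f"series length {y.size} too short for {k} peaks")
    y = y - y.mean()

    if nperseg is not None:
        freqs, power = signal.welch(y, fs=1.0, nperseg=nperseg)
    else:
        coeffs = np.fft.rfft(y)
        power = np.abs(coeffs) ** 2 / y.size
        freqs = np.fft.rfftfreq(y.size, d=1.0)

    power = power.copy()
    power[0] = 0.0  # exclude the zero frequency
    peak_idx, _ = signal.find_peaks(power)
    if peak_idx.size == 0:
        peak_idx = np.argsort(power)[::-1][:k]
    order = peak_idx[np.argsort(power[peak_idx])[::-1]][:k]
    return [(float(freqs[i]), float(power[i])) for i in order]
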
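"""Trend/fluctuation separation for sensor series.

Two trend estimators (a centered moving average with filter frequency
``f`` hours, and EMD with the ``m`` fastest modes treated as fluctuation),
each in an additive and a multiplicative flavour:

    additive:        y = T + F
    multiplicative:  y = T * F

Multiplicative decompositions are computed by log-transforming the (strictly
positive) series, detrending additively in log space and exponentiating
back, so the identity ``multiplicative(y) == exp(additive(log y))`` holds
exactly for both methods.  Remainder noise is folded into the fluctuation:
reconstruction is exact to floating tolerance in every variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .emd import IMFSet, emd

__all__ = [
    "DecompositionResult",
    "moving_average_trend",
    "seasonal_detrend",
    "emd_detrend",
]

Mode = Literal["additive", "multiplicative"]


@dataclass
class DecompositionResult:
    """Trend/fluctuation split of one series under a named method and mode."""

    mode: str
    method: str
    trend: np.ndarray
    fluctuation: np.ndarray
    params: dict = field(default_factory=dict)

    def reconstruct(self) -> np.ndarray:
        if self.mode == "additive":
            return self.trend + self.fluctuation
        return self.trend * self.fluctuation


def _window_length(f_hours: float, step_minutes: float) -> int:
    w = int(round(60.0 * f_hours / step_minutes))
    if w < 2:
        raise ValueError(
            f"filter frequency {f_hours} h spans fewer than 2 samples at "
            f"{step_minutes}-min steps"
        )
    if w % 2 == 0:
        w += 1  # symmetric centered window; preserves linear signals exactly
    return w


def moving_average_trend(y, f_hours: float, step_minutes: float = 15.0) -> np.ndarray:
    """Centered moving average with filter frequency ``f_hours``.

    The window length is round(60 f / step) samples, forced odd.  At the
    boundaries the window shrinks symmetrically to fit the record (no
    padding), so the output has the input's length and a centered window
    everywhere — in particular linear signals are reproduced exactly,
    including at the edges.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("moving_average_trend expects a one-dimensional series")
    n = y.size
    w = _window_length(f_hours, step_minutes)
    if w > n:
        raise ValueError(f"window of {w} samples exceeds series length {n}")
    half = w // 2
    idx = np.arange(n)
    k = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(y)])
    lo = idx - k
    hi = idx + k + 1
    return (cs[hi] - cs[lo]) / (hi - lo)


def _require_positive(y: np.ndarray, timestamps=None) -> None:
    bad = np.flatnonzero(~(y > 0))
    if bad.size:
        where = bad[0] if timestamps is None else timestamps[bad[0]]
        raise ValueError(
            f"multiplicative detrending requires strictly positive values; "
            f"first offending sample at index/time {where} (value {y[bad[0]]})"
        )


def seasonal_detrend(
    y,
    f_hours: float = 6.0,
    mode: Mode = "additive",
    step_minutes: float = 15.0,
    timestamps=None,
) -> DecompositionResult:
    """Moving-average detrend: F = y - T (additive) or F = y / T (multiplicative).

    In multiplicative mode the trend is exp(moving average of log y), i.e.
    the additive procedure applied in log space, keeping the two modes
    related by the exact log-transform identity.
    """
    y = np.asarray(y, dtype=float)
    if mode == "additive":
        trend = moving_average_trend(y, f_hours, step_minutes)
        fluct = y - trend
    elif mode == "multiplicative":
        _require_positive(y, timestamps)
        trend = np.exp(moving_average_trend(np.log(y), f_hours, step_minutes))
        fluct = y / trend
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DecompositionResult(
        mode=mode, method="seasonal", trend=trend, fluctuation=fluct,
        params={"f_hours": f_hours, "step_minutes": step_minutes},
    )


def emd_detrend(
    y,
    m_dropped: int = 3,
    mode: Mode = "additive",
    residue_to: Literal["trend", "fluctuation"] = "trend",
    timestamps=None,
    **emd_kwargs,
) -> DecompositionResult:
    """EMD detrend: trend = slow IMFs, fluctuation = the ``m_dropped`` fastest.

    With IMFs ordered slow -> fast, the trend is the sum of the first
    ``N - m_dropped`` IMFs and the fluctuation the sum of the ``m_dropped``
    fastest.  ``residue_to`` controls where the non-oscillatory residue
    goes; the default 'trend' yields fluctuations centered near 0
    (additive) or 1 (multiplicative), while 'fluctuation' folds it into F.
    Multiplicative mode runs the whole procedure on log(y) and
    exponentiates back, so y = T * F exactly.
    """
    y = np.asarray(y, dtype=float)
    if mode == "multiplicative":
        _require_positive(y, timestamps)
        inner = emd_detrend(
            np.log(y), m_dropped=m_dropped, mode="additive",
            residue_to=residue_to, **emd_kwargs,
        )
        return DecompositionResult(
            mode="multiplicative", method="emd",
            trend=np.exp(inner.trend), fluctuation=np.exp(inner.fluctuation),
            params=inner.params,
        )
    if mode != "additive":
        raise ValueError(f"unknown mode {mode!r}")

    modes = emd(y, **emd_kwargs)
    n_modes = modes.n
    if not (1 <= m_dropped <= n_modes):
        raise ValueError(
            f"m_dropped={m_dropped} out of range for decomposition with "
            f"{n_modes} IMFs"
        )
    slow = modes.imfs[: n_modes - m_dropped]
    fast = modes.imfs[n_modes - m_dropped:]
    trend = np.sum(slow, axis=0) if slow else np.zeros_like(y)
    fluct = np.sum(fast, axis=0) if fast else np.zeros_like(y)
    if residue_to == "trend":
        trend = trend + modes.residue
    elif residue_to == "fluctuation":
        fluct = fluct + modes.residue
    else:
        raise ValueError(f"unknown residue_to {residue_to!r}")
    return DecompositionResult(
        mode="additive", method="emd", trend=trend, fluctuation=fluct,
        params={"m_dropped": m_dropped, "n_imfs": n_modes, "residue_to": residue_to},
    )
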
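"""Chronological windowing, naive forecast baselines and error metrics.

The forecasting dataset is built the way sequence models consume it:
chronological train/validation/test split (never shuffled across the
boundary), per-column normalisation statistics from the training rows only,
and sliding (input, horizon) windows that never span a data gap or a split
boundary.  Three baselines are provided:

* Last    — persist the final observed DO value over the horizon;
* Repeat  — replay the start of the previous half-day (48-step) block,
            exploiting the tidal half-day periodicity of DO;
* Linear  — least-squares map from the final input step's 14 covariates to
            the horizon vector of targets.

Errors are mean absolute error and the symmetric mean absolute percentage
error SMAPE = 100/n * sum |y - yhat| / (|y| + |yhat|)  (denominator
|y|+|yhat| with no factor 2), reported per horizon step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import COVARIATE_COLUMNS, TARGET_COLUMN

__all__ = [
    "ForecastDataset",
    "MetricReport",
    "make_windows",
    "baseline_last",
    "baseline_repeat",
    "LinearBaseline",
    "baseline_linear_fit",
    "evaluate",
    "mae",
    "smape",
]

HALF_DAY_STEPS = 48


@dataclass
class ForecastDataset:
    """Chronologically split, train-normalised forecasting windows."""

    features: np.ndarray          # (n, 14) normalised covariates
    target: np.ndarray            # (n,) raw DO
    segment_ids: np.ndarray       # (n,) contiguity labels; windows stay within one
    input_len: int
    horizon: int
    origins: Dict[str, np.ndarray]  # split -> window start row indices
    norm_mean: np.ndarray
    norm_std: np.ndarray
    target_mean: float
    target_std: float
    split_bounds: Tuple[int, int]

    def n_windows(self, split: str) -> int:
        return len(self.origins[split])

    def windows(self, split: str) -> Tuple[np.ndarray, np.ndarray]:
        """Materialise (X, Y): X (nw, input_len, 14) normalised, Y (nw, horizon) raw."""
        starts = self.origins[split]
        L, h = self.input_len, self.horizon
        X = np.stack([self.features[s:s + L] for s in starts]) if len(starts) else \
            np.empty((0, L, self.features.shape[1]))
        Y = np.stack([self.target[s + L:s + L + h] for s in starts]) if len(starts) else \
            np.empty((0, h))
        return X, Y

    def normalize_target(self, y: np.ndarray) -> np.ndarray:
        return (y - self.target_mean) / self.target_std

    def denormalize_target(self, y: np.ndarray) -> np.ndarray:
        return y * self.target_std + self.target_mean


def make_windows(
    features: pd.DataFrame,
    input_len: int,
    horizon: int,
    fractions: Sequence[float] = (0.7, 0.2, 0.1),
    seed=None,
    step_minutes: float = 15.0,
) -> ForecastDataset:
    """Split chronologically, normalise from training rows, build windows.

    ``features`` is a :func:`doflux.features.build_features` frame with a
    DatetimeIndex.  Rows whose timestamp gap exceeds the nominal step start
    a new contiguity segment; no window crosses a segment or split
    boundary.  Training window order is shuffled when ``seed`` is given.
    A split too short to hold a single window is a hard error.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"split fractions must sum to 1; got {fractions}")
    if len(fractions) != 3:
        raise ValueError("expected (train, val, test) fractions")
    cols = [c for c in COVARIATE_COLUMNS if c in features.columns]
    if len(cols) != len(COVARIATE_COLUMNS):
        missing = set(COVARIATE_COLUMNS) - set(cols)
        raise ValueError(f"feature frame is missing covariates: {sorted(missing)}")
    n = len(features)
    idx = features.index
    step = pd.Timedelta(minutes=step_minutes)
    deltas = idx[1:] - idx[:-1]
    breaks = np.concatenate([[False], deltas > step])
    segment_ids = np.cumsum(breaks)

    i1 = int(np.floor(fractions[0] * n))
    i2 = int(np.floor((fractions[0] + fractions[1]) * n))
    bounds = {"train": (0, i1), "val": (i1, i2), "test": (i2, n)}

    raw = features[COVARIATE_COLUMNS].to_numpy(dtype=float)
    train_rows = raw[:i1]
    mean = np.nanmean(train_rows, axis=0)
    std = np.nanstd(train_rows, axis=0)
    std = np.where(std > 0, std, 1.0)
    normed = (raw - mean) / std

    target = features[TARGET_COLUMN].to_numpy(dtype=float)
    t_col = COVARIATE_COLUMNS.index(TARGET_COLUMN)
    target_mean, target_std = float(mean[t_col]), float(std[t_col])

    L, h = int(input_len), int(horizon)
    span = L + h
    origins: Dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for split, (lo, hi) in bounds.items():
        cand = np.arange(lo, hi - span + 1)
        if cand.size:
            ok = segment_ids[cand] == segment_ids[cand + span - 1]
            cand = cand[ok]
        if cand.size == 0:
            raise ValueError(
                f"{split} split ({hi - lo} rows) too short for one "
                f"({L} input + {h} horizon) window"
            )
        if split == "train" and seed is not None:
            cand = rng.permutation(cand)
        origins[split] = cand

    return ForecastDataset(
        features=normed,
        target=target,
        segment_ids=segment_ids,
        input_len=L,
        horizon=h,
        origins=origins,
        norm_mean=mean,
        norm_std=std,
        target_mean=target_mean,
        target_std=target_std,
        split_bounds=(i1, i2),
    )


def baseline_last(ds: ForecastDataset, split: str = "test") -> np.ndarray:
    """Persist the final observed DO of each window across the horizon."""
    starts = ds.origins[split]
    last = ds.target[starts + ds.input_len - 1]
    return np.repeat(last[:, None], ds.horizon, axis=1)


def baseline_repeat(
    ds: ForecastDataset,
    split: str = "test",
    alignment: str = "block_start",
) -> np.ndarray:
    """Replay the previous half-day of DO as the forecast.

    ``alignment='block_start'`` (default, the literal reading): the forecast
    is the first ``horizon`` values of the 48-step block that ends 48 steps
    before the forecast origin.  ``alignment='lagged'``: the ``horizon``
    values exactly one half-day before the forecast window.  Windows without
    48 steps of contiguous history before the origin are a hard error.
    """
    starts = ds.origins[split]
    h = ds.horizon
    preds = np.empty((len(starts), h))
    for j, s in enumerate(starts):
        origin = s + ds.input_len
        hist_start = origin - 2 * HALF_DAY_STEPS
        if hist_start < 0:
            raise ValueError(
                f"window at row {s}: needs {2 * HALF_DAY_STEPS} steps of history "
                "before the forecast origin"
            )
        if ds.segment_ids[hist_start] != ds.segment_ids[origin - 1]:
            raise ValueError(f"window at row {s}: history crosses a data gap")
        if alignment == "block_start":
            preds[j] = ds.target[hist_start:hist_start + h]
        elif alignment == "lagged":
            preds[j] = ds.target[origin - HALF_DAY_STEPS:origin - HALF_DAY_STEPS + h]
        else:
            raise ValueError(f"unknown alignment {alignment!r}")
    return preds


@dataclass
class LinearBaseline:
    """Affine map from the final input step's covariates to the horizon vector."""

    weights: np.ndarray  # (n_covariates + 1, horizon); last row is the intercept
    rank_deficient: bool = False
    ridge_used: bool = False

    def predict(self, ds: ForecastDataset, split: str = "test") -> np.ndarray:
        X = _last_step_design(ds, split)
        return X @ self.weights


def _last_step_design(ds: ForecastDataset, split: str) -> np.ndarray:
    starts = ds.origins[split]
    X = ds.features[starts + ds.input_len - 1]
    return np.hstack([X, np.ones((len(starts), 1))])


def baseline_linear_fit(ds: ForecastDataset, ridge: float = 1e-8) -> LinearBaseline:
    """Least-squares fit of the linear single-step projection on train windows.

    Rank-deficient designs (e.g. constant covariates in a synthetic
    fixture) are solved by the minimum-norm SVD solution, which still
    interpolates consistent systems exactly, and flagged.  If that solve
    ever yields non-finite weights, a tiny ridge (``ridge`` times the mean
    diagonal of the normal matrix) is applied instead and flagged.
    """
    X = _last_step_design(ds, "train")
    starts = ds.origins["train"]
    Y = np.stack([ds.target[s + ds.input_len:s + ds.input_len + ds.horizon] for s in starts])
    W, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    rank_deficient = rank < X.shape[1]
    ridge_used = False
    if not np.all(np.isfinite(W)):
        gram = X.T @ X
        gram = gram + ridge * (np.trace(gram) / gram.shape[0]) * np.eye(gram.shape[0])
        W = np.linalg.solve(gram, X.T @ Y)
        ridge_used = True
    return LinearBaseline(weights=W, rank_deficient=rank_deficient, ridge_used=ridge_used)


def mae(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.mean(np.abs(y_true - y_pred)))


def smape(y_true, y_pred) -> float:
    """SMAPE in percent: 100 * mean |y - yhat| / (|y| + |yhat|); 0/0 terms are 0."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    num = np.abs(y_true - y_pred)
    den = np.abs(y_true) + np.abs(y_pred)
    terms = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return float(np.mean(terms)) * 100.0


@dataclass
class MetricReport:
    """Per-horizon MAE and SMAPE for one model on one split."""

    model: str
    n: int
    per_horizon: Dict[int, Dict[str, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"model": self.model, "horizon": t, **m} for t, m in self.per_horizon.items()
        ]
        return pd.DataFrame(rows)


def evaluate(
    forecasts: np.ndarray,
    truths: np.ndarray,
    horizons: Sequence[int] = (1, 12, 24, 48),
    model: str = "model",
) -> MetricReport:
    """MAE_t and SMAPE_t at each requested horizon step (1-based).

    Horizons beyond the forecast width are skipped.
    """
    forecasts = np.atleast_2d(np.asarray(forecasts, dtype=float))
    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    if forecasts.shape != truths.shape:
        raise ValueError(
            f"forecast/truth shape mismatch: {forecasts.shape} vs {truths.shape}"
        )
    width = forecasts.shape[1]
    report = MetricReport(model=model, n=forecasts.shape[0])
    for t in horizons:
        if t > width:
            continue
        yp, yt = forecasts[:, t - 1], truths[:, t - 1]
        report.per_horizon[int(t)] = {"mae": mae(yt, yp), "smape": smape(yt, yp)}
    return report
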
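"""Windowing contracts, baseline definitions and error metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doflux import (
    baseline_last,
    baseline_linear_fit,
    baseline_repeat,
    build_features,
    evaluate,
    mae,
    make_windows,
    smape,
)
from tests.conftest import make_periodic_series


@pytest.fixture(scope="module")
def dataset(periodic_series):
    return make_windows(build_features(periodic_series), input_len=96, horizon=48, seed=1)


def test_chronological_split_contract(dataset):
    i1, i2 = dataset.split_bounds
    span = dataset.input_len + dataset.horizon
    assert dataset.origins["train"].max() + span <= i1
    assert dataset.origins["val"].min() >= i1
    assert dataset.origins["val"].max() + span <= i2
    assert dataset.origins["test"].min() >= i2


def test_every_usable_origin_in_exactly_one_split(dataset):
    all_origins = np.concatenate([dataset.origins[s] for s in ("train", "val", "test")])
    assert len(all_origins) == len(np.unique(all_origins))


def test_normalization_roundtrip(dataset):
    y = dataset.target[:500]
    assert np.allclose(dataset.denormalize_target(dataset.normalize_target(y)), y, atol=1e-10)


def test_normalization_statistics_from_train_rows_only(periodic_series):
    feats = build_features(periodic_series)
    ds = make_windows(feats, input_len=48, horizon=12)
    i1 = ds.split_bounds[0]
    raw = feats["do_mgl"].to_numpy()[:i1]
    assert ds.target_mean == pytest.approx(raw.mean())
    assert ds.target_std == pytest.approx(raw.std())


def test_gap_excludes_spanning_windows():
    s = make_periodic_series(seed=1, n_days=12)
    data = s.data.drop(s.data.index[500:520])  # carve a 5-hour outage
    s2 = type(s)(s.site_id, data, s.dist_to_sea_km)
    feats = build_features(s2)
    ds = make_windows(feats, input_len=48, horizon=12, fractions=(0.7, 0.2, 0.1))
    span = ds.input_len + ds.horizon
    for split in ("train", "val", "test"):
        for o in ds.origins[split]:
            assert ds.segment_ids[o] == ds.segment_ids[o + span - 1]
    # count reconciliation: candidate origins minus those straddling the gap
    i1 = ds.split_bounds[0]
    candidates = np.arange(0, i1 - span + 1)
    straddling = np.sum(ds.segment_ids[candidates] != ds.segment_ids[candidates + span - 1])
    assert len(ds.origins["train"]) == len(candidates) - straddling


def test_bad_fractions_and_short_split_rejected(periodic_series):
    feats = build_features(periodic_series)
    with pytest.raises(ValueError, match="sum to 1"):
        make_windows(feats, 48, 12, fractions=(0.5, 0.2, 0.2))
    with pytest.raises(ValueError, match="too short"):
        make_windows(feats.iloc[:300], input_len=96, horizon=48)


def test_baseline_last_definition(dataset):
    pred = baseline_last(dataset, "test")
    starts = dataset.origins["test"]
    last_vals = dataset.target[starts + dataset.input_len - 1]
    assert np.allclose(pred, last_vals[:, None])


def test_baseline_last_constant_input_zero_error():
    s = make_periodic_series(seed=0, n_days=12)
    data = s.data.copy()
    data["do_mgl"] = 7.0
    ds = make_windows(build_features(type(s)(s.site_id, data, 1.0)), 48, 12)
    _, Y = ds.windows("test")
    assert mae(Y, baseline_last(ds, "test")) == 0.0


def test_baseline_repeat_exact_on_periodic_signal():
    s = make_periodic_series(seed=0, n_days=20)
    data = s.data.copy()
    t = np.arange(len(data))
    data["do_mgl"] = 9.0 + np.cos(2 * np.pi * t / 48)  # exactly 12-h periodic
    ds = make_windows(build_features(type(s)(s.site_id, data, 1.0)), 96, 48)
    _, Y = ds.windows("test")
    pred = baseline_repeat(ds, "test")
    assert np.max(np.abs(pred - Y)) < 1e-12
    # horizon 48 copies the entire previous half-day block
    starts = ds.origins["test"]
    o = starts[0] + ds.input_len
    assert np.array_equal(pred[0], ds.target[o - 96:o - 48])


def test_baseline_repeat_alignments_differ_on_offperiod_signal():
    s = make_periodic_series(seed=0, n_days=20)
    data = s.data.copy()
    t = np.arange(len(data))
    data["do_mgl"] = 9.0 + np.cos(2 * np.pi * t / 44)  # 11-h period: phase drifts
    ds = make_windows(build_features(type(s)(s.site_id, data, 1.0)), 96, 48)
    _, Y = ds.windows("test")
    err_a = mae(Y, baseline_repeat(ds, "test", alignment="block_start"))
    err_b = mae(Y, baseline_repeat(ds, "test", alignment="lagged"))
    assert err_a > 0 and err_b > 0
    assert not np.isclose(err_a, err_b)


def test_baseline_repeat_insufficient_history_errors():
    s = make_periodic_series(seed=0, n_days=12)
    ds = make_windows(build_features(s), input_len=48, horizon=12)
    # earliest train window starts at row 0: only 48 steps of history
    with pytest.raises(ValueError, match="history"):
        baseline_repeat(ds, "train")


def test_linear_baseline_interpolates_linear_truth():
    """A single-harmonic DO signal is an exact linear function of the
    half-day sin/cos covariates at any horizon (phase shift = rotation), so
    the linear baseline fits it to numerical precision."""
    s = make_periodic_series(seed=4, n_days=80)  # train split spans two months
    data = s.data.copy()
    n = len(data)
    t = np.arange(n)
    rng = np.random.default_rng(4)
    data["do_mgl"] = 9.0 + 1.2 * np.cos(2 * np.pi * t / 48)
    # jitter companion channels so the design has full column rank
    for col in ("temp_c", "cond_uscm", "ph", "ammonium_mgl", "turbidity_ntu", "rainfall_mm"):
        data[col] = data[col] + 0.01 * rng.standard_normal(n)
    ds = make_windows(build_features(type(s)(s.site_id, data, 1.0)), 96, 12)
    fit = baseline_linear_fit(ds)
    assert not fit.ridge_used  # min-norm solve handles the collinear DO column
    _, Y_tr = ds.windows("train")
    assert mae(Y_tr, fit.predict(ds, "train")) < 1e-8


def test_linear_baseline_noise_floor_matches_gaussian_mae():
    """With targets = linear truth + N(0, sigma^2), out-of-sample MAE tends to
    sigma sqrt(2/pi)."""
    rng = np.random.default_rng(1)
    n_tr, n_te, p, h = 4000, 4000, 15, 4
    sigma = 0.3
    X = np.hstack([rng.standard_normal((n_tr + n_te, p - 1)), np.ones((n_tr + n_te, 1))])
    W = rng.standard_normal((p, h))
    Y = X @ W + sigma * rng.standard_normal((n_tr + n_te, h))
    W_fit, *_ = np.linalg.lstsq(X[:n_tr], Y[:n_tr], rcond=None)
    err = mae(Y[n_tr:], X[n_tr:] @ W_fit)
    assert err == pytest.approx(sigma * np.sqrt(2 / np.pi), rel=0.10)


def test_linear_baseline_permutation_invariance(dataset):
    fit = baseline_linear_fit(dataset)
    pred = fit.predict(dataset, "test")
    perm = np.random.default_rng(2).permutation(14)
    # permute covariates consistently in the stored feature matrix
    import copy

    shuffled = copy.copy(dataset)
    shuffled.features = np.hstack([dataset.features[:, perm]])
    fit2 = baseline_linear_fit(shuffled)
    pred2 = fit2.predict(shuffled, "test")
    assert np.allclose(pred, pred2, atol=1e-8)


def test_metric_worked_example_and_symmetry():
    rep = evaluate(np.array([[1.0]]), np.array([[3.0]]), horizons=(1,))
    assert rep.per_horizon[1]["mae"] == pytest.approx(2.0)
    assert rep.per_horizon[1]["smape"] == pytest.approx(50.0)
    assert smape([3.0], [1.0]) == smape([1.0], [3.0])
    assert smape([2.0, 4.0], [2.0, 4.0]) == 0.0
    assert mae([2.0], [2.0]) == 0.0
    assert smape([0.0], [0.0]) == 0.0  # 0/0 convention


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    y=st.lists(st.floats(0.01, 100), min_size=1, max_size=30),
    scale=st.floats(0.1, 10),
)
def test_metric_scale_properties(y, scale):
    rng = np.random.default_rng(0)
    y = np.asarray(y)
    yh = y * (1 + 0.1 * rng.standard_normal(y.size))
    yh = np.abs(yh) + 1e-9
    s = smape(y, yh)
    assert 0.0 <= s <= 100.0
    assert smape(scale * y, scale * yh) == pytest.approx(s, rel=1e-9)
    assert mae(scale * y, scale * yh) == pytest.approx(scale * mae(y, yh), rel=1e-9)


def test_repeat_beats_last_and_linear_at_multistep_horizons(dataset):
    """Half-day periodicity makes the Repeat baseline the strongest naive
    model at multi-step horizons, matching the expected ordering."""
    _, Y = dataset.windows("test")
    reports = {
        "last": evaluate(baseline_last(dataset), Y),
        "repeat": evaluate(baseline_repeat(dataset), Y),
        "linear": evaluate(baseline_linear_fit(dataset).predict(dataset), Y),
    }
    for t in (12, 24, 48):
        assert reports["repeat"].per_horizon[t]["smape"] < reports["last"].per_horizon[t]["smape"]
        assert reports["repeat"].per_horizon[t]["smape"] < reports["linear"].per_horizon[t]["smape"]
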
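"""Synthetic tidal-river dissolved-oxygen generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage is testable without proprietary telemetry data:

* 15-minute sampling over months to years;
* annual seasonality (winter-high, summer-low DO) and a half-day tidal
  oscillation, both as cosines on a strictly positive baseline;
* multiplicative heavy-tailed fluctuations: DO(t) = trend(t) * exp(sigma z_t)
  with z_t a chi-square superposition of Gaussians (slowly switching
  inverse variance), so the log-fluctuations are q-Gaussian by construction
  and the multiplicative-EMD pipeline is the correctly specified model;
* companion channels (temperature anti-correlated with DO annually, diel pH,
  tidal conductivity, lognormal ammonium/turbidity, daily rainfall) that are
  simple coupled sinusoids plus noise — enough to exercise feature building,
  not a river-chemistry model;
* multi-site ensembles whose fitted q-Gaussian scale parameter beta varies
  linearly with distance to sea via the per-site fluctuation scale sigma.

z is clipped at ``|z| <= z_clip`` so generated DO respects the 25 mg/L QC
ceiling (physically, an oxygen-saturation bound); with the defaults the
clip touches only the extreme tail.  Everything is deterministic under the
config seed; per-site seeds derive from (seed, distance) so permuting the
distance list permutes, but does not change, the generated ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import _year_fraction
from .qc import WaterQualitySeries, pair_rainfall
from .superstat import SuperstatChi2Params, implied_qgauss_beta, simulate_chi2_superposition

__all__ = ["SyntheticConfig", "generate_site", "generate_raw_site", "generate_multisite",
           "generate_daily_rainfall"]

STEPS_PER_DAY = 96
HALFDAY_STEPS = 48


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults describe a mid-estuary monitoring site."""

    n_days: int = 365
    step_minutes: int = 15
    start: str = "2020-01-01"
    baseline_do: float = 9.0          # mg/L
    annual_amplitude: float = 2.0     # mg/L, winter-high / summer-low
    halfday_amplitude: float = 1.2    # mg/L, tidal oscillation
    sigma: float = 0.035              # scale of log-fluctuations
    fluctuation: SuperstatChi2Params = field(
        default_factory=lambda: SuperstatChi2Params(n_dof=2.0, beta0_hat=1.0, window_len=48)
    )
    z_clip: float = 20.0
    spike_rate: float = 0.0           # events/day; 0 disables spikes
    spike_log_amplitude: float = 0.15
    # companion-channel couplings
    temp_base: float = 12.0
    temp_annual_amplitude: float = 7.0   # anti-phase with DO annual cycle
    temp_diel_amplitude: float = 0.4
    temp_noise: float = 0.3
    ph_base: float = 7.8
    ph_diel_amplitude: float = 0.15
    ph_noise: float = 0.05
    cond_base: float = 550.0
    cond_tidal_amplitude: float = 120.0
    cond_noise: float = 25.0
    ammonium_median: float = 0.08
    turbidity_median: float = 12.0
    rain_wet_prob: float = 0.45
    rain_mean_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_do - self.annual_amplitude - self.halfday_amplitude <= 0:
            raise ValueError(
                "trend can reach non-positive DO: require "
                "baseline_do > annual_amplitude + halfday_amplitude"
            )
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_days * (24 * 60 // self.step_minutes)


def _streams(seed, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_daily_rainfall(cfg: SyntheticConfig, rng=None) -> pd.Series:
    """Daily rainfall (mm/day): dry days with probability 1 - rain_wet_prob,
    gamma-distributed depth on wet days."""
    if rng is None:
        rng = _streams(cfg.seed, 8)[6]
    days = pd.date_range(cfg.start, periods=cfg.n_days, freq="D")
    wet = rng.random(cfg.n_days) < cfg.rain_wet_prob
    depth = rng.gamma(1.2, cfg.rain_mean_mm / 1.2, size=cfg.n_days)
    return pd.Series(np.where(wet, depth, 0.0), index=days, name="rainfall_mm")


def _do_trend(cfg: SyntheticConfig, idx: pd.DatetimeIndex) -> np.ndarray:
    t = np.arange(len(idx))
    annual = cfg.annual_amplitude * np.cos(2.0 * np.pi * _year_fraction(idx))
    tidal = cfg.halfday_amplitude * np.cos(2.0 * np.pi * t / HALFDAY_STEPS)
    return cfg.baseline_do + annual + tidal


def generate_site(
    cfg: SyntheticConfig,
    site_id: str = "SYN1",
    dist_to_sea_km: float = 10.0,
) -> WaterQualitySeries:
    """Generate one site's multi-indicator series; deterministic under cfg.seed."""
    n = cfg.n_samples
    idx = pd.date_range(cfg.start, periods=n, freq=f"{cfg.step_minutes}min")
    rng_z, rng_temp, rng_ph, rng_cond, rng_chem, rng_spike, rng_rain, _ = _streams(cfg.seed, 8)

    trend = _do_trend(cfg, idx)
    if cfg.sigma > 0:
        z = simulate_chi2_superposition(cfg.fluctuation, n, seed=rng_z)
        z = np.clip(z, -cfg.z_clip, cfg.z_clip)
        log_f = cfg.sigma * z
    else:
        log_f = np.zeros(n)
    if cfg.spike_rate > 0:
        n_events = rng_spike.poisson(cfg.spike_rate * cfg.n_days)
        for _ in range(n_events):
            at = rng_spike.integers(0, n)
            width = int(rng_spike.integers(2, 9))
            amp = rng_spike.exponential(cfg.spike_log_amplitude) * rng_spike.choice([-1.0, 1.0])
            log_f[at:at + width] += amp
    do = trend * np.exp(log_f)

    t = np.arange(n)
    yearfrac = _year_fraction(idx)
    temp = (
        cfg.temp_base
        - cfg.temp_annual_amplitude * np.cos(2.0 * np.pi * yearfrac)
        + cfg.temp_diel_amplitude * np.sin(2.0 * np.pi * t / STEPS_PER_DAY)
        + cfg.temp_noise * rng_temp.standard_normal(n)
    )
    ph = (
        cfg.ph_base
        + cfg.ph_diel_amplitude * np.sin(2.0 * np.pi * t / STEPS_PER_DAY)
        + cfg.ph_noise * rng_ph.standard_normal(n)
    )
    cond = (
        cfg.cond_base
        + cfg.cond_tidal_amplitude * np.cos(2.0 * np.pi * t / HALFDAY_STEPS + 1.0)
        + cfg.cond_noise * rng_cond.standard_normal(n)
    )
    cond = np.maximum(cond, 1.0)
    ammonium = cfg.ammonium_median * np.exp(0.4 * rng_chem.standard_normal(n))
    turbidity = cfg.turbidity_median * np.exp(0.5 * rng_chem.standard_normal(n))

    data = pd.DataFrame(
        {
            "do_mgl": do,
            "temp_c": temp,
            "cond_uscm": cond,
            "ph": ph,
            "ammonium_mgl": ammonium,
            "turbidity_ntu": turbidity,
            "rainfall_mm": np.nan,
        },
        index=idx.rename("timestamp"),
    )
    series = WaterQualitySeries(site_id=site_id, data=data, dist_to_sea_km=dist_to_sea_km)
    rain = generate_daily_rainfall(cfg, rng=rng_rain)
    return pair_rainfall(series, rain)


def generate_raw_site(
    cfg: SyntheticConfig,
    site_id: str = "SYN1",
    dist_to_sea_km: float = 10.0,
    n_faults: int = 40,
) -> Tuple[pd.DataFrame, pd.Series]:
    """A deliberately dirty raw table (plus its daily rainfall) for QC exercises.

    Starts from :func:`generate_site` output and injects the fault classes
    the QC rules target: DO spikes above 25 mg/L, non-positive indicator
    readings, duplicated timestamps, missing values, and a redundant
    salinity column.  Returns a raw frame with a 'timestamp' column.
    """
    series = generate_site(cfg, site_id=site_id, dist_to_sea_km=dist_to_sea_km)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 9173]))
    df = series.data.reset_index()
    n = len(df)
    pick = lambda k: rng.choice(n, size=min(k, n), replace=False)

    k = max(1, n_faults // 4)
    df.loc[pick(k), "do_mgl"] = 25.0 + rng.exponential(5.0, size=k)
    df.loc[pick(k), "ph"] = -rng.random(k)
    df.loc[pick(k), "cond_uscm"] = 0.0
    df.loc[pick(k), "turbidity_ntu"] = np.nan
    # duplicated timestamps: re-append a handful of existing rows
    dup_rows = df.iloc[pick(max(1, n_faults // 8))]
    df = pd.concat([df, dup_rows], ignore_index=True)
    df["salinity"] = df["cond_uscm"] * 0.00055
    rain = generate_daily_rainfall(cfg)
    return df, rain


def generate_multisite(
    base: SyntheticConfig,
    distances: Sequence[float],
    beta_slope: float = -8.0,
    beta_intercept: float = 600.0,
) -> List[WaterQualitySeries]:
    """One series per distance, with target q-Gaussian beta linear in distance.

    The marginal of the chi-square superposition has scale parameter
    beta_z = beta0_hat (n+1)/(2n); fitting the multiplicative fluctuation
    exp(sigma z) recovers beta ~= beta_z / sigma^2, so each site's sigma is
    set to sqrt(beta_z / beta_target(d)).  Non-positive implied beta is a
    hard error.  Per-site seeds derive from (base.seed, distance).
    """
    beta_z = implied_qgauss_beta(base.fluctuation)
    out = []
    for i, d in enumerate(distances):
        beta_target = beta_intercept + beta_slope * float(d)
        if beta_target <= 0:
            raise ValueError(
                f"implied beta {beta_target} <= 0 at distance {d} km; "
                "adjust beta_intercept/beta_slope"
            )
        site_seed = int(
            np.random.SeedSequence([base.seed, int(round(float(d) * 1000))])
            .generate_state(1)[0] % (2**31)
        )
        cfg = replace(base, sigma=math.sqrt(beta_z / beta_target), seed=site_seed)
        out.append(
            generate_site(cfg, site_id=f"SYN{i + 1:02d}", dist_to_sea_km=float(d))
        )
    return out
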
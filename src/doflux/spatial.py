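"""Spatial trends of fitted superstatistical parameters versus distance to sea.

Each monitoring site contributes one fitted (q, beta) record per detrending
variant; this module fits an ordinary least-squares line of a chosen
parameter against distance-to-sea and attaches a seeded permutation p-value
for the Pearson correlation, since the handful of sites makes asymptotic
p-values fragile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DistanceTrend", "fit_distance_trend", "permutation_pvalue"]


@dataclass(frozen=True)
class DistanceTrend:
    """OLS line of a parameter against distance-to-sea."""

    param: str
    slope: float
    intercept: float
    r_value: float
    stderr: float
    n: int
    p_perm: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "param": self.param,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r_value,
            "stderr": self.stderr,
            "n": self.n,
            "p_perm": self.p_perm,
        }


def permutation_pvalue(distances, values, n_perm: int = 10_000, seed=None) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    Values are permuted against distances ``n_perm`` times; the p-value is
    (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r_obs = abs(np.corrcoef(d, v)[0, 1])
    d_c = d - d.mean()
    d_norm = np.sqrt(np.sum(d_c**2))
    hits = 0
    for _ in range(n_perm):
        vp = rng.permutation(v)
        vc = vp - vp.mean()
        r = abs(np.dot(d_c, vc) / (d_norm * np.sqrt(np.sum(vc**2))))
        if r >= r_obs - 1e-15:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def fit_distance_trend(
    records: pd.DataFrame,
    param: str = "beta",
    variant: Optional[str] = None,
    n_perm: int = 10_000,
    seed=None,
) -> DistanceTrend:
    """OLS line of ``param`` (e.g. 'beta' or 'q') against ``dist_to_sea_km``.

    ``records`` carries one row per (site, variant) with columns including
    ``dist_to_sea_km`` and ``param``; pass ``variant`` to restrict to one
    detrending variant.  Requires at least 3 records and non-degenerate
    distances.  Set ``n_perm=0`` to skip the permutation p-value.
    """
    df = records
    if variant is not None:
        df = df[df["variant"] == variant]
    if len(df) < 3:
        raise ValueError(f"need at least 3 site records; got {len(df)}")
    d = df["dist_to_sea_km"].to_numpy(dtype=float)
    v = df[param].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("all distances equal: degenerate design, no trend can be fit")
    res = stats.linregress(d, v)
    p_perm = permutation_pvalue(d, v, n_perm=n_perm, seed=seed) if n_perm else None
    return DistanceTrend(
        param=param,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
        stderr=float(res.stderr),
        n=len(df),
        p_perm=p_perm,
    )
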
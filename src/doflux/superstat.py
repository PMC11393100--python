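"""Superstatistics: chi-square mixtures of Gaussians and detrending model selection.

A slowly fluctuating inverse variance beta-hat, chi-square distributed with
``n`` degrees of freedom and mean ``beta0_hat``, mixed over locally Gaussian
fluctuations yields a marginal that is exactly a q-Gaussian with

    q = 1 + 2 / (n + 1),        beta = beta0_hat * (n + 1) / (2 n),

i.e. a Student-t with ``n`` degrees of freedom up to scale.  This module
simulates that two-time-scale process (piecewise-constant beta-hat over
windows of fixed length) and ranks detrending variants of a series by the
maximum likelihood a q-Gaussian achieves on their fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .detrend import DecompositionResult, emd_detrend, seasonal_detrend
from .qgauss import QGaussianFit, fit_qgauss_mle

__all__ = [
    "SuperstatChi2Params",
    "q_from_dof",
    "dof_from_q",
    "implied_qgauss_beta",
    "simulate_chi2_superposition",
    "compare_detrending_loglik",
]


@dataclass(frozen=True)
class SuperstatChi2Params:
    """Chi-square superstatistics: dof ``n``, mean inverse variance, window length.

    ``window_len`` is the number of consecutive samples sharing one beta-hat
    draw — the long superstatistical time scale in sampling steps.
    """

    n_dof: float
    beta0_hat: float = 1.0
    window_len: int = 48

    def __post_init__(self) -> None:
        if not (self.n_dof > 0):
            raise ValueError(f"n_dof must be positive; got {self.n_dof}")
        if not (self.beta0_hat > 0):
            raise ValueError(f"beta0_hat must be positive; got {self.beta0_hat}")
        if not (self.window_len >= 1):
            raise ValueError(f"window_len must be >= 1; got {self.window_len}")


def q_from_dof(n: float) -> float:
    """Entropic index of the marginal for chi-square dof ``n``: q = 1 + 2/(n+1)."""
    return 1.0 + 2.0 / (n + 1.0)


def dof_from_q(q: float) -> float:
    """Inverse of :func:`q_from_dof`."""
    if not (1.0 < q < 3.0):
        raise ValueError(f"q must lie in (1, 3); got {q}")
    return 2.0 / (q - 1.0) - 1.0


def implied_qgauss_beta(sp: SuperstatChi2Params) -> float:
    """q-Gaussian scale parameter of the marginal: beta0_hat (n+1) / (2 n)."""
    n = sp.n_dof
    return sp.beta0_hat * (n + 1.0) / (2.0 * n)


def simulate_chi2_superposition(sp: SuperstatChi2Params, n_total: int, seed=None) -> np.ndarray:
    """Simulate the two-scale process: windows of Gaussians with chi^2 beta-hat.

    For each consecutive window of ``sp.window_len`` samples one inverse
    variance beta-hat is drawn from Gamma(shape n/2, mean beta0_hat); within
    the window samples are N(0, 1/beta-hat).  Returns ``n_total`` samples.
    """
    if n_total < sp.window_len:
        raise ValueError(
            f"n_total ({n_total}) must be at least window_len ({sp.window_len})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_windows = -(-n_total // sp.window_len)  # ceil
    shape = sp.n_dof / 2.0
    scale = sp.beta0_hat / shape  # mean = shape * scale = beta0_hat
    beta_hats = rng.gamma(shape, scale, size=n_windows)
    sigmas = 1.0 / np.sqrt(beta_hats)
    z = rng.standard_normal(n_windows * sp.window_len)
    x = (z.reshape(n_windows, sp.window_len) * sigmas[:, None]).ravel()
    return x[:n_total]


def _center_fluctuation(fluct: np.ndarray, mode: str) -> np.ndarray:
    """Zero-center a fluctuation sample before fitting.

    Additive fluctuations: subtract the sample mean.  Multiplicative
    fluctuations (ratios around 1): divide by the sample mean and subtract 1,
    so both modes feed zero-centered samples to the q-Gaussian.
    """
    if mode == "additive":
        return fluct - float(np.mean(fluct))
    m = float(np.mean(fluct))
    if m <= 0:
        raise ValueError("multiplicative fluctuation has non-positive mean")
    return fluct / m - 1.0


def _run_variant(y: np.ndarray, method: str, mode: str, params: dict,
                 step_minutes: float) -> DecompositionResult:
    if method == "seasonal":
        return seasonal_detrend(
            y, f_hours=params.get("f_hours", 6.0), mode=mode, step_minutes=step_minutes
        )
    if method == "emd":
        kwargs = {k: v for k, v in params.items() if k != "m_dropped"}
        return emd_detrend(y, m_dropped=params.get("m_dropped", 3), mode=mode, **kwargs)
    raise ValueError(f"unknown detrending method {method!r}")


def compare_detrending_loglik(
    y,
    variants: Sequence[Tuple[str, str, dict]],
    step_minutes: float = 15.0,
    standardize: bool = False,
    fit_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Rank detrending variants by q-Gaussian mean log-likelihood.

    ``variants`` is a sequence of ``(method, mode, params)`` with method in
    {'seasonal', 'emd'} and mode in {'additive', 'multiplicative'}.  Each
    variant's fluctuation sample is centered (and, with ``standardize=True``,
    scaled to unit variance so the comparison is shape-only) and fit by MLE;
    the table is sorted by mean per-observation log-likelihood, descending.
    Variants that fail (e.g. multiplicative on non-positive data) appear in
    the table with status 'failed' rather than being dropped.
    """
    if len(variants) == 0:
        raise ValueError("variants must be non-empty")
    y = np.asarray(y, dtype=float)
    fit_kwargs = fit_kwargs or {}
    rows = []
    for method, mode, params in variants:
        label = f"{mode}-{method}"
        row = {"variant": label, "method": method, "mode": mode, "params": dict(params)}
        try:
            dec = _run_variant(y, method, mode, params, step_minutes)
            f = _center_fluctuation(np.asarray(dec.fluctuation, dtype=float), mode)
            scale = 1.0
            if standardize:
                scale = float(np.std(f))
                if scale <= 0:
                    raise ValueError("zero-variance fluctuation")
                f = f / scale
            fit = fit_qgauss_mle(f, **fit_kwargs)
            row.update(
                status="ok",
                q=fit.params.q,
                beta=fit.params.beta,
                mu=fit.params.mu,
                loglik=fit.log_likelihood,
                mean_loglik=fit.mean_log_likelihood,
                n_obs=fit.n_obs,
                converged=fit.converged,
                scale=scale,
            )
        except (ValueError, FloatingPointError) as exc:
            row.update(status="failed", error=str(exc), mean_loglik=np.nan)
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values("mean_loglik", ascending=False, na_position="last")
    return table.reset_index(drop=True)
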
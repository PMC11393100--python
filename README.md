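# doflux — superstatistics of dissolved-oxygen time series

`doflux` analyses high-frequency (15-minute) dissolved-oxygen (DO) records
from tidal-river water-quality sondes. DO is the single most important
indicator of aquatic ecosystem health; its fluctuations around the seasonal
and tidal trend are heavy-tailed, and modelling those tails is what flags
sites at risk of extreme low-oxygen events. The package is aimed at
limnologists and environmental data scientists who want a tested,
end-to-end pipeline rather than one-off notebook code.

The pipeline:

1. **QC / ingest** (`doflux.qc`) — rule-based cleaning of raw sonde tables
   (DO > 25 mg/L discarded, non-positive probe readings removed, mS/cm to
   uS/cm conversion by explicit declaration, exclusion intervals, duplicate
   timestamps), with a report that reconciles every removed row, plus
   calendar-date pairing of daily rainfall onto 15-minute rows.
2. **Detrending** (`doflux.detrend`, `doflux.emd`) — four variants:
   additive/multiplicative x moving-average/EMD, all exactly reconstructing
   the input, with the multiplicative path defined through the log
   transform.
3. **Superstatistics** (`doflux.qgauss`, `doflux.superstat`) — the
   q-Gaussian density

       p(x) = C_q^{-1} [1 + (q-1) beta (x-mu)^2]^{1/(1-q)},

   exact sampling via the Student-t representation, maximum-likelihood
   fitting of (q, beta, mu), simulation of the chi-square superposition
   whose marginal is exactly q-Gaussian with q = 1 + 2/(n+1), and ranking
   of detrending variants by fitted log-likelihood.
4. **Spatial trends** (`doflux.spatial`) — OLS of fitted parameters against
   distance-to-sea with permutation p-values.
5. **Forecast baselines** (`doflux.features`, `doflux.forecast`) — the
   fourteen-covariate feature matrix (seven channels + calendar/periodic
   encodings), chronological 70/20/10 windowing with train-set
   normalisation, the Last/Repeat/Linear baselines, and MAE / SMAPE
   (denominator |y|+|yhat|, in percent) per forecast horizon.
6. **Synthetic data** (`doflux.synth`) — a generator of tidal-river DO-like
   series (annual + half-day trend, multiplicative chi-square-mixture
   fluctuations, coupled companion channels, multi-site ensembles with a
   linear beta-distance law) so the whole pipeline is testable without
   proprietary telemetry data.

See `docs/methods.md` for the model, the parameter choices and their
rationale, and known limitations.

## Worked example

Fluctuation statistics of a synthetic year of tidal DO:

```python
import numpy as np
from doflux import (SyntheticConfig, generate_site, emd_detrend,
                    fit_qgauss_mle, q_from_dof)

cfg = SyntheticConfig(n_days=365, seed=4)          # chi^2 dof n=2 -> q = 5/3
y = generate_site(cfg).do_mgl.to_numpy()

dec = emd_detrend(y, m_dropped=3, mode="multiplicative")   # y = T * F exactly
f = dec.fluctuation
fit = fit_qgauss_mle(f / f.mean() - 1.0)

print(f"q = {fit.params.q:.3f}  (generator implies {q_from_dof(2.0):.3f})")
print(f"beta = {fit.params.beta:.0f}")
print(f"mean log-likelihood = {fit.mean_log_likelihood:.3f}")
```

Output:

```
q = 1.635  (generator implies 1.667)
beta = 586
mean log-likelihood = 1.421
```

The fitted entropic index recovers the heavy-tail index implied by the
generator's chi-square mixture to within sampling error, and beta measures
the inverse squared width of the relative fluctuations (here a few percent
of the trend).

The numbered drivers under `analysis/` run the full study on synthetic
data and write small tables under `results/`:

```bash
python analysis/01_qc_demo.py                 # QC report, rainfall pairing
python analysis/02_detrend_model_selection.py # multiplicative-EMD wins 10/10
python analysis/03_superstat_identity.py      # q_hat tracks 1 + 2/(n+1)
python analysis/04_spatial_trends.py          # beta decreases seaward->inland
python analysis/05_forecast_baselines.py      # Last/Repeat/Linear MAE & SMAPE
```

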
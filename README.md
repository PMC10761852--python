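# dendrorecon

Tree-ring chronology building and transfer-function climate
reconstruction, written for dendroclimatologists who want the full
workflow — raw ring widths to a validated, spectrally characterized
seasonal precipitation reconstruction — as a tested, scriptable Python
library instead of a chain of GUI tools.

The package covers:

- **I/O** — Tucson/RWL decadal ring-width files and station monthly
  climate CSVs (`dendrorecon.rwl_io`);
- **cross-dating checks** — Gleichläufigkeit and COFECHA-style segment
  correlations against a leave-one-out biweight master
  (`dendrorecon.crossdating`);
- **chronologies** — modified-negative-exponential detrending
  (`a·e^(−b·t)+k`, ratio indices), AIC-selected AR prewhitening, Tukey
  biweight averaging, running Rbar and EPS with truncation at
  EPS ≥ 0.85 (`dendrorecon.chronology`);
- **growth–climate response** — bootstrapped correlation functions over
  a 17-month window, seasonal partial correlations (precipitation
  primary / temperature secondary) with AR(1)-surrogate significance,
  moving correlations (`dendrorecon.climate_response`);
- **reconstruction** — OLS transfer function with leave-one-out and
  split-sample validation: r, R², R²adj, RMSE, F, Durbin–Watson, sign
  test, product-mean test, RE, CE, PRESS (`dendrorecon.reconstruction`);
- **variability** — extreme years (mean ± 1.5 SD), persistent wet/dry
  periods on a 10-yr low-pass spline, per-century extreme counts,
  multitaper spectra with AR(1) red-noise significance, and Morlet
  wavelet power (`dendrorecon.variability`);
- **synthetic data** — a seeded generator of westerly-regime monthly
  climate and climate-driven multi-site forests with known ground truth,
  so every stage is testable without any archive download
  (`dendrorecon.synthetic`).

The core statistical chain, in the field's notation: ring-width index
`RWI_t = w_t / (a·e^(−b·t)+k)`; chronology = biweight mean of (optionally
prewhitened) indices; `EPS = N·r̄/(N·r̄+1−r̄)`; transfer function
`P̂_FebJun = β̂·RC_t + α̂` calibrated by OLS and validated by
`RE = 1 − SSE/SSE(cal-mean)` and `CE = 1 − SSE/SSE(ver-mean)`.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

The `analysis/` directory is a numbered narrative over the library: it
simulates a 719-yr study (three sites, 48 cores, Feb–Jun precipitation
coupling tuned for a calibration correlation near 0.73), then runs each
stage. With the default seed:

```bash
cd analysis
python 01_simulate.py
python 03_chronology.py
python 05_reconstruction.py
```

prints, among other lines:

```
composite chronology 1361-2018, 48 series
  running rbar median 0.260, EPS median 0.906
  EPS >= 0.85 from 1586 CE -> reconstruction span 1586-2018

transfer function: P_FebJun = 270.4 * RC + -23.92
  calibration 1965-2018: r=0.732 R2=0.535 R2adj=0.526 RMSE=49.5 mm F=59.9 DW=1.96
  LOOCV: R2=0.488 RE=0.488 RMSE=52.0 sign 39/14 PMT t=2.92
  split (early_cal): RE=0.576 CE=0.524
  split (late_cal): RE=0.368 CE=0.241
reconstruction 1586-2018 (433 yr), mean 247 mm, band +/- 50 mm
  correlation with simulated truth before 1965: 0.731
```

Reading this: the pooled chronology carries a strong common signal
(EPS above the 0.85 reliability convention from 1586 on), the transfer
function explains ~53% of calibration-era Feb–Jun precipitation
variance, both validation schemes keep positive skill (RE, CE > 0), and
— because the study is synthetic — the pre-instrumental reconstruction
can be scored against the true simulated precipitation, which it tracks
at r ≈ 0.73, matching the calibration-era strength.  `02_crossdate.py`,
`04_climate_response.py` and `06_variability.py` complete the narrative
(dating checks; the positive-precipitation / negative-temperature
response structure; extremes, wet/dry periods and the recovery of the
injected 2.7-yr and 8.2-yr cycles). Tables land in `results/`.

The same workflow is available as a config-driven CLI:

```bash
dendrorecon run-all --config config.yaml --out out/      # or any stage:
dendrorecon chronology --seed 7 --out out/
```

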
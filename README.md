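# greycast

Grey GM(1,1) forecasting for short annual time series, built for the kind
of data environmental agencies actually have: a handful of yearly pollutant
-emission totals, no covariates, and a need for a defensible trend
forecast. The package ships the annual wastewater-emission records of the
Three Gorges Reservoir Area (industrial, domestic, ship-oily and
ship-domestic wastewater, 2008–2014) and reproduces the published grey
analysis of those series end to end.

## The model

For a non-negative series `x⁰ = (x⁰(1), …, x⁰(n))`, `n ≥ 4`, the even
GM(1,1) model smooths the data by first-order accumulation
`x¹(k) = Σ_{j≤k} x⁰(j)` and fits the grey difference equation

```
x⁰(k) + a·z¹(k) = b ,   z¹(k) = ½(x¹(k) + x¹(k−1)) ,   k = 2..n
```

by least squares. `a` is the development coefficient (per-step exponential
rate; `a < 0` means growth), `b` the grey action quantity. The whitenized
equation `dx¹/dt + a·x¹ = b` gives the time-response function
`x̂¹(k) = (C − b/a)·e^{−a(k−1)} + b/a`, and first differencing restores
fitted and forecast values on the original scale:

```
x̂⁰(k) = (1 − eᵃ)(C − b/a)·e^{−a(k−1)} ,   k = 2, 3, …
```

Three refinements around this core:

- **Strengthening buffer operator** for monotone series distorted by
  reporting shocks: `x(k)d = (x(1)+…+x(k−1)+k·x(k))/(2k−1)`, last value
  kept, applied here to the industrial-wastewater record.
- **Initial-condition optimization**: instead of anchoring `C` at `x⁰(1)`,
  choose the `C` minimizing the sum of squared relative simulation errors —
  a strictly convex quadratic with a closed-form minimizer (checked
  against a bounded 1-D search).
- **Adequacy tests**: average relative error `Δ̄` and grey absolute
  correlation degree `η ∈ (0, 1]`, each graded I–IV against the standard
  critical values (Δ̄: 0.01/0.05/0.1/0.2; η: 0.9/0.8/0.7/0.6).

## Worked example

```python
from greycast import GM11, three_gorges_series

data = three_gorges_series()          # W1_raw, W1 (buffered), W2, W3, W4
res = GM11(data["W2"]).fit(init="optimized")
print(res.summary())
```

```
GM(1,1) results: W2 [10^8 tons]
==========================================================
nobs 7   years 2008-2014
development coefficient a      -0.056
grey action quantity    b       5.637
initial condition       C       5.927  (optimized)
----------------------------------------------------------
  year   observed     fitted   residual  rel.err
  2008       5.93       5.93     0.0000   0.0000
  2009       6.23       6.14     0.0917   0.0147
  2010       6.15       6.49    -0.3413   0.0555
  2011       7.06       6.86     0.1953   0.0277
  2012       7.31       7.26     0.0506   0.0069
  2013       7.87       7.68     0.1931   0.0245
  2014       7.94       8.12    -0.1784   0.0225
----------------------------------------------------------
avg relative error  0.0253  (grade II)
grey correlation    0.9923  (grade I)
```

Domestic wastewater grew at rate `e^{−a} − 1 ≈ 5.7%` per year over
2008–2014; the fit is grade II on relative error (average 2.5%) and grade I
on the correlation test, so the model is considered adequate for
extrapolation. Six-year forecasts continue the exponential:

```python
print(res.forecast(6).to_frame())
```

```
 year  forecast
 2015  8.585269
 2016  9.078994
 2017  9.601112
 2018 10.153256
 2019 10.737153
 2020 11.354629
```

i.e. domestic wastewater rising from about 8.59 to about 11.35×10⁸ tons by
2020, while the same pipeline forecasts industrial wastewater falling from
1.64 to 0.66×10⁸ tons.

The same pipeline is scriptable:

```
greycast fit --input emissions.csv --column W2
greycast forecast --input emissions.csv --column W2 --horizon 6
greycast diagnose --input emissions.csv
greycast reproduce        # re-run the packaged study and check every number
greycast synth --a 0.1 --b 5 --c 4 --noise-sd 0.02 --seed 7
```

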
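# pollenmat

Quantitative reconstruction of past forest cover from fossil pollen using
the Modern Analog Technique (MAT), for palynologists and paleoecologists who
need gridded, continuous vegetation-cover estimates rather than qualitative
arboreal-pollen curves.

## The method

A calibration set pairs modern pollen assemblages with satellite forest
cover extracted around each sample as a Gaussian distance-weighted mean,

    cover = Σᵢ wᵢ vᵢ / Σᵢ wᵢ,   wᵢ = exp(−rᵢ² / 2σ²),

over land pixels within a 50-km search radius (water excluded; σ = 500 m
for moss/soil polsters, 100 m for dense-forest samples when it yields higher
cover, 10 km for lakes, with small forested lakes falling back to 500 m).
Assemblages are converted to plant functional type (PFT) scores,
score(PFT) = Σ √(max(0, p − θ)) over member taxa, to blunt no-analog
situations. A fossil assemblage *p* is compared with every calibration
assemblage *q* by squared-chord distance

    d(p, q) = Σₖ (√pₖ − √qₖ)²,   d ∈ [0, 2],

and receives the inverse-distance-weighted mean cover of its k = 8 nearest
analogs with d ≤ T = 0.3, with standard error sd(covers)/√n. Because analog
methods compress dense-forest predictions, a quantile-mapping calibration
curve (resampled quartiles → empirical quantiles → monotone smoothing
spline) is fitted on two-fold cross-validation pairs and applied to all
predictions. Reconstructions are binned into 49 timeslices (250-yr windows,
12,000–0 BP) and interpolated over an elevation model with a
(lon, lat, elevation, age) thin-plate spline, with low-density and water
masks, regional area-average series, Alpine-style elevation-band summaries,
and coarse error grids (interpolated analog SE + delete-one-site jackknife).

Everything is exercised end-to-end on synthetic worlds with known ground
truth: a smooth latent cover field, a pollen forward model with
long-distance transport, metadata defect injection, and fossil cores driven
by a prescribed cover history.

## Worked example

`examples/06_end_to_end_recovery.py` pushes a synthetic world whose forest
cover rises to a plateau between 8,500 and 6,000 BP and then declines
through the full chain:

```
calibration entries: 140, after quality control: 120
two-fold CV (60 iterations): r2 = 0.90, RMSEP = 4.8 %
gridded timeslices: 47
recovered vs true regional series: r = 0.972
recovered peak at 8000 BP; true maximum spans 8500-5750 BP (offset 0 yr)
```

The quality filters removed 20 of 140 modern samples; cross-validation on
the clean synthetic calibration explains 90 % of cover variance with a
4.8-point prediction error; and the regional mean series recovered from
pollen counts alone tracks the prescribed history at r = 0.97, placing the
forest maximum inside the true plateau. The other examples demonstrate each
stage in isolation (generation, extraction, analog matching, bias
correction, gridding).

A thin CLI mirrors the pipeline stages
(`pollenmat simulate|calibrate|qc|reconstruct|map|summarize`), each taking
`--config`, `--seed` and `--log-level`.

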
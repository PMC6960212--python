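# rateguard

Precision and accuracy of specific-rate estimators for fed-batch
cultivations, quantified by simulation.

Specific rates are the workhorse quantities of upstream bioprocess
development: the specific growth rate µ = d ln(xV)/dt (1/h) and the specific
substrate uptake rate qS (g substrate · g biomass⁻¹ · h⁻¹) summarize the
physiological state of a culture and feed directly into process models and
cell-line comparisons. In practice they must be recovered from a handful of
noisy off-line measurements — biomass, substrate, volume, feed rate — and the
estimator chosen for that step has a much larger effect on the result than
most users expect.

`rateguard` provides, in one tested package:

* a **fed-batch simulator** with known kinetics (Monod-limited growth, and an
  induced process with non-competitive inhibition by an accumulating
  product), so that the *true* rates are available as ground truth;
* a **noise model** that mimics realistic analytics: CV-scaled Gaussian
  errors on biomass (2.5–12.5%), substrate (1%) and volume (1%), and a 1%
  full-scale error on the spot feed-rate reading;
* three **growth-rate estimators** — the stepwise log-difference
  µᵢ = ln(Xᵢ₊₁/Xᵢ)/Δt, its moving-average post-smoothing, and the first
  derivative of a penalized cubic smoothing spline (the csaps objective
  p·Σ(y−f)² + (1−p)·∫f″², so p = 1 interpolates and p = 0 is a straight
  line);
* three **uptake-rate formulations** that differ in where the feed enters
  (total consumption smoothed first; total substrate smoothed, feed
  subtracted after; concentration form via the dilution rate D = uf/V);
* an **evaluation layer** that scores every estimator across replicate
  ensembles by per-timepoint CV, RMSE and MAPE against the true rates, over
  sampling intervals of 0.5–4 h.

The headline findings the package reproduces: the stepwise estimator's CV
*grows* as sampling gets more frequent (≈40–50% even with 2.5% biomass
noise at 0.5 h, up to ≈400% on a dynamic process at 12.5% noise); the
smoothing spline holds its CV near or below 50% regardless of interval, an
order of magnitude more precise in the worst case; the RMSE-vs-p surface has
a broad optimum at p ≈ 0.4 (p ≈ 0.2 for the coarsest, noisiest data); and
incorporating the fed substrate *before* smoothing (option 1) keeps the
uptake-rate MAPE near 5% where the subtract-after variants reach ≈18%.

## Worked example

```python
import rateguard as rg

cfg = rg.noncompetitive_default()          # induced process, 24 h
traj = rg.simulate(cfg)                    # noise-free ground truth
obs = rg.sample_and_corrupt(traj, 1.0,     # hourly sampling, 7.5% biomass CV
                            rg.NoiseSpec(cv_biomass=7.5, seed=7))

res = rg.GrowthRateModel(obs, method="spline", p=0.4).fit()
print(res.summary())
print(res.score(traj))
```

```
GrowthRateModel results
----------------------------------------
method:           spline (p=0.4)
rate points:      25
time span:        0.00 .. 24.00 h
mean rate:        0.1837
min / max rate:   0.1479 / 0.2157
fit residual sd:  2.176
{'rmse': 0.0199, 'mape_pct': 9.2}
```

The spline rate tracks the induced decline from µ ≈ 0.19 1/h to ≈ 0.13 1/h
with under 10% mean error from hourly samples at 7.5% biomass noise; the
stepwise estimate on the same data is about four times worse
(`method="stepwise"` → rmse 0.078, mape 39%).

The same two-object pattern covers uptake rates:

```python
feed = rg.FeedRecord.from_trajectory(traj, obs)   # totalizer feed record
qs = rg.SubstrateUptakeModel(obs, feed=feed, option=1, p=0.4).fit()
```

A command-line interface wraps the library (`rateguard simulate | estimate |
qs | evaluate | reproduce`); `rateguard reproduce all --reps 100` regenerates
every summary table of the four studies into `results/`.

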
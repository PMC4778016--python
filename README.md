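# pyroclim

Statistical toolkit for linking boreal forest fire activity to
ocean/climate state from proxy records.

Fire-history networks (tree-ring fire scars, lake-sediment charcoal,
modern forestry statistics) and paleoclimate series (reconstructed
summer temperature, SST, ice-rafted debris, sea-ice cover) come at
mixed resolutions and need a specific chain of statistics before any
claim like *"large fire years cluster in cold ocean regimes"* can be
tested. `pyroclim` implements that chain as a reusable library with a
CLI, for fire ecologists and paleoclimatologists who want the pieces
individually or the pipeline end to end:

* **Large fire year (LFY) detection.** Site-burning in a year is a
  binomial process: with N recording sites and per-site burn
  probability p, a year with X sites burned is anomalous when
  P[count ≥ X] = Σ_{k≥X} C(N,k) p^k (1−p)^{N−k} falls below α. Years
  must also pass a synchronicity filter (fraction of sites burned);
  a Pearson chi-square test checks the binomial model itself.
* **Regime shift detection (STARS).** Sequential t-tests on a series'
  mean with the Regime Shift Index
  RSI(c,m) = Σᵢ wᵢ xᵢ* / (l σ_l), Huber outlier weighting, optional
  AR(1) prewhitening (subsampled OLS with bias correction), and
  least-squares re-dating of confirmed shifts.
* **Cold/warm bootstrap.** Whether LFYs fall preferentially in cold
  regimes, against a null of event years resampled with replacement
  (1000 draws), preserving regime durations.
* **Teleconnection statistics.** Pearson correlation maps between a
  fire index and gridded monthly fields with effective-sample-size
  adjustment n_eff = n(1 − r₁ᵃr₁ᵇ)/(1 + r₁ᵃr₁ᵇ), Monte-Carlo field
  significance, moving-window correlation stability, and superposed
  epoch analysis around event years.
* **Series conditioning.** log/sqrt variance stabilisation, z-scoring,
  constant-resolution binning, multi-site compositing, charcoal
  Box-Cox preparation, linear detrending, 100-yr moving cumulative
  burned area at 10-yr shifts.
* **Synthetic data generators** with the exact statistical structure
  the analyses assume (AR(1) red noise with mean steps, binomial site
  burning with planted LFYs, gridded fields with a localised linear
  teleconnection), so everything is testable without external data.

## Worked example

Detect LFYs in a synthetic 500-yr, 20-site fire-scar network, find
temperature regimes, and test whether the fire years cluster in the
cold regime:

```python
import numpy as np
import pyroclim as pc

m = pc.gen_site_burn_matrix(500, 20, base_p=0.02,
                            lfy_years=[220, 250, 290, 310, 350, 60, 470],
                            lfy_p=0.5, seed=11, start_year=1400)
res = pc.detect_lfy(m, alpha=0.05, min_fraction=0.2)
print("p_hat =", round(res.model.p, 4))
print("LFY years:", res.lfy_years.tolist())
print("chi2 p =", round(res.chi_square_p, 4))

temp = pc.gen_regime_series([pc.SegmentSpec(0, 200, 0.2),
                             pc.SegmentSpec(200, 180, -0.4),
                             pc.SegmentSpec(380, 120, 0.3)],
                            ar1=0.3, sd=0.2, seed=5, start_year=1400)
seg = pc.detect_regimes(temp, pc.StarsConfig(cutoff_l=100, alpha=0.1))
conf = ~seg.provisional
print("change points:", seg.change_points[conf].astype(int).tolist(),
      "RSI:", np.round(seg.rsi_at_change[conf], 2).tolist())

labels = pc.label_years(seg, temp)
boot = pc.bootstrap_lfy_test(res.lfy_years, labels, n_boot=1000, seed=3)
print(f"cold {boot.observed_cold} vs warm {boot.observed_warm}: "
      f"diff {boot.observed_diff}, p = {boot.p_value:.3f}, "
      f"99.9% null quantile = {boot.quantile_999:.1f}")
```

prints

```
p_hat = 0.0266
LFY years: [1460, 1620, 1650, 1690, 1710, 1750, 1870]
chi2 p = 0.0001
change points: [1600, 1780] RSI: [0.96, 1.0]
cold 5 vs warm 2: diff 3, p = 0.058, 99.9% null quantile = 5.0
```

Reading it: the pooled burn probability is 2.7% per site-year; all
seven planted fire years (five in the 1600–1779 interval, two outside)
are recovered with no false positives. The chi-square test rejects the
plain binomial model — correctly, since the planted LFYs are exactly
the kind of overdispersion it looks for. The regime detector confirms
mean shifts at 1600 and 1780 (the planted cold interval) with strong
shift indices, and the bootstrap finds 5 of 7 LFYs in cold years — a
cold excess of 3, suggestive (p = 0.058) but, with only seven events,
not conclusive at the 5% level; the 99.9% quantile of the null
difference is 5.

The same stages are available as a CLI (`pyroclim simulate | process |
lfy | regimes | boottest | fieldcorr | sea | run`); `pyroclim run`
executes the whole pipeline on synthetic data from a YAML config and
writes CSV/NetCDF artifacts plus a JSON log of every seed and
parameter. Reruns are bit-identical.

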
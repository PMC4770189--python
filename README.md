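# orchardgrowth

Thermal-time growth analysis for orchard field data: when is the growth of
an apple tree's organs limited by resources, and what is each organ's
maximum potential growth rate?

Fruit trees allocate carbon among competing sinks — fruits, extension
shoots, the woody frame. An organ growing at its intrinsic capacity is
*sink limited*; an organ held back by assimilate supply is *source
limited*. The classical way to tell them apart is to remove competitors
(defruit a tree, or thin its fruit heavily), measure repeatedly through
the season, and compare relative growth rates against unmanipulated
controls. `orchardgrowth` implements that complete analysis chain for
long-format measurement tables, plus a synthetic-orchard generator with
known ground truth for validating every step.

## What it computes

* **Thermal time.** Growing degree days from hourly temperatures:
  daily GDD = mean of hourly values clamped into [4.5, 35] °C minus the
  4.5 °C base, accumulated from full bloom. All analysis runs on the GDD
  axis.
* **Allometric dry mass.** Fruit volume as a rotational spheroid
  V = 4/3 π r₁r₂r₃; woody above-ground biomass from trunk circumference
  via the power law `wood_AGB = 202.9379 · (c/π)^1.6115` (c in cm, mass
  in g); AIC-selected linear dry-weight models for shoots
  (length, log length × GDD) and fruits (log volume, treatment × GDD),
  fitted to destructively sampled calibration organs.
* **Relative rates.** For sizes x₁, x₂ at thermal times g₁ < g₂, the
  interval rate is (ln x₂ − ln x₁)/(g₂ − g₁), assigned to the interval
  midpoint: RER for length, RGR for dry mass. Trunk RGR is the slope of a
  straight line through mean ln(biomass) vs. GDD.
* **Maximum potential extraction.** Spur filter (final length > 4 cm);
  proleptic/epicormic classification from pruning traces; the five
  heaviest shoots per class ("Max" shoots); the tree with the highest
  normalized circumference increment ("Max" tree); the plain thinned-tree
  mean for fruit, justified by two diagnostic regressions showing fruit
  variability is driven by fruit-set timing.
* **Treatment comparisons.** Per-date one-sided Mann–Whitney tests (shoot
  RER) and Welch t-tests (fruit RGR), Bonferroni-adjusted within each
  comparison series, starred at ≤0.05 / ≤0.01 / ≤0.001; an OLS model of
  trunk relative increment on treatment and GDD.

## Worked example

```python
import orchardgrowth as og
from orchardgrowth.cli_io import run_report

config = og.OrchardConfig(seed=1)          # 15 trees: 5 FRU / 5 DEF / 5 THI
orchard = og.generate_orchard(config)
measurements = og.sample_measurements(orchard)
calibration = og.generate_calibration(orchard)
bundle = run_report(measurements, orchard.weather, calibration,
                    config.bloom_date)
```

prints (via the bundle's contents):

```
season length: 2161 GDD
shoot model: terms=['length', 'log_length:gdd'] RMSE=0.142 g adj R2=0.989
trunk RGR (per GDD): FRU=3.20e-05 DEF=8.46e-05 Max=1.12e-04
Max trunk tree: DEF1_T
 gdd_mid  n_a  n_b  adj_p stars
166.1030   43   20 0.0000   ***
300.2022   43   20 0.0000   ***
454.6876   43   20 0.0000   ***
626.3242   43   20 0.0001   ***
811.4886   43   20 0.0332     *
harvest~initial slope 15.75 (p=0.13), initial~earlyRGR slope -44.0 (p=0.0015)
```

Reading this: the AIC-selected shoot model recovered the generator's
length → mass rule; defruited trees grew woody biomass ~2.6× faster than
controls, and the Max tree faster still; thinned-tree fruit RGR exceeded
control fruit RGR significantly from the first measurement until the
closing of the gap mid-season (the stars column); and initial fruit mass
is negatively related to early RGR — the signature of staggered fruit
set rather than resource limitation.

The same pipeline is scriptable from a shell:

```bash
orchardgrowth simulate --out sim --seed 1
orchardgrowth gdd --weather sim/weather.csv --bloom 2014-04-02
orchardgrowth report --measurements sim/measurements.csv \
    --weather sim/weather.csv --calib sim/calibration.csv \
    --bloom 2014-04-02 --out report/
```

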
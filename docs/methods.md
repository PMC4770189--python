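# Methods

## Thermal time

Physiological time is accumulated growing degree days (GDD) after full
bloom. Sub-hourly temperature records are first averaged to hourly means;
each hourly value is then restricted to the interval [base, cutoff]
(defaults 4.5 °C and 35 °C) and the daily GDD is the mean of the processed
hours minus the base, so 0 ≤ daily GDD ≤ 30.5 by construction.

"Restricting" out-of-range hours is implemented as **clamping**
(saturation) by default. The alternative — discarding those hours — is
available via `cutoff_mode="discard"`, but discarding biases the daily
mean upward on cold days and is not standard degree-day practice. Daily
GDD is credited at the end of its calendar day, and measurement dates map
to end-of-day cumulative GDD, since field measurements are daily
resolution. A day is usable when at least 18 of its 24 hours carry data;
sparser days raise rather than silently biasing the mean.

## Allometric dry-mass estimation

Fruit volume comes from three orthogonal caliper diameters under the
rotational-spheroid formula; it is exactly symmetric in the diameters and
scales cubically.

Woody above-ground biomass uses a fixed power law of trunk circumference,
`AGB = a (c/π)^b` with a = 202.9379 and b = 1.6115. The equation's source
does not document units; this package standardizes on circumference in cm
and mass in g, which yields realistic tree masses (≈8 kg at 10 cm trunk
diameter), and exposes both coefficients in the run configuration.

Shoot and fruit dry-weight models are linear in named transformed
predictors. The formula shorthand "log(length)·GDD" is expanded, by the
usual model-formula convention, to main effects plus interaction; a
pure-interaction candidate set is also offered, and the fitted model is
whichever candidate minimizes AIC. The default family is Gaussian with
identity link (ordinary least squares), which reproduces conventional
RMSE and adjusted-R² diagnostics; a Gamma family with log link is
available because organ dry weights are right-skewed and strictly
positive. When the identity-link fit predicts a non-positive mass for any
calibration organ, the pipeline refits with the Gamma-log family (logged
as a warning): a linear response in log(volume) necessarily undershoots
the smallest fruitlets when masses span two orders of magnitude. Any
non-positive prediction that still arises on tagged organs is treated as
below the model's resolution and masked as missing. Natural logarithms
are used throughout.

The shoot model is fitted on control-tree (FRU) calibration samples only
and applied to all shoots. Defruited shoots have larger basal diameters
than control shoots of equal length, so their predicted masses are
lower-bound estimates; this matters for interpretation, not for the
machinery.

## Relative growth rates

For a size x observed at thermal times g₁ < g₂, the interval relative
rate is (ln x₂ − ln x₁)/(g₂ − g₁): the relative elongation rate (RER) for
length, the relative growth rate (RGR) for dry mass, both per °C·day.
Rates attach to the interval's GDD midpoint — standard in classical
growth analysis and symmetric in the two endpoints. Negative rates are
retained: late-season fruit mass genuinely declines. Rates are invariant
under any common rescaling of the size unit, and summing rate × interval
width reconstructs ln(final/initial) exactly; both properties are tested.

Cohort mean curves align organs on a shared interval grid (the midpoint
vector of the longest series in the cohort). Organs measured on the same
dates may *miss* intervals — a mass below the model's resolution early
on — but may not sit between grid cells; misalignment beyond 1 GDD (a
configurable tolerance) is an error naming the offending organs.

Trunk RGR is the OLS slope of ln(woody biomass) against GDD. The default
path fits the per-date mean of ln(AGB) across a treatment's trees; a
per-tree fit serves the Max-tree path. Normalized trunk circumference is
each reading divided by the tree's first reading, so the relative
increment is (c_t − c₀)/c₀.

Elongation cessation is the first interval midpoint from which *all*
subsequent RER values stay below 10⁻² per °C·day — requiring the plateau
to be sustained makes the detector robust to a single noisy dip.

## Maximum-potential extraction

Shoots with final length not strictly greater than 4 cm are removed as
probable spurs. Shoots on branches with pruning traces are classed
epicormic, the rest proleptic; shoots without the flag are `unknown` and
excluded from selection. Per class, the five shoots with the highest
end-of-season dry mass (pooled across trees) represent the class's
maximum potential; ties break by final length, then organ id, making the
selection deterministic. For the trunk, the Max tree maximizes the final
normalized-circumference increment (the fitted log-linear slope is
reported alongside, but the increment is the selection metric). For
fruit, the plain mean over non-pest-damaged thinned-tree fruits stands in
for the maximum potential, because two diagnostic regressions show the
variability is dominated by fruit-set timing: harvest mass increases with
first-date mass, and first-date mass *decreases* with early-season
(first-interval) RGR — late-set fruits are small but young, hence fast.

## Treatment comparisons

Shoot RER is compared between defruited and control trees with one-sided
unpaired Mann–Whitney tests, fruit RGR between thinned and control trees
with one-sided Welch t-tests, one test per shared measurement interval.
The one-sided direction encodes the resource-limitation hypothesis: the
manipulated group is tested as *greater*. The Mann–Whitney p-value is
exact (full enumeration) when the combined sample size is ≤16 and there
are no ties, otherwise the tie-corrected normal approximation is used.
Welch (unequal variance) is preferred over the pooled t-test as the safer
default. Raw p-values are Bonferroni-multiplied by the number of tested
intervals *within one comparison series* — not across the whole study —
and starred at ≤0.05 (*), ≤0.01 (**), ≤0.001 (***); only the two
stricter thresholds are conventional in the source figures, the
single-star level is the standard completion. Two zero-variance samples
with equal means return p = 0.5 by convention: the data carry no
one-sided evidence.

The trunk analysis first fits OLS of per-tree-and-date relative
circumference increment on treatment (categorical) and GDD, reporting the
full coefficient table; treatment log-biomass RGR lines are then fitted
per treatment and for the Max tree.

## The synthetic orchard

The generator emulates the study conditions: 15 trees in three groups of
five (defruited DEF, heavily thinned THI with nine tagged fruits per
tree, control FRU carrying 0.47 fruits per shoot), measured biweekly
April–July and monthly thereafter, with bloom on 2 April and a ~190-day
season reaching ≈2100 GDD.

* **Weather** is a seasonal sine (mean 10.5 °C, amplitude 8 °C) plus a
  diurnal cosine (amplitude 6 °C, peak 15:00) and iid Gaussian noise
  (sd 1.5 °C), hourly.
* **Shoot length** is logistic in GDD. Control proleptics approach
  ~22 cm with cessation by ≈600 GDD; defruited proleptics ~28 cm
  (controls end ≈28% shorter) slightly later; epicormic shoots (a 20%
  fraction on defruited trees, flagged by pruning traces) approach
  ~96 cm with midpoint 1200 GDD, i.e. they keep elongating into late
  summer, which is what makes their late-season RGR rise above the
  proleptic Max group. A 15% spur fraction (asymptote 2.5 cm) exercises
  the spur filter. Per-shoot asymptotes carry 15% log-normal scatter.
* **Shoot mass** follows the known rule m₀ + m_len·L + m_int·ln(L)·g
  (0.1, 0.08, 0.0004), so the calibration fit has a recoverable truth in
  its candidate term space.
* **Fruit mass** is expolinear, W(g) = (c/r)·ln(1 + e^{r(g−t_b)}):
  exponential at rate r early, linear at rate c late. Thinned trees use
  c = 0.022 g/GDD, r = 0.009/GDD; controls 0.015 and 0.0065 (the thinned
  early RGR ≈39% higher, harvest mass ≈45% higher). Per-fruit set-time
  jitter (sd 60 GDD on t_b) induces the negative initial-mass/early-RGR
  correlation; rate scatter (12% on c, 5% on r) adds the rest of the
  variability. Fruit volume is mass over a seasonal dry-matter density
  (8·10⁻⁵ + 3·10⁻⁸·g g/mm³), emitted as three orthogonal diameters whose
  anisotropy jitter preserves the product, so the spheroid volume
  round-trips exactly. An optional late-season mass decline is off by
  default — it contradicts the pure expolinear form — but available
  since field fruit do shrink slightly before harvest. 8% of fruits are
  flagged pest-damaged.
* **Trunk biomass** is exponential in GDD with treatment rates 2.5·10⁻⁵
  (FRU), 9·10⁻⁵ (DEF), 5·10⁻⁵ (THI) per GDD and 30% per-tree log-normal
  scatter — the realized Max tree then runs ~50% above its group mean.
  Circumference is back-computed through the wood power law; measurement
  noise reflects the collar's 1 mm precision (CV 0.0015 on ≈240 mm).

All randomness flows from one root seed through named substreams, so
weather, tree parameters and measurement noise are independently
reproducible. `ground_truth()` returns every generating parameter; the
truth for a treatment's trunk RGR is the mean of its *realized* per-tree
rates, which is what a fitted treatment line estimates.

What the generator does **not** emulate: within-tree spatial correlation
(canopy level is a label, not a driver), weather-coupled growth (latent
trajectories depend on GDD only through the axis), missing visits,
measurement drift, or biennial-bearing history. Pipeline tests passing on
this generator therefore demonstrate the estimators' correctness under
the stated statistical structure, not robustness to every field
pathology.

## Numerical and testing choices

Simulation-based tests use the study's own scale (5 trees per treatment,
12 shoots per tree, 9 thinned fruits per tree) and seeded replicates:
100 replicates for pipeline-recovery rates, 500 for family-wise error
calibration. The Mann–Whitney exact path is verified against a full
enumeration oracle for all splits up to a combined n of 8. AIC model
selection is tested against its asymptotic behaviour — with k spurious
extra parameters the true smaller model is kept with probability
P(χ²_k ≤ 2k), about 86.5% for k = 2 — rather than against an arbitrary
higher figure. Dry-weight models serialise to JSON (terms, coefficients,
family, treatment levels), and the report bundle is a pure function of
(inputs, configuration), reproducible byte-for-byte.

## Known limitations

* The wood allometry's coefficients are fixed inputs, not refitted; no
  uncertainty propagates from them.
* Interval rates are unsmoothed; no functional (spline or Richards)
  growth-curve fitting is provided, by design.
* Per-date tests treat dates independently; no repeated-measures or
  mixed-effects modelling.
* The gamma-log fallback changes the model family based on a training-set
  diagnostic; when it triggers, reported RMSE/adjusted R² refer to the
  refitted family.
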
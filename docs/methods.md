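# Methods

## Model and procedure

Tooth dentine and bone apatite precipitate in oxygen isotope equilibrium
with body water, which in cetaceans closely tracks ambient seawater, so
phosphate δ¹⁸O varies linearly with source-water δ¹⁸O:

    δ¹⁸O_P = β₀ + β₁ · δ¹⁸O_marine.

The package inverts this interspecific calibration per whale,
m̂ = (x − β₀)/β₁, and treats the three sources of uncertainty — the
measurement error on x and the sampling uncertainty of β₀ and β₁ — as
independent zero-mean normals, propagated by a first-order Taylor (delta
method) expansion:

    SE(m̂)² = (σₓ² + σ_β₀²)/β₁² + (x − β₀)² σ_β₁² / β₁⁴.

The second term grows with leverage |x − β₀|, which is why whales with
extreme δ¹⁸O_P carry the widest intervals.  Confidence intervals use the
standard normal quantile (1.959964 at 95%), consistent with a delta-method
construction; no t correction is applied because the calibration's effective
degrees of freedom are not published with it.

Assignment is pure extraction: a grid cell of the sea-surface δ¹⁸O isoscape
is consistent with a whale iff its value lies in the closed interval
[ci_lo, ci_hi].  Boundary cells count (the conservative reading), land and
no-data cells are never assignable, and no spatial interpolation or
smoothing is performed.  Only estimate-side variance enters the interval;
variance of the isoscape product itself is not modelled, so masks are
conditional on the gridded field being exact.

δ¹³C of structural carbonate is normalised for the oceanic Suess effect —
the secular decline of marine δ¹³C under fossil-fuel CO₂ — to a common
reference year before any cross-decade comparison:

    adjusted = raw + rate · (ref_year − midpoint),

with the tissue deposition midpoint = year of death − age/2 (whole teeth and
bone integrate over the animal's life, so the midpoint is the natural single
time stamp).  Whales without an age estimate are adjusted from their year of
death and flagged in all outputs.  An OLS screen of isotope values against
midpoint (slope, two-sided t-test p with n − 2 df) is reported alongside but
never gates the adjustment: the correction is applied unconditionally at the
configured rate.  δ¹³C is never used for isoscape assignment — dietary and
metabolic influences on carbonate δ¹³C cannot be separated from baseline
variation without trophic information the specimens do not carry.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `beta0_mean` ± `beta0_sd` | 18.73 ± 0.30 | ‰ VSMOW | calibration intercept |
| `beta1_mean` ± `beta1_sd` | 0.81 ± 0.23 | – | calibration slope |
| `meas_sd` | 0.22 | ‰ | replicate reproducibility of a δ¹⁸O_P analysis |
| `ci_level` | 0.95 | – | two-sided CI for assignment |
| `rate` | −0.023 | ‰ yr⁻¹ | Suess drift of marine δ¹³C |
| `ref_year` | 2013 | year | normalisation target (most recent sample) |
| `cluster_k` | 3 | – | dendrogram cut reported by the pipeline |

`meas_sd` is the published average replicate reproducibility of the δ¹⁸O_P
method; it is the only measurement-error scale the delta method needs, and
with it the propagated SEs reproduce the published per-whale values at two
decimals across the full fixture.  β₀ and β₁ are treated as independent
(their covariance is not published); this slightly misstates the SE if the
original fit's coefficients were correlated, a documented limitation.

## Statistics

Rank-based comparisons are implemented directly (and cross-checked against
scipy/statsmodels in the test suite, which are never used as the
implementation): midranks for ties, the tie-corrected Kruskal–Wallis H
referred to χ²_{k−1}, Dunn's pairwise z with the pooled tie correction and
two-sided normal p-values, and Benjamini–Hochberg step-up adjustment over
all pairs jointly.  When every pooled value is identical the tie correction
divides by zero and the functions raise a degenerate-data error rather than
returning a statistic.

Clustering is UPGMA (average linkage) on pairwise |Δδ¹⁸O_P| — the Euclidean
metric in one dimension.  When two candidate merges are exactly tied, the
pair whose smallest member leaf appears earliest in input order merges
first; this makes the dendrogram over the fixture (which contains an exact
three-way tie at 17.62‰) reproducible.  Trees export to newick with branch
lengths equal to merge-height differences, and the parser reconstructs a
tree with identical leaves and cophenetic distances.  `cut_tree(k)` removes
the k − 1 highest merges.  Group SDs use the n − 1 denominator; a singleton
group reports its SD as missing rather than zero.

Per-tooth growth-layer (GLG) series support standardisation to the first
layer (first value → 0, other analyte untouched) and a within-tooth
variation index (sample SD and range), the series-level measure of
interannual variation in distribution.

## Synthetic data and what it validates

`gen_isoscape` builds value(lat) = base + slope·lat + step·[lat ≥ front] +
noise with randomly placed land cells: the minimal structure — gradient plus
sharp front — that the assignment logic exercises.  Defaults emulate a North
Atlantic-like field: −0.02‰/° gradient, −2‰ step at 40°N, 10% land, on a
60×72 grid spanning 0–80°N, 80°W–10°E.  `gen_specimens` places whales
uniformly in their group's latitude band, draws observed δ¹⁸O_P through the
forward calibration model, and generates δ¹³C as a group baseline plus the
configured Suess drift at the whale's deposition midpoint plus N(0, 0.3‰)
noise.  Default cohort sizes (10 + 7) mirror the real ECA/NWA sample; the
validation experiments scale the same generator up (200 for parameter
recovery, 1000 for coverage), sizes chosen so binomial/OLS error bands are
tight enough to be informative while the full suite runs in seconds.  All
draws derive from per-component substreams of one seed, so regenerating the
grid alone never shifts the cohort draws.

The coverage experiment draws, per whale, a calibration realisation
β₀* ~ N(β₀, σ_β₀), β₁* ~ N(β₁, σ_β₁) in addition to measurement noise, and
measures how often the true source cell lands in the whale's CI mask.  This
forward randomisation is deliberate: it generates data whose estimator-error
distribution is exactly the one the delta method claims to describe, making
the nominal 95% level the correct expectation (observed ≈ 0.94–0.95 at
n = 1000).  With the coefficients held fixed instead, the propagated SE
would overstate the per-whale error and coverage would drift toward 1 —
a conservative, but uninformative, experiment.  A ~10⁻⁹‰ guard is added to
the interval when checking the true cell so that the all-noise-free
degenerate limit yields coverage exactly 1 despite floating-point roundoff;
it is orders of magnitude below measurement precision and has no effect
otherwise.

What the generator does **not** emulate: ocean circulation, salinity–δ¹⁸O
structure, seasonal movement, longitudinal gradients, bone remodelling, or
spatially correlated isoscape error.  Passing the synthetic experiments
therefore shows the estimation and extraction machinery is correct and
calibrated under the model's own assumptions — not that the model captures
every feature of real specimens or real isoscapes.

## The Monte-Carlo oracle

`mc_oracle_se` validates the delta method by simulating the forward
measurement model around the point estimate — x* = β₀* + β₁*·m̂ + ε, then
re-estimating m* = (x* − β₀)/β₁ exactly as the inversion does — and taking
the sample SD of m* over 10⁶ draws.  This is the empirical sampling SD of
the estimator, the quantity a standard error describes; it agrees with the
delta formula to ~0.1% and would expose an error in any term of it.  Note
that naively dividing by the *drawn* slope instead yields a ratio of
normals, which has no finite moments: its sample SD is dominated by
whichever draw lands nearest β₁* = 0 and never converges (empirically it
wanders over two orders of magnitude across seeds).  The exact ratio
distribution's central spread is also genuinely a few percent wider than the
first-order linearisation at high leverage (slope CV ≈ 28%) — the reason
published intervals of this kind should be read as first-order
approximations.

## Numerical and edge-case choices

- Latitudes are normalised ascending on read; longitudes are wrapped to
  [−180, 180) but kept in file order (assignment is value-based, so
  longitude rotation cannot change a mask's content).
- Missing values are `None`/NaN throughout, never sentinel zeros; a missing
  age is representable and distinct from age 0.
- The fixture's expected-value table flags two rows whose published
  Suess-adjusted δ¹³C cells are interchanged (each matches the formula
  applied to the other's raw value) and the four age-less bone rows whose
  published adjustments are not reconstructible; comparisons use the
  formula-consistent reading and skip the flagged cells.
- Recomputing the two small bone cohorts' summaries from the rounded
  published inputs shifts the Greenland mean to exactly the half-way case
  17.375 and the Denmark SD to 0.397; comparisons for those two cells allow
  one unit in the last printed digit, since the published digits came from
  unrounded laboratory values.
- Presentation rounding (2 d.p.) happens only in `results.csv`; every other
  artifact carries full precision, and reruns on identical inputs are
  byte-identical.

## Known limitations

- The calibration covariance between β₀ and β₁ is unavailable and assumed
  zero.
- Surface-layer isoscape values only; vertical δ¹⁸O structure (relevant for
  deep-foraging whales) is not modelled.
- Whole-tooth and bone samples integrate decades; the assignment is a
  long-term average distribution, blind to seasonal movement.
- Isoscape-side variance is not propagated into the masks, so empty or
  narrow masks can reflect isoscape error as much as whale biology.
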